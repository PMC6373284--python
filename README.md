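# veinadapt

A hybrid PDE / agent-based / particle simulator of vein-graft vascular
adaptation on a 2D cross section.

After bypass surgery, a vein graft adapts to its new arterial environment
through intimal hyperplasia — smooth muscle cells (SMCs) migrating into the
intima, proliferating and depositing extracellular matrix (ECM) — and
through inward/outward wall remodeling. The balance of these processes
decides whether the lumen stays open or restenoses. `veinadapt` models the
graft cross section as four sub-domains (lumen, tunica intima, tunica
media, external support) bounded by elastic membranes and couples three
sub-models on a time-split hourly cycle:

- **Mechanical model (MM).** Steady fully developed lumen flow with no-slip
  walls imposed by a volume penalty on a Cartesian grid, rescaled to a
  prescribed flow rate Q (constant-flow control); wall shear τ_wall from
  one-sided normal derivatives; thick-cylinder (Lamé) strain energy σ
  across the wall; and a growth factor G diffusing from the lumen boundary
  (Dirichlet value F(τ) = max(0, (τ̄−τ)/τ̄), zero external flux). The MM
  is refreshed only when the lumen boundary moves more than a tolerance of
  the order of one SMC diameter.
- **Tissue plasticity (TP).** Each SMC is a disc agent with a 12 h mitotic
  clock and a 2 h ECM clock, interrogated hourly. Event probabilities follow
  the stochastic laws p_div = α₁A(t)(1 + α₅G), p_apo = α₁A(t),
  p_prod = α₂A(t)(1 + α₆Δσ/σ̄), p_deg = α₂A(t), p_mig = α₇A(t)(1 + α₈G),
  all scaled by the macrophage activity envelope A(t) = exp(−(t−T)/δT).
- **Tissue remodeling (TR).** The wall is a highly viscous incompressible
  medium on a staggered grid; membranes exert spring tension spread through
  the 4-point regularized delta kernel (immersed boundary method); a Chorin
  projection with event mass sources/sinks in the pressure Poisson problem
  reorganizes the tissue; SMCs move passively with the medium and actively
  by Ẋ = V_S + V_E + V_G + V_R (cell–cell repulsion, matrix invasion,
  chemotaxis, bounded random motility). An energy criterion on the Lamé
  wall energy decides whether growth is accommodated inward (lumen loss)
  or outward.

A reduced zero-dimensional dynamical system (radii triple R/re/r, intimal
drift dA_I/dt = turnover·A(t)·γ·(Δτ/τ̄)·A_I with Poiseuille shear feedback
under constant flow) cross-validates the hybrid model: a seeded genetic
algorithm calibrates γ against the hybrid ensemble's mean lumen-area
trajectory.

## Worked example

```python
import numpy as np
from veinadapt import preset_experiments, run_simulation

cfg = preset_experiments("cross_validation")
cfg.horizon_hours = 480            # 20 days
res = run_simulation(cfg, seed=2)
tr = res.trajectory[res.trajectory.t_h % 120 == 0]
print(tr[["t_h", "lumen_area", "intimal_area", "smc_intima"]].to_string(index=False))
```

prints (areas in mm²):

```
 t_h  lumen_area  intimal_area  smc_intima
   0    0.180927      0.065345         145
 120    0.153079      0.089726         431
 240    0.126035      0.114637         704
 360    0.115321      0.124843         812
 480    0.114823      0.125654         824
```

Under the 50% shear drop the lumen narrows from 0.181 mm² toward the
constant-flow shear set point (lumen ratio (1−0.5)^(2/3) ≈ 0.63) while the
intima roughly doubles by SMC proliferation, then freezes as the macrophage
envelope decays — the classic early-restenosis trajectory. The companion
zero-dimensional system reproduces the same curve after γ calibration
(on the 5-run ensemble mean the calibrated gain comes out γ* ≈ 4.6 with a
maximum pointwise lumen-area discrepancy between the two models below 2%).

The command line mirrors the library:

```bash
veinadapt simulate basic_solution --seed 1 --runs 3 --out out/
veinadapt simulate cross_validation --seed 1 --out out_cv/
veinadapt calibrate --hybrid-csv out_cv/run_00/trajectory.csv --out calib/
veinadapt make-fixtures --out fixtures/
```

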