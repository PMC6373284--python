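"""Experiment configuration, the hourly MM→TP→TR driver, and presets.

The driver realizes the time-split coupling: every simulated hour the
mechanical fields are refreshed if the lumen moved beyond tolerance, the
stochastic plasticity rules emit an event batch, and the immersed-boundary
relaxation reorganizes the tissue.  A run arrests when the stenosis
reaches the stop occlusion (50% by default) — the physiological flow-
control mechanism fails beyond that point — or at the horizon.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .dynamical_system import DSState, calibrate_gamma
from .geometry import (INTIMA, MEDIA, build_basic_geometry, occlusion_fraction,
                       seed_cells)
from .mechanics import (compute_fields, rescale_gf_amplitude,
                        should_update_mechanics, wall_potential_energy)
from .params import (DEFAULTS, DSParams, GAConfig, MechanicsParams,
                     PlasticityParams, RemodelingParams)
from .plasticity import step_plasticity
from .remodeling import StokesSolver, membrane_elastic_energy, relax_tissue
from .snapshots import agents_frame, write_snapshot

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "RunResult", "EnsembleResult",
           "run_simulation", "run_ensemble", "preset_experiments",
           "cross_validate", "intimal_nn_cv", "medial_angular_uniformity_p"]

_GEO = DEFAULTS["geometry"]
ALL_FORCES = ("random", "repulsion", "invasion", "chemotaxis")


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    name: str = "custom"
    r_lumen: float = _GEO["r_lumen"]
    r_iel: float = _GEO["r_iel"]
    r_outer: float = _GEO["r_outer"]
    h: float = _GEO["h"]
    r_smc: float = _GEO["r_smc"]
    r_ecm: float = _GEO["r_ecm"]
    smc_fraction: float = _GEO["smc_fraction"]
    horizon_hours: int = 240
    n_runs: int = 10
    shear_drop: float = 0.0
    force_growth: bool = False
    stop_occlusion: float = 0.5
    motility_forces: tuple = ALL_FORCES
    snapshot_hours: tuple = ()
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    ds: DSParams = field(default_factory=DSParams)
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.r_lumen < self.r_iel < self.r_outer):
            raise ValueError("radii must be strictly increasing")
        if self.h >= 2.0 * self.r_smc:
            raise ValueError("grid step must be smaller than an SMC diameter")
        if not (0.0 <= self.shear_drop < 1.0):
            raise ValueError("shear_drop in [0, 1)")
        if not (0.0 < self.stop_occlusion <= 1.0):
            raise ValueError("stop_occlusion in (0, 1]")
        unknown = set(self.motility_forces) - set(ALL_FORCES)
        if unknown:
            raise ValueError(f"unknown motility forces: {unknown}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key, typ in (("mechanics", MechanicsParams),
                         ("plasticity", PlasticityParams),
                         ("remodeling", RemodelingParams),
                         ("ds", DSParams), ("ga", GAConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in d[key].items()})
        for key in ("motility_forces", "snapshot_hours"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class RunResult:
    trajectory: pd.DataFrame
    section: object
    pop: object
    ecm: object
    seed: int
    arrested: bool
    status: str = "completed"


@dataclass
class EnsembleResult:
    mean: pd.DataFrame
    runs: list


def _default_snapshot_hours(horizon: int) -> tuple:
    hours = [0, 24] + list(range(168, horizon, 168)) + [horizon]
    return tuple(sorted(set(h for h in hours if h <= horizon)))


def run_simulation(config: ExperimentConfig, seed: int,
                   out_dir: str | None = None) -> RunResult:
    """One seeded hybrid run; returns the hourly diagnostics trajectory.

    A single root seed is split into named substreams (seeding, plasticity,
    motility) so toggling one force does not shift another module's draws.
    """
    ss = np.random.SeedSequence(seed)
    s_seed, s_plast, s_mot = ss.spawn(3)
    rng_seed = np.random.default_rng(s_seed)
    rng_plast = np.random.default_rng(s_plast)
    rng_mot = np.random.default_rng(s_mot)

    section = build_basic_geometry(
        config.r_lumen, config.r_iel, config.r_outer, h=config.h,
        membrane_stiffness=config.remodeling.membrane_stiffness)
    pop, ecm = seed_cells(section, config.smc_fraction, rng_seed,
                          r_smc=config.r_smc, r_ecm=config.r_ecm,
                          mitotic_cycle=config.plasticity.mitotic_cycle,
                          ecm_cycle=config.plasticity.ecm_cycle)

    # baselines from the basic solution, then apply the flow perturbation
    mech = replace(config.mechanics, tol=config.r_smc)
    fields = compute_fields(section, mech)
    wall = (section.region_mask == INTIMA) | (section.region_mask == MEDIA)
    tau_bar = float(np.mean(fields.tau_wall))
    sigma_bar = float(np.mean(fields.sigma[wall]))
    mech = replace(mech, tau_bar=tau_bar, sigma_bar=sigma_bar,
                   Q_target=config.mechanics.Q_target * (1.0 - config.shear_drop))
    fields = compute_fields(section, mech, force_growth=config.force_growth)

    solver = StokesSolver(section.grid, config.remodeling)
    toggles = frozenset(config.motility_forces)
    initial_lumen = section.lumen_area()

    snapshot_hours = set(config.snapshot_hours or
                         (_default_snapshot_hours(config.horizon_hours)
                          if out_dir else ()))
    outp = Path(out_dir) if out_dir else None
    if outp:
        outp.mkdir(parents=True, exist_ok=True)

    def diag_row(t):
        return {
            "t_h": t,
            "lumen_area": section.lumen_area(),
            "intimal_area": section.intimal_area(),
            "medial_area": section.medial_area(),
            "occlusion": occlusion_fraction(section, initial_lumen),
            "smc_intima": pop.count(INTIMA),
            "smc_media": pop.count(MEDIA),
            "elastic_energy": sum(membrane_elastic_energy(m)
                                  for m in section.membranes()),
            "wall_energy": wall_potential_energy(section, mech, fields.sigma),
        }

    rows = [diag_row(0)]
    event_rows: list[tuple] = []
    if outp and 0 in snapshot_hours:
        write_snapshot(str(outp / "snapshot_t0000.h5"), section, pop, ecm, 0,
                       fields)
    arrested = False
    status = "completed"
    try:
        for t in range(1, config.horizon_hours + 1):
            if should_update_mechanics(fields.lumen_snapshot,
                                       section.lumen_wall, mech):
                fields = compute_fields(section, mech,
                                        force_growth=config.force_growth)
            if config.force_growth:
                fields_now = fields
            else:
                # cheap amplitude tracking between full PDE updates
                fields_now = rescale_gf_amplitude(fields, section, mech)
            batch = step_plasticity(pop, ecm, fields_now, section, float(t),
                                    config.plasticity, rng_plast, sigma_bar)
            if outp:
                event_rows.extend((t, e.kind, e.location[0], e.location[1],
                                   e.agent_id) for e in batch)
            relax_tissue(section, pop, ecm, batch, fields_now, mech,
                         config.remodeling, rng_mot, solver=solver,
                         motility_toggles=toggles)
            rows.append(diag_row(t))
            if outp and t in snapshot_hours:
                write_snapshot(str(outp / f"snapshot_t{t:04d}.h5"),
                               section, pop, ecm, t, fields)
            if rows[-1]["occlusion"] >= config.stop_occlusion:
                arrested = True
                break
    except Exception as exc:   # partial outputs still flushed below
        status = f"failed at t={len(rows)}: {exc}"
        logger.exception("run failed; flushing partial outputs")
        if outp is None:
            raise

    traj = pd.DataFrame(rows)
    if outp:
        traj.to_csv(outp / "trajectory.csv", index=False)
        agents_frame(pop).to_csv(outp / "agents_final.csv", index=False)
        pd.DataFrame(event_rows, columns=["t", "kind", "x", "y", "agent_id"]
                     ).to_csv(outp / "events.csv", index=False)
        pd.DataFrame({"x": section.lumen_wall.points[:, 0],
                      "y": section.lumen_wall.points[:, 1],
                      "tau_wall": fields.tau_wall}
                     ).to_csv(outp / "tau_wall.csv", index=False)
        manifest = {"config": json.loads(json.dumps(self_dict(config))),
                    "seed": int(seed), "status": status,
                    "arrested": bool(arrested),
                    "versions": {"veinadapt": _version,
                                 "numpy": np.__version__}}
        (outp / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(trajectory=traj, section=section, pop=pop, ecm=ecm,
                     seed=seed, arrested=arrested, status=status)


def self_dict(config: ExperimentConfig) -> dict:
    return config.to_dict()


def _normalize(traj: pd.DataFrame) -> pd.DataFrame:
    out = traj.copy()
    for col in ("lumen_area", "intimal_area", "medial_area"):
        out[col + "_norm"] = out[col] / out[col].iloc[0]
    return out


def run_ensemble(config: ExperimentConfig, N: int, base_seed: int,
                 out_dir: str | None = None) -> EnsembleResult:
    """N independent seeded runs; per-hour mean and SD of normalized areas."""
    if N < 1:
        raise ValueError("N must be >= 1")
    runs = []
    for i in range(N):
        rd = (str(Path(out_dir) / f"run_{i:02d}") if out_dir else None)
        res = run_simulation(config, seed=base_seed + i, out_dir=rd)
        if res.status != "completed":
            logger.warning("run %d did not complete: %s", i, res.status)
        runs.append(res)
    ok = [r for r in runs if r.status == "completed"]
    if not ok:
        raise RuntimeError("no run completed")
    if len(ok) < len(runs):
        logger.warning("averaging over %d/%d completed runs", len(ok), len(runs))
    n_hours = min(len(r.trajectory) for r in ok)
    cols = ["lumen_area_norm", "intimal_area_norm", "medial_area_norm"]
    normed = [_normalize(r.trajectory).iloc[:n_hours] for r in ok]
    mean = normed[0][["t_h"]].copy()
    for c in cols:
        stack = np.column_stack([d[c].to_numpy() for d in normed])
        mean[c.replace("_norm", "_mean")] = stack.mean(axis=1)
        mean[c.replace("_norm", "_sd")] = stack.std(axis=1, ddof=0)
    # absolute means too (for calibration targets)
    for c in ("lumen_area", "intimal_area", "medial_area"):
        stack = np.column_stack([d[c].to_numpy() for d in normed])
        mean[c] = stack.mean(axis=1)
    if out_dir:
        mean.to_csv(Path(out_dir) / "ensemble_mean.csv", index=False)
    return EnsembleResult(mean=mean, runs=runs)


def intimal_nn_cv(pop) -> float:
    """Coefficient of variation of nearest-neighbor distances among intimal
    SMCs — the quantitative stand-in for the visual uniformity comparison
    (lower CV = more uniform distribution)."""
    from scipy.spatial import cKDTree
    pts = pop.pos[pop.layer == INTIMA]
    if len(pts) < 3:
        return float("nan")
    d, _ = cKDTree(pts).query(pts, k=2)
    nn = d[:, 1]
    return float(nn.std() / nn.mean())


def medial_angular_uniformity_p(pop, n_bins: int = 8) -> float:
    """Chi-square p-value for uniformity of medial SMC angular positions."""
    from scipy.stats import chisquare
    pts = pop.pos[pop.layer == MEDIA]
    if len(pts) < n_bins:
        return float("nan")
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    counts, _ = np.histogram(theta, bins=n_bins, range=(-np.pi, np.pi))
    return float(chisquare(counts).pvalue)


def preset_experiments(name: str) -> ExperimentConfig:
    """The four experiment presets (early hyperplasia in its b/c/d variants)."""
    # presets run the relaxation in 5 substeps (4 for the long-horizon
    # cross-validation), a resolution at which trajectory statistics are
    # converged to well within the run-to-run stochastic spread
    five = dict(remodeling=RemodelingParams(substeps=5))
    presets = {
        "basic_solution": dict(
            name="basic_solution", horizon_hours=240, n_runs=10,
            shear_drop=0.0, h=0.0075, **five),
        "early_hyperplasia": dict(
            name="early_hyperplasia", horizon_hours=24, n_runs=10,
            shear_drop=0.5, h=0.0075,
            motility_forces=("random", "repulsion", "invasion"), **five),
        "early_hyperplasia_b": dict(
            name="early_hyperplasia_b", horizon_hours=24, n_runs=10,
            shear_drop=0.5, h=0.0075, motility_forces=("random",), **five),
        "early_hyperplasia_c": dict(
            name="early_hyperplasia_c", horizon_hours=24, n_runs=10,
            shear_drop=0.5, h=0.0075,
            motility_forces=("random", "repulsion"), **five),
        "early_hyperplasia_d": dict(
            name="early_hyperplasia_d", horizon_hours=24, n_runs=10,
            shear_drop=0.5, h=0.0075,
            motility_forces=("random", "repulsion", "invasion"), **five),
        "late_hyperplasia": dict(
            name="late_hyperplasia", horizon_hours=720, n_runs=10,
            shear_drop=0.5, h=0.0075, **five),
        "cross_validation": dict(
            name="cross_validation", horizon_hours=2880, n_runs=10,
            shear_drop=0.5, h=0.0075,
            remodeling=RemodelingParams(substeps=4)),
    }
    if name not in presets:
        raise KeyError(f"unknown preset '{name}'; choose from {sorted(presets)}")
    return ExperimentConfig(**presets[name])


def cross_validate(config: ExperimentConfig, base_seed: int,
                   out_dir: str | None = None) -> dict:
    """Hybrid ensemble + GA calibration of the reduced system.

    Returns gamma*, the max percent relative error on the lumen-area
    trajectory, and the ensemble size actually used.
    """
    ens = run_ensemble(config, config.n_runs, base_seed, out_dir=out_dir)
    daily = ens.mean[ens.mean["t_h"] % 24 == 0]
    target = daily["lumen_area"].to_numpy()
    ds_initial = DSState(config.r_outer, config.r_iel, config.r_lumen)
    ds_params = replace(config.ds, shear_drop=config.shear_drop,
                        T=config.plasticity.T, deltaT=config.plasticity.deltaT)
    gamma, err = calibrate_gamma(
        ds_initial, target, ga_config=config.ga, ds_params=ds_params,
        seed=base_seed,
        history_out=(str(Path(out_dir) / "ga_history.csv") if out_dir else None))
    result = {"gamma_star": gamma, "max_percent_relative_error": err,
              "n_runs": len(ens.runs), "horizon_days": len(target) - 1}
    if out_dir:
        (Path(out_dir) / "calibration.json").write_text(
            json.dumps(result, indent=2))
    return result
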