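"""Reduced zero-dimensional counterpart of the hybrid model.

The hybrid simulator resolves individual cells on a 2D cross section; this
module keeps only the radii triple (outer wall R, internal elastic lamina
re, lumen r) and evolves the intimal area with the mean-field limit of the
agent rules:

    dA_I/dt = turnover * A(t) * gamma * (Δτ/τ̄) * A_I

where A_I is the *cellular* intimal compartment (division is performed by
cells, so the drift is proportional to the SMC-occupied area — initially
``smc_fraction`` of the geometric intima — not to the whole intimal area),
the shear deficit Δτ/τ̄ is recomputed every step from the Poiseuille wall
shear at the current lumen radius under constant (possibly dropped) flow,
and A(t) is the macrophage activity envelope shared with the hybrid model.
Growth is accommodated inward (the IEL stays put, so lumen area is lost
one-for-one), matching the energy-selected inward remodeling of the full
model.  Cross-validation calibrates the single gain ``gamma`` (the
counterpart of the division gain alpha5) against the hybrid model's mean
lumen-area trajectory with a seeded genetic algorithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import DSParams, GAConfig

logger = logging.getLogger(__name__)

__all__ = ["DSState", "ds_simulate", "calibrate_gamma", "trajectory_error"]


@dataclass
class DSState:
    """Radii triple of the reduced model, mm."""

    R_outer: float
    re_iel: float
    r_lumen: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_lumen < self.re_iel < self.R_outer):
            raise ValueError("radii must satisfy 0 < r_lumen < re_iel < R_outer")


def _mean_activity(day: float, params: DSParams) -> float:
    """Daily mean of the (clamped) macrophage envelope over [day, day+1)."""
    if not params.use_envelope:
        return 1.0
    t0, t1 = day * 24.0, (day + 1) * 24.0
    dT = params.deltaT
    # analytic mean of min(1, exp(-(t-T)/dT)) over [t0, t1]
    if t1 <= params.T:
        return 1.0
    ta = max(t0, params.T)
    flat = ta - t0
    decay = dT * (math.exp(-(ta - params.T) / dT) - math.exp(-(t1 - params.T) / dT))
    return (flat + decay) / (t1 - t0)


def ds_simulate(initial: DSState, params: DSParams, horizon: int
                ) -> pd.DataFrame:
    """Integrate the reduced system with explicit daily steps.

    Returns a frame with one row per day (day 0 = initial state) and
    columns lumen_area, intimal_area, medial_area (mm^2) plus the arrest
    flag ``collapsed``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive (days)")
    r0 = initial.r_lumen
    A_lum = math.pi * initial.r_lumen ** 2
    A_int = math.pi * (initial.re_iel ** 2 - initial.r_lumen ** 2)
    A_med = math.pi * (initial.R_outer ** 2 - initial.re_iel ** 2)
    A_cell = params.smc_fraction * A_int     # SMC-occupied intimal area
    rows = [(0, A_lum, A_int, A_med, False)]
    collapsed = False
    for day in range(horizon):
        r = math.sqrt(A_lum / math.pi)
        # Poiseuille: tau/tau_bar = (1 - shear_drop) * (r0/r)^3 at constant flow
        deficit = max(0.0, 1.0 - (1.0 - params.shear_drop) * (r0 / r) ** 3)
        growth = (params.turnover * _mean_activity(day, params)
                  * params.gamma * deficit * A_cell)
        A_cell += growth
        A_int += growth
        A_lum -= growth
        if A_lum <= 0.0:
            collapsed = True
            A_lum = 0.0
            rows.append((day + 1, A_lum, A_int, A_med, True))
            break
        rows.append((day + 1, A_lum, A_int, A_med, False))
    df = pd.DataFrame(rows, columns=["day", "lumen_area", "intimal_area",
                                     "medial_area", "collapsed"])
    df.attrs["collapsed"] = collapsed
    return df


def trajectory_error(ds_lumen: np.ndarray, target_lumen: np.ndarray) -> float:
    """Maximum pointwise percent relative error between two trajectories."""
    n = min(len(ds_lumen), len(target_lumen))
    a = np.asarray(ds_lumen[:n], dtype=float)
    b = np.asarray(target_lumen[:n], dtype=float)
    return float(np.max(np.abs(a - b) / np.abs(b)) * 100.0)


def _objective(gamma: float, initial: DSState, params: DSParams,
               target_norm: np.ndarray) -> float:
    """L2 distance between normalized daily lumen-area trajectories."""
    p = replace(params, gamma=float(gamma))
    df = ds_simulate(initial, p, horizon=len(target_norm) - 1)
    lum = df["lumen_area"].to_numpy()
    lum = lum / lum[0]
    n = min(len(lum), len(target_norm))
    return float(np.sqrt(np.mean((lum[:n] - target_norm[:n]) ** 2)))


def calibrate_gamma(ds_initial: DSState, hybrid_mean_trajectory: np.ndarray,
                    ga_config: GAConfig | None = None,
                    ds_params: DSParams | None = None,
                    seed: int = 0,
                    history_out: str | None = None
                    ) -> tuple[float, float]:
    """Genetic-algorithm calibration of the intimal growth gain.

    ``hybrid_mean_trajectory`` is the daily lumen-area trajectory of the
    hybrid model's ensemble mean (absolute or normalized; it is normalized
    to its first sample internally).  Returns ``(gamma_star,
    max_percent_relative_error)`` of the calibrated reduced model against
    the target.  Real-coded GA: tournament selection, blend crossover,
    Gaussian mutation, fully seeded.
    """
    ga = ga_config or GAConfig()
    params = ds_params or DSParams()
    target = np.asarray(hybrid_mean_trajectory, dtype=float)
    if target.ndim != 1 or len(target) < 2:
        raise ValueError("hybrid trajectory must be a 1D array of daily samples")
    target_norm = target / target[0]
    rng = np.random.default_rng(seed)

    pop = rng.random(ga.population) * ga.gamma_max
    fit = np.array([_objective(g, ds_initial, params, target_norm) for g in pop])
    best_g, best_f = float(pop[np.argmin(fit)]), float(fit.min())
    stall = 0
    history = []
    for gen in range(ga.generations):
        children = np.empty(ga.population)
        for k in range(ga.population):
            # tournament selection of two parents
            def pick():
                idx = rng.integers(0, ga.population, size=ga.tournament)
                return pop[idx[np.argmin(fit[idx])]]
            p1, p2 = pick(), pick()
            if rng.random() < ga.crossover_rate:
                w = rng.random()
                child = w * p1 + (1.0 - w) * p2
            else:
                child = p1
            if rng.random() < ga.mutation_rate:
                child += rng.normal(0.0, ga.mutation_sigma * ga.gamma_max
                                    * (0.5 ** (gen / max(ga.generations / 4, 1))))
            children[k] = min(max(child, 0.0), ga.gamma_max)
        child_fit = np.array([_objective(g, ds_initial, params, target_norm)
                              for g in children])
        # elitism: keep the best-so-far individual alive
        worst = int(np.argmax(child_fit))
        children[worst], child_fit[worst] = best_g, best_f
        pop, fit = children, child_fit
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_f - 1e-15:
            best_f, best_g = float(fit[gen_best]), float(pop[gen_best])
            stall = 0
        else:
            stall += 1
        history.append((gen, best_g, best_f))
        if stall >= ga.patience:
            logger.warning("GA stalled for %d generations; returning best-so-far",
                           stall)
            break

    if history_out is not None:
        pd.DataFrame(history, columns=["generation", "best_gamma", "objective"]
                     ).to_csv(history_out, index=False)

    p_best = replace(params, gamma=best_g)
    df = ds_simulate(ds_initial, p_best, horizon=len(target_norm) - 1)
    lum = df["lumen_area"].to_numpy()
    err = trajectory_error(lum / lum[0], target_norm)
    return best_g, err
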