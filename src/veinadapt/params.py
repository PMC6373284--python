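"""Parameter containers for the vein-graft adaptation model.

All tunable constants live in ``data/defaults.yaml``; the dataclasses here
are thin, validated views of that file.  Every parameter object can be
overridden field-by-field through :func:`load_params` or the experiment
configuration layer.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

__all__ = [
    "DEFAULTS",
    "MechanicsParams",
    "PlasticityParams",
    "RemodelingParams",
    "DSParams",
    "GAConfig",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set violates a model constraint."""


def _load_defaults() -> dict:
    ref = importlib.resources.files("veinadapt.data").joinpath("defaults.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


DEFAULTS = _load_defaults()
_P = DEFAULTS["plasticity"]
_M = DEFAULTS["mechanics"]
_R = DEFAULTS["remodeling"]
_D = DEFAULTS["dynamical_system"]
_G = DEFAULTS["geometry"]


@dataclass
class MechanicsParams:
    """Constants of the mechanical model (flow, wall stress, GF diffusion)."""

    mu: float = _M["mu"]                    # blood viscosity, Pa s
    Q_target: float = _M["Q_target"]        # flow rate, mm^3/s
    c: float = _M["c"]                      # GF diffusion coefficient, mm^2/h
    p_internal: float = _M["p_internal"]    # Pa
    p_external: float = _M["p_external"]    # Pa
    E: float = _M["E"]                      # Young modulus, Pa
    nu: float = _M["nu"]                    # Poisson ratio
    penalty: float = _M["penalty"]          # Angot penalty eta
    tol: float = _G["r_smc"]                # mechanics-update tolerance, mm
    tau_bar: float = 1.0                    # baseline wall shear, Pa (set from basic solution)
    sigma_bar: float = 1.0                  # baseline strain energy density, Pa

    def __post_init__(self) -> None:
        for name in ("mu", "c", "penalty", "tol", "E"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"MechanicsParams.{name} must be positive")
        if self.Q_target < 0:
            raise ConfigurationError("Q_target must be nonnegative")


@dataclass
class PlasticityParams:
    """Rate coefficients of the stochastic SMC/ECM event rules."""

    alpha1: float = _P["alpha1"]
    alpha2: float = _P["alpha2"]
    alpha3: float = _P["alpha3"]   # T, h
    alpha4: float = _P["alpha4"]   # deltaT, h
    alpha5: float = _P["alpha5"]
    alpha6: float = _P["alpha6"]
    alpha7: float = _P["alpha7"]
    alpha8: float = _P["alpha8"]
    mitotic_cycle: float = _P["mitotic_cycle"]
    ecm_cycle: float = _P["ecm_cycle"]
    step: float = _P["step"]
    allow_pre_peak_growth: bool = _P["allow_pre_peak_growth"]
    division_layers: tuple = tuple(_P["division_layers"])
    apoptosis_layers: tuple = tuple(_P["apoptosis_layers"])
    ecm_layers: tuple = tuple(_P["ecm_layers"])

    # time of max macrophage activity / relaxation time aliases
    @property
    def T(self) -> float:
        return self.alpha3

    @property
    def deltaT(self) -> float:
        return self.alpha4

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 <= 1.0 and 0.0 <= self.alpha2 <= 1.0):
            raise ConfigurationError("alpha1, alpha2 must lie in [0, 1]")
        if self.alpha4 <= 0:
            raise ConfigurationError("deltaT (alpha4) must be positive")
        for name in ("alpha5", "alpha6", "alpha7", "alpha8"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for cyc in (self.mitotic_cycle, self.ecm_cycle):
            if abs(cyc / self.step - round(cyc / self.step)) > 1e-12:
                raise ConfigurationError("step must divide the mitotic and ECM cycles")
        if 2.0 * self.alpha2 * (1.0 + self.alpha6) > 1.0 + 1e-12:
            raise ConfigurationError("ECM event probabilities exceed 1: alphas too large")


@dataclass
class RemodelingParams:
    """Constants of the immersed-boundary relaxation and SMC motility."""

    delta_t: float = _R["delta_t"]          # relaxation duration per hourly cycle
    substeps: int = _R["substeps"]
    rho: float = _R["rho"]
    mu_tissue: float = _R["mu_tissue"]
    n_s: int = _R["n_s"]                    # repulsion range, cell diameters
    n_e: int = _R["n_e"]                    # invasion range, cell diameters
    k_S: float = _R["k_S"]
    k_E: float = _R["k_E"]
    k_G: float = _R["k_G"]
    random_motility: float = _R["random_motility"]
    membrane_stiffness: float = _R["membrane_stiffness"]
    adjust_magnitude: float = _R["adjust_magnitude"]
    plastic_rate: float = _R["plastic_rate"]
    lennard_jones_repulsion: bool = _R["lennard_jones_repulsion"]

    @property
    def dt_ibm(self) -> float:
        return self.delta_t / self.substeps

    def __post_init__(self) -> None:
        if self.delta_t <= 0 or self.substeps < 1:
            raise ConfigurationError("delta_t must be positive, substeps >= 1")
        if self.n_s < 1 or self.n_e < 1:
            raise ConfigurationError("n_s and n_e must be small positive integers")
        if self.mu_tissue <= 0 or self.rho <= 0:
            raise ConfigurationError("rho and mu_tissue must be positive")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the gamma calibration."""

    population: int = 40
    generations: int = 100
    tournament: int = 3
    mutation_sigma: float = 0.3   # relative to the search width
    crossover_rate: float = 0.7
    mutation_rate: float = 0.4
    gamma_max: float = 20.0
    patience: int = 30


@dataclass
class DSParams:
    """Parameters of the reduced zero-dimensional dynamical system."""

    gamma: float = _D["gamma"]          # intimal growth gain (alpha5)
    shear_drop: float = _D["shear_drop"]
    turnover: float = _D["turnover"]    # 1/day, cellular-compartment turnover
    smc_fraction: float = _D["smc_fraction"]
    tau_setpoint: float = 1.0           # baseline shear (normalized internally)
    T: float = _P["alpha3"]             # macrophage envelope shared with the hybrid
    deltaT: float = _P["alpha4"]
    use_envelope: bool = True

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ConfigurationError("gamma must be nonnegative")
        if not (0.0 <= self.shear_drop < 1.0):
            raise ConfigurationError("shear_drop must lie in [0, 1)")


def load_params(overrides: dict | None = None):
    """Build (MechanicsParams, PlasticityParams, RemodelingParams, DSParams)
    from the shipped defaults, optionally overriding individual fields.

    ``overrides`` mirrors the YAML structure, e.g.
    ``{"plasticity": {"alpha1": 0.1}}``.
    """
    overrides = overrides or {}
    mech = MechanicsParams(**overrides.get("mechanics", {}))
    plas = PlasticityParams(**overrides.get("plasticity", {}))
    remo = RemodelingParams(**overrides.get("remodeling", {}))
    ds = DSParams(**overrides.get("dynamical_system", {}))
    return mech, plas, remo, ds
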