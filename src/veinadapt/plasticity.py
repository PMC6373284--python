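"""Stochastic tissue plasticity: the hourly agent-based event rules.

Each SMC carries a 12 h mitotic clock and a 2 h ECM-synthesis clock.  Every
hour each agent is interrogated; agents whose clock completes draw a
division-vs-apoptosis (or ECM production-vs-degradation) outcome from the
probability laws, all modulated by the macrophage activity envelope A(t)
and by the local growth-factor and strain-energy deviations from the
basic-solution baselines.  Medial agents adjacent to the internal elastic
lamina may additionally draw a migration event into the intima wherever
the membrane stress admits passage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (INTIMA, MEDIA, AgentPopulation, ECMField,
                       VesselCrossSection)
from .mechanics import FieldSet
from .params import ConfigurationError, PlasticityParams

__all__ = [
    "MITOSIS", "APOPTOSIS", "ECM_PRODUCTION", "ECM_DEGRADATION", "MIGRATION",
    "Event", "EventBatch", "EventProbabilities",
    "macrophage_activity", "event_probabilities", "step_plasticity",
]

MITOSIS = "mitosis"
APOPTOSIS = "apoptosis"
ECM_PRODUCTION = "ecm_production"
ECM_DEGRADATION = "ecm_degradation"
MIGRATION = "migration"


@dataclass
class Event:
    kind: str
    location: tuple[float, float]
    agent_id: int | None = None
    cell_index: tuple[int, int] | None = None   # (row, col) for ECM events


@dataclass
class EventBatch:
    """Per-step list of cellular events; the mass sources/sinks of the IBM."""

    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    def net_smc_area(self, r_smc: float) -> float:
        """Net SMC disc area added by this batch, mm^2."""
        return (self.count(MITOSIS) - self.count(APOPTOSIS)) * math.pi * r_smc ** 2

    def net_ecm_area(self, r_ecm: float) -> float:
        return (self.count(ECM_PRODUCTION) - self.count(ECM_DEGRADATION)) * math.pi * r_ecm ** 2


@dataclass
class EventProbabilities:
    division: float
    apoptosis: float
    ecm_production: float
    ecm_degradation: float
    migration: float


def macrophage_activity(t: float, params: PlasticityParams) -> float:
    """Macrophage activity envelope A(t) = exp(-(t - T)/deltaT).

    The printed exponential exceeds 1 before the peak time T; unless
    ``allow_pre_peak_growth`` is set it is clamped at 1 so that A truly
    peaks at the time of maximum macrophage activity.
    """
    a = math.exp(-(t - params.T) / params.deltaT)
    if not params.allow_pre_peak_growth:
        a = min(a, 1.0)
    return a


def _clip01(p: float) -> float:
    return min(max(p, 0.0), 1.0)


def probabilities_from_locals(G_norm: float, dsigma_rel: float, layer: int,
                              t: float, params: PlasticityParams
                              ) -> EventProbabilities:
    """Table of event probabilities from the local normalized fields.

    ``G_norm`` is the growth factor driven by the shear deficit (already
    normalized by the baseline shear), ``dsigma_rel`` is (sigma - sigma_bar)
    / sigma_bar.  The growth-factor gains act where the biology puts them:
    G boosts division in the intima and migration out of the media.
    """
    A = macrophage_activity(t, params)
    gain_div = params.alpha5 * G_norm if layer == INTIMA else 0.0
    p_div = _clip01(params.alpha1 * A * (1.0 + gain_div))
    p_apo = _clip01(params.alpha1 * A)
    p_pro = _clip01(params.alpha2 * A * (1.0 + params.alpha6 * dsigma_rel))
    p_deg = _clip01(params.alpha2 * A)
    gain_mig = params.alpha8 * G_norm if layer == MEDIA else 0.0
    p_mig = _clip01(params.alpha7 * A * (1.0 + gain_mig))
    if p_pro + p_deg > 1.0 + 1e-12:
        raise ConfigurationError("ECM production + degradation probabilities exceed 1")
    return EventProbabilities(p_div, p_apo, p_pro, p_deg, p_mig)


def event_probabilities(agent, fields: FieldSet, grid, t: float,
                        params: PlasticityParams, sigma_bar: float
                        ) -> EventProbabilities:
    """Per-event probabilities for one agent, sampling the fields at its position."""
    pos = np.asarray(agent.position, dtype=float)
    Gn = float(fields.sample_G(grid, pos)[0])
    sig = float(fields.sample_sigma(grid, pos)[0])
    dsig = (sig - sigma_bar) / sigma_bar if sigma_bar > 0 else 0.0
    return probabilities_from_locals(Gn, dsig, int(agent.layer), t, params)


def step_plasticity(pop: AgentPopulation, ecm: ECMField, fields: FieldSet,
                    section: VesselCrossSection, t: float,
                    params: PlasticityParams, rng: np.random.Generator,
                    sigma_bar: float) -> EventBatch:
    """One hourly interrogation of every agent; returns the event batch.

    Clocks advance by the step; completing clocks trigger a mutually
    exclusive draw (divide / die / nothing, produce / degrade / nothing).
    Each agent contributes at most one event per step, with cell-fate
    events taking precedence over ECM events, and ECM over migration.
    Agent order is randomized from the seeded stream, so the batch sequence
    is reproducible for a fixed seed and configuration.
    """
    batch = EventBatch()
    n = len(pop)
    if n == 0:
        return batch
    g = section.grid

    pop.mitosis_clock += params.step
    pop.ecm_clock += params.step
    mit_done = pop.mitosis_clock >= params.mitotic_cycle
    ecm_done = pop.ecm_clock >= params.ecm_cycle
    pop.mitosis_clock[mit_done] -= params.mitotic_cycle
    pop.ecm_clock[ecm_done] -= params.ecm_cycle

    Gn = fields.sample_G(g, pop.pos)
    dsig = ((fields.sample_sigma(g, pop.pos) - sigma_bar) / sigma_bar
            if sigma_bar > 0 else np.zeros(n))

    division_layers = {INTIMA if s == "intima" else MEDIA for s in params.division_layers}
    apoptosis_layers = {INTIMA if s == "intima" else MEDIA for s in params.apoptosis_layers}
    ecm_layers = {INTIMA if s == "intima" else MEDIA for s in params.ecm_layers}

    # eligibility for migration: medial agents adjacent to the IEL
    iel_pts = section.iel.points
    near_iel = np.zeros(n, dtype=bool)
    medial = pop.layer == MEDIA
    if medial.any():
        from scipy.spatial import cKDTree
        d, nearest = cKDTree(iel_pts).query(pop.pos[medial])
        near_iel[np.nonzero(medial)[0]] = d <= 2.0 * pop.radius
        nearest_idx = np.full(n, -1)
        nearest_idx[np.nonzero(medial)[0]] = nearest
    else:
        nearest_idx = np.full(n, -1)

    # membrane tension magnitude per IEL point (for porosity gating)
    seg = section.iel.segment_lengths()
    tension = section.iel.stiffness * np.abs(seg - section.iel.rest_lengths) \
        / np.maximum(section.iel.rest_lengths, 1e-30)
    pt_tension = 0.5 * (tension + np.roll(tension, 1))   # segments meeting at point

    order = rng.permutation(n)
    for i in order:
        layer = int(pop.layer[i])
        probs = probabilities_from_locals(float(Gn[i]), float(dsig[i]),
                                          layer, t, params)
        pos = (float(pop.pos[i, 0]), float(pop.pos[i, 1]))
        aid = int(pop.ids[i])
        claimed = False
        if mit_done[i] and (layer in division_layers or layer in apoptosis_layers):
            p_div = probs.division if layer in division_layers else 0.0
            p_apo = probs.apoptosis if layer in apoptosis_layers else 0.0
            if p_div + p_apo > 1.0 + 1e-12:
                raise ConfigurationError(
                    "division + apoptosis probabilities exceed 1 (alphas too large)")
            u = rng.random()
            if u < p_div:
                batch.events.append(Event(MITOSIS, pos, agent_id=aid))
                claimed = True
            elif u < p_div + p_apo:
                batch.events.append(Event(APOPTOSIS, pos, agent_id=aid))
                claimed = True
        if not claimed and ecm_done[i] and layer in ecm_layers:
            u = rng.random()
            ci = _cell_index(g, pop.pos[i])
            if u < probs.ecm_production:
                batch.events.append(Event(ECM_PRODUCTION, pos, agent_id=aid,
                                          cell_index=ci))
                claimed = True
            elif u < probs.ecm_production + probs.ecm_degradation:
                batch.events.append(Event(ECM_DEGRADATION, pos, agent_id=aid,
                                          cell_index=ci))
                claimed = True
        if not claimed and layer == MEDIA and near_iel[i]:
            if pt_tension[nearest_idx[i]] >= section.iel.porosity_threshold:
                if rng.random() < probs.migration:
                    batch.events.append(Event(MIGRATION, pos, agent_id=aid))
    return batch


def _cell_index(grid, pos: np.ndarray) -> tuple[int, int]:
    i = int(np.clip(round((pos[0] - grid.origin[0]) / grid.h), 0, grid.nx - 1))
    j = int(np.clip(round((pos[1] - grid.origin[1]) / grid.h), 0, grid.ny - 1))
    return (j, i)
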