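"""Stochastic event rules: activity envelope, probability laws, hourly step."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veinadapt.geometry import INTIMA, MEDIA, CellAgent, build_basic_geometry, seed_cells
from veinadapt.mechanics import FieldSet
from veinadapt.params import ConfigurationError, PlasticityParams
from veinadapt.plasticity import (APOPTOSIS, MITOSIS, EventBatch,
                                  macrophage_activity,
                                  probabilities_from_locals, step_plasticity)


@pytest.fixture(scope="module")
def small_world():
    sec = build_basic_geometry(0.24, 0.28, 0.30, h=0.0075,
                               membrane_stiffness=0.02)
    pop, ecm = seed_cells(sec, 0.25, rng_seed=3)
    return sec, pop, ecm


def make_fields(section, G=0.0, sigma=1.0):
    shape = section.region_mask.shape
    return FieldSet(axial_velocity=np.zeros(shape),
                    tau_wall=np.zeros(len(section.lumen_wall.points)),
                    sigma=np.full(shape, sigma),
                    G=np.full(shape, G),
                    lumen_snapshot=section.lumen_wall.copy())


class TestMacrophageActivity:
    def test_peak_value_is_one(self):
        p = PlasticityParams()
        assert macrophage_activity(p.T, p) == pytest.approx(1.0)

    def test_one_relaxation_time_after_peak(self):
        p = PlasticityParams()
        assert macrophage_activity(p.T + p.deltaT, p) == pytest.approx(
            math.exp(-1.0), rel=1e-12)

    def test_monotone_decay_after_peak(self):
        p = PlasticityParams()
        ts = p.T + np.linspace(0, 10 * p.deltaT, 50)
        vals = [macrophage_activity(t, p) for t in ts]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-4

    def test_pre_peak_clamped_unless_flagged(self):
        p = PlasticityParams()
        assert macrophage_activity(0.0, p) == 1.0
        p2 = PlasticityParams(allow_pre_peak_growth=True)
        assert macrophage_activity(0.0, p2) == pytest.approx(
            math.exp(p2.T / p2.deltaT))


class TestEventProbabilities:
    def test_basic_solution_balance(self):
        # G = 0 and sigma = sigma_bar at the activity peak: Table-2 balance
        p = PlasticityParams()
        probs = probabilities_from_locals(0.0, 0.0, INTIMA, p.T, p)
        assert probs.division == pytest.approx(p.alpha1)
        assert probs.apoptosis == pytest.approx(p.alpha1)
        assert probs.ecm_production == pytest.approx(p.alpha2)
        assert probs.ecm_degradation == pytest.approx(p.alpha2)

    def test_unit_gain_doubles_division(self):
        p = PlasticityParams()
        G = 1.0 / p.alpha5          # alpha5 * G = 1
        probs = probabilities_from_locals(G, 0.0, INTIMA, p.T, p)
        assert probs.division == pytest.approx(2.0 * p.alpha1)

    def test_all_alphas_zero_all_probabilities_zero(self):
        p = PlasticityParams(alpha1=0, alpha2=0, alpha5=0, alpha6=0,
                             alpha7=0, alpha8=0)
        probs = probabilities_from_locals(0.7, 0.3, INTIMA, 100.0, p)
        assert (probs.division == probs.apoptosis == probs.ecm_production
                == probs.ecm_degradation == probs.migration == 0.0)

    def test_division_gain_intima_only(self):
        p = PlasticityParams()
        intima = probabilities_from_locals(0.5, 0.0, INTIMA, p.T, p)
        media = probabilities_from_locals(0.5, 0.0, MEDIA, p.T, p)
        assert intima.division > media.division
        assert media.migration > intima.migration

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(G=st.floats(0, 5), dsig=st.floats(-3, 3),
           t=st.floats(0, 5000), layer=st.sampled_from([INTIMA, MEDIA]))
    def test_probabilities_always_in_unit_interval(self, G, dsig, t, layer):
        p = PlasticityParams(alpha5=1.0, alpha6=1.0)  # large gains still clip
        probs = probabilities_from_locals(G, dsig, layer, t, p)
        for v in (probs.division, probs.apoptosis, probs.ecm_production,
                  probs.ecm_degradation, probs.migration):
            assert 0.0 <= v <= 1.0

    def test_division_monotone_in_G(self):
        p = PlasticityParams()
        vals = [probabilities_from_locals(g, 0.0, INTIMA, p.T, p).division
                for g in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_oversized_alphas_rejected(self):
        with pytest.raises(ConfigurationError):
            PlasticityParams(alpha2=0.4, alpha6=0.5)   # ECM draws exceed 1

    def test_oversized_fate_probabilities_raise_at_draw(self, small_world):
        sec, pop0, ecm = small_world
        p = PlasticityParams(alpha1=0.45, alpha5=4.6)   # p_div + p_apo > 1 at high G
        fields = make_fields(sec, G=1.0)
        with pytest.raises(ConfigurationError):
            for t in range(12):
                step_plasticity(pop0.copy(), ecm, fields, sec, float(t), p,
                                np.random.default_rng(0), 1.0)


class TestStepPlasticity:
    def test_forced_division_when_certain(self, small_world):
        # degenerate Bernoulli: alpha1 = 1 with apoptosis disabled
        sec, pop0, ecm = small_world
        pop = pop0.copy()
        p = PlasticityParams(alpha1=1.0, alpha2=0.0, alpha5=0.0, alpha7=0.0,
                             apoptosis_layers=())
        fields = make_fields(sec, G=0.0)
        rng = np.random.default_rng(0)
        completing = int(np.sum((pop.mitosis_clock + 1 >= 12)
                                & (pop.layer == INTIMA)))
        batch = step_plasticity(pop, ecm, fields, sec, p.T, p, rng, 1.0)
        assert batch.count(MITOSIS) == completing
        assert batch.count(APOPTOSIS) == 0

    def test_expected_division_count_binomial(self, small_world):
        sec, pop0, ecm = small_world
        p = PlasticityParams(alpha1=0.2, alpha2=0.0, alpha5=0.0, alpha7=0.0)
        fields = make_fields(sec, G=0.0)
        total, M = 0, 0
        for s in range(30):
            pop = pop0.copy()
            rng = np.random.default_rng(s)
            M += int(np.sum((pop.mitosis_clock + 1 >= 12)
                            & (pop.layer == INTIMA)))
            batch = step_plasticity(pop, ecm, fields, sec, p.T, p, rng, 1.0)
            total += batch.count(MITOSIS)
        exp = M * p.alpha1
        sd = math.sqrt(M * p.alpha1 * (1 - p.alpha1))
        assert abs(total - exp) <= 3.0 * sd

    def test_division_apoptosis_exchangeable_at_baseline(self, small_world):
        # basic solution: over many agent-cycles, the division/apoptosis
        # difference stays within 4 binomial standard deviations
        sec, pop0, ecm = small_world
        p = PlasticityParams(alpha2=0.0, alpha7=0.0)
        fields = make_fields(sec, G=0.0)
        div = apo = trials = 0
        pop = pop0.copy()
        rng = np.random.default_rng(11)
        for t in range(60):
            trials += int(np.sum((pop.mitosis_clock + 1 >= 12)
                                 & (pop.layer == INTIMA)))
            batch = step_plasticity(pop, ecm, fields, sec, float(t), p, rng, 1.0)
            div += batch.count(MITOSIS)
            apo += batch.count(APOPTOSIS)
            # keep the population fixed: no bookkeeping of births/deaths here
        sd = math.sqrt(trials * 2 * p.alpha1)
        assert trials > 500
        assert abs(div - apo) <= 4.0 * sd

    def test_deterministic_given_seed(self, small_world):
        sec, pop0, ecm0 = small_world
        p = PlasticityParams()
        fields = make_fields(sec, G=0.3)
        batches = []
        for _ in range(2):
            pop = pop0.copy()
            rng = np.random.default_rng(99)
            b = step_plasticity(pop, ecm0.copy(), fields, sec, 5.0, p, rng, 1.0)
            batches.append([(e.kind, e.agent_id, e.location) for e in b])
        assert batches[0] == batches[1]

    def test_agent_appears_at_most_once_per_step(self, small_world):
        sec, pop0, ecm = small_world
        pop = pop0.copy()
        p = PlasticityParams(alpha1=0.3, alpha2=0.45, alpha5=0.5, alpha6=0.1,
                             alpha7=0.01)
        fields = make_fields(sec, G=0.5)
        rng = np.random.default_rng(5)
        for t in range(12):
            batch = step_plasticity(pop, ecm, fields, sec, float(t), p, rng, 1.0)
            ids = [e.agent_id for e in batch]
            assert len(ids) == len(set(ids))
            for e in batch:
                assert sec.layer_of(np.array(e.location)[None, :])[0] in (INTIMA, MEDIA)
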