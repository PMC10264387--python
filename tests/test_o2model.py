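"""Dissolved-O2 isotope model: Rayleigh respiration, mixing, inversion,
and scenario classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkox.o2model import (
    AIR_EQUILIBRATED,
    EndMember,
    GasIsotopeObservation,
    ScenarioLabel,
    ScenarioParams,
    air_contamination,
    classify_scenario,
    forward_dark_o2,
    invert_dark_o2,
    mix_o2_pools,
    rayleigh_respiration,
)


class TestRayleighRespiration:
    def test_identity_at_f_one(self):
        out = rayleigh_respiration(AIR_EQUILIBRATED, 1.0, 18.0)
        assert out.o2_ar == pytest.approx(1.0)
        assert out.d18o == pytest.approx(23.9)

    def test_zero_epsilon_scales_ratio_only(self):
        out = rayleigh_respiration(AIR_EQUILIBRATED, 0.5, 0.0)
        assert out.o2_ar == pytest.approx(0.5)
        assert out.d18o == pytest.approx(23.9)

    def test_worked_value(self):
        out = rayleigh_respiration(AIR_EQUILIBRATED, 0.5, 18.0)
        assert out.o2_ar == pytest.approx(0.5)
        assert out.d18o == pytest.approx(36.7548672, abs=1e-6)

    def test_singular_f_zero(self):
        with pytest.raises(ValueError):
            rayleigh_respiration(AIR_EQUILIBRATED, 0.0, 18.0)


class TestMixing:
    def test_x_zero_identity(self):
        src = EndMember(0.0, -20.0)
        out = mix_o2_pools(AIR_EQUILIBRATED, src, 0.0)
        assert out.o2_ar == AIR_EQUILIBRATED.o2_ar
        assert out.d18o == AIR_EQUILIBRATED.d18o

    def test_dark_o2_diagnostic_direction(self):
        # adding 10% light O2: O2/Ar up, d18O down to ~+19.9
        out = mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), 0.1)
        assert out.o2_ar == pytest.approx(1.1)
        assert out.d18o == pytest.approx((23.9 - 2.0) / 1.1, abs=1e-12)
        assert out.d18o == pytest.approx(19.909, abs=1e-3)
        assert out.o2_ar > AIR_EQUILIBRATED.o2_ar and out.d18o < AIR_EQUILIBRATED.d18o

    def test_equal_deltas_degenerate(self):
        out = mix_o2_pools(EndMember(1.0, 5.0), EndMember(1.0, 5.0), 0.37)
        assert out.d18o == pytest.approx(5.0)

    @given(x=st.floats(min_value=0.0, max_value=2.0),
           d_add=st.floats(min_value=-50.0, max_value=50.0))
    @settings(derandomize=True, max_examples=200)
    def test_conservation_of_o2_and_18o_amounts(self, x, d_add):
        base = AIR_EQUILIBRATED
        out = mix_o2_pools(base, EndMember(0.0, d_add), x)
        # O2 amount (in Ar-normalized units) is conserved
        assert out.o2_ar == pytest.approx(base.o2_ar * (1 + x), rel=1e-12)
        # delta-linear 18O amount is conserved
        lhs = out.o2_ar * out.d18o
        rhs = base.o2_ar * base.d18o + base.o2_ar * x * d_add
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)

    def test_exact_ratio_space_agrees_within_hundredth_permil(self):
        approx = mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), 0.3)
        exact = mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), 0.3, exact=True)
        assert abs(approx.d18o - exact.d18o) < 0.01

    def test_negative_x_raises(self):
        with pytest.raises(ValueError):
            mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), -0.1)

    @given(x=st.floats(min_value=1e-4, max_value=1.0))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_dark_addition(self, x):
        lighter = mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), x)
        lighter2 = mix_o2_pools(AIR_EQUILIBRATED, EndMember(0.0, -20.0), x * 1.01)
        assert lighter2.d18o < lighter.d18o
        assert lighter2.o2_ar > lighter.o2_ar


class TestAirContamination:
    def test_full_replacement(self):
        obs = EndMember(0.5, 35.0)
        out = air_contamination(obs, AIR_EQUILIBRATED, 1.0)
        assert out.o2_ar == pytest.approx(1.0)
        assert out.d18o == pytest.approx(23.9)

    def test_zero_is_identity(self):
        obs = EndMember(0.5, 35.0)
        out = air_contamination(obs, AIR_EQUILIBRATED, 0.0)
        assert (out.o2_ar, out.d18o) == (0.5, 35.0)

    @given(x=st.floats(min_value=0.01, max_value=0.99))
    @settings(derandomize=True, max_examples=100)
    def test_moves_strictly_toward_air_equilibrated(self, x):
        obs = EndMember(0.5, 35.0)
        out = air_contamination(obs, AIR_EQUILIBRATED, x)
        assert 23.9 < out.d18o < 35.0
        assert 0.5 < out.o2_ar < 1.0


class TestInversion:
    def test_null_case(self):
        obs = GasIsotopeObservation("s", 1, 1.0, 23.9)
        inv = invert_dark_o2(obs)
        assert inv.feasible
        assert inv.f_resp == pytest.approx(1.0, abs=1e-9)
        assert inv.x_prod == pytest.approx(0.0, abs=1e-9)
        assert inv.dark_fraction == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_recovers_parameters(self):
        params = ScenarioParams(epsilon_resp=18.0, delta_source=-20.0,
                                f_resp=0.8, x_prod=0.15)
        em = forward_dark_o2(params)
        inv = invert_dark_o2(GasIsotopeObservation("s", 1, em.o2_ar, em.d18o))
        assert inv.feasible
        assert inv.f_resp == pytest.approx(0.8, abs=1e-6)
        assert inv.x_prod == pytest.approx(0.15, abs=1e-6)

    def test_forward_of_inverted_reproduces_observation(self):
        # forward(invert(obs)) == obs across a grid of generating parameters
        for f in np.linspace(0.3, 1.0, 50):
            for x in np.linspace(0.0, 0.5, 50):
                em = forward_dark_o2(ScenarioParams(f_resp=float(f), x_prod=float(x)))
                inv = invert_dark_o2(GasIsotopeObservation("s", 1, em.o2_ar, em.d18o))
                assert inv.feasible
                em2 = forward_dark_o2(
                    ScenarioParams(f_resp=inv.f_resp, x_prod=inv.x_prod)
                )
                assert em2.o2_ar == pytest.approx(em.o2_ar, abs=1e-9)
                assert em2.d18o == pytest.approx(em.d18o, abs=1e-9)

    def test_supersaturated_light_pool_requires_production(self):
        # any feasible point with O2/Ar above air-equilibrated forces
        # x_prod = s - f >= s - 1 > 0 strictly
        obs = GasIsotopeObservation("s", 1, 1.05, 21.0)
        inv = invert_dark_o2(obs)
        assert inv.feasible
        assert inv.x_prod > 0.0

    def test_infeasible_point_flagged(self):
        # heavier than air-eq but with *elevated* O2/Ar cannot be built from
        # respiration + production (production only lowers delta)
        obs = GasIsotopeObservation("s", 1, 1.3, 40.0)
        inv = invert_dark_o2(obs)
        assert not inv.feasible


def _reps(o2_ar, d18o, n=3, jitter=0.0):
    rng = np.random.default_rng(0)
    return [
        GasIsotopeObservation("s", i + 1,
                              o2_ar + (rng.normal(0, jitter) if jitter else 0.0),
                              d18o + (rng.normal(0, jitter) if jitter else 0.0))
        for i in range(n)
    ]


class TestClassifyScenario:
    def test_air_equilibrated_point(self):
        v = classify_scenario(_reps(1.0, 23.9))
        assert v.label is ScenarioLabel.AIR_EQUILIBRATED

    def test_respiration_point_on_rayleigh_curve(self):
        em = rayleigh_respiration(AIR_EQUILIBRATED, 0.7, 18.0)
        # forward oracle: (1000+23.9)*0.7**(-0.018) - 1000
        assert em.d18o == pytest.approx(30.4947, abs=1e-3)
        v = classify_scenario(_reps(em.o2_ar, em.d18o))
        assert v.label is ScenarioLabel.RESPIRATION_CONSISTENT
        assert v.fitted.f_resp == pytest.approx(0.7, abs=0.01)

    def test_contamination_point(self):
        em = rayleigh_respiration(AIR_EQUILIBRATED, 0.5, 20.0)
        mixed = air_contamination(em, AIR_EQUILIBRATED, 0.5)
        v = classify_scenario(_reps(mixed.o2_ar, mixed.d18o))
        assert v.label in (
            ScenarioLabel.CONTAMINATION_CONSISTENT,
            ScenarioLabel.RESPIRATION_CONSISTENT,  # degenerate overlap on this plane
        )

    def test_elevated_ratio_depressed_delta_requires_light_source(self):
        v = classify_scenario(_reps(1.1, 21.0))
        assert v.label is ScenarioLabel.REQUIRES_LIGHT_SOURCE
        assert v.dark_fraction > 0.0

    def test_empty_replicates_raise(self):
        with pytest.raises(ValueError):
            classify_scenario([])

    def test_replicate_scatter_propagates(self):
        v = classify_scenario(_reps(1.0, 23.9, n=3, jitter=0.02))
        assert v.se_d18o > 0 and v.se_o2_ar > 0


class TestQuadrantExclusivity:
    """No respiration-only or contamination-only scenario reaches the
    {O2/Ar above air-eq, d18O below air-eq} quadrant."""

    SIGMA_R, SIGMA_D = 0.05, 0.1

    def test_brute_force_sweep_never_enters_quadrant(self):
        r_min = 1.0 + 3 * self.SIGMA_R
        d_max = 23.9 - 3 * self.SIGMA_D
        f_grid = np.linspace(1e-3, 1.0, 120)
        x_grid = np.linspace(0.0, 1.0, 120)
        eps_grid = np.linspace(0.0, 25.0, 26)
        for eps in eps_grid:
            for f in f_grid:
                em = rayleigh_respiration(AIR_EQUILIBRATED, float(f), float(eps))
                assert not (em.o2_ar > r_min and em.d18o < d_max)
                for x in x_grid[:: 6]:  # contamination on top of respiration
                    mixed = air_contamination(em, AIR_EQUILIBRATED, float(x))
                    assert not (mixed.o2_ar > r_min and mixed.d18o < d_max)

    def test_classifier_labels_quadrant_requires_light_source(self):
        for r, d in [(1.16, 23.5), (1.2, 22.0), (1.5, 20.0), (1.16, 10.0)]:
            v = classify_scenario(_reps(r, d))
            assert v.label is ScenarioLabel.REQUIRES_LIGHT_SOURCE
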