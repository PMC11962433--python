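"""Two-compartment fate model: rate matrix, steady state, transient oracle."""

import numpy as np
import pytest

from plastifate import (FateParameters, ParticleGeometry, build_rate_matrix,
                        degradation_rate_constant, steady_state_fate_factors,
                        transient_oracle, fate_factors)
from plastifate.errors import InfiniteResidenceError

WORKED_K = np.array([[0.5, -0.001], [-0.4, 0.013]])


def make_params(**kw):
    defaults = dict(k_sed=0.4, k_resusp=0.001, k_burial=0.002, ssdr_water=0.1)
    defaults.update(kw)
    return FateParameters(**defaults)


class TestDegradationRateConstant:
    @pytest.mark.parametrize("vd,shape,d0,expected", [
        (0.0, "sphere", 100.0, 0.0),
        (0.1, "sphere", 100.0, 0.006),   # 6 vd / d0
        (0.1, "fiber", 100.0, 0.004),    # 4 vd / d0
        (0.1, "film", 100.0, 0.002),     # 2 vd / d0, two-sided slab
    ])
    def test_mapping(self, vd, shape, d0, expected):
        k = degradation_rate_constant(vd, ParticleGeometry(shape, d0))
        assert k == pytest.approx(expected, rel=1e-12)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ValueError):
            degradation_rate_constant(-0.1, ParticleGeometry("sphere", 100.0))


class TestBuildRateMatrix:
    def test_zero_rates_give_zero_matrix(self):
        params = make_params(k_sed=0.0, k_resusp=0.0, k_burial=0.0)
        assert np.allclose(build_rate_matrix(params, 0.0, 0.0), 0.0)

    def test_worked_assembly(self):
        K = build_rate_matrix(make_params(), 0.1, 0.01)
        assert np.allclose(K, WORKED_K)

    def test_column_sums_are_net_losses(self):
        """Column sums equal loss-only rates: internal transfers cancel."""
        K = build_rate_matrix(make_params(), 0.1, 0.01)
        assert K[:, 0].sum() == pytest.approx(0.1)            # k_deg_w
        assert K[:, 1].sum() == pytest.approx(0.01 + 0.002)   # k_deg_s + k_burial

    def test_ssdr_sediment_defaults_to_water(self):
        p = make_params(ssdr_water=0.25)
        assert p.ssdr_sediment == 0.25
        p2 = make_params(ssdr_water=0.25, ssdr_sediment=0.05)
        assert p2.ssdr_sediment == 0.05


class TestSteadyState:
    def test_worked_example(self):
        ff = steady_state_fate_factors(WORKED_K)
        assert ff.ff_water == pytest.approx(2.131, abs=0.01)
        assert ff.ff_sediment == pytest.approx(65.57, abs=0.01)

    def test_single_compartment_limit(self):
        params = make_params(k_sed=0.0, k_resusp=0.0, k_burial=0.0)
        K = build_rate_matrix(params, 0.05, 0.0)
        ff = steady_state_fate_factors(K)
        assert ff.ff_water == pytest.approx(1.0 / 0.05, rel=1e-12)
        assert ff.ff_sediment == 0.0

    def test_rate_scaling_homogeneity(self):
        ff1 = steady_state_fate_factors(WORKED_K)
        ff2 = steady_state_fate_factors(2.0 * WORKED_K)
        assert ff2.ff_water == pytest.approx(ff1.ff_water / 2.0, rel=1e-12)
        assert ff2.ff_sediment == pytest.approx(ff1.ff_sediment / 2.0, rel=1e-12)

    def test_no_loss_pathway_is_infinite_residence(self):
        with pytest.raises(InfiniteResidenceError, match="water"):
            steady_state_fate_factors(np.zeros((2, 2)))
        # water->sediment loop with no sediment sink
        params = make_params(k_burial=0.0)
        K = build_rate_matrix(params, 0.0, 0.0)
        with pytest.raises(InfiniteResidenceError, match="sediment"):
            steady_state_fate_factors(K)

    def test_sedimentation_dominated_regime(self):
        """As sedimentation overwhelms everything (no resuspension), water
        residence vanishes and sediment residence tends to the inverse of its
        loss rate."""
        params = make_params(k_sed=1e6, k_resusp=0.0)
        K = build_rate_matrix(params, 0.01, 0.004)
        ff = steady_state_fate_factors(K)
        assert ff.ff_water < 1e-5
        assert ff.ff_sediment == pytest.approx(1.0 / (0.004 + 0.002), rel=1e-3)

    def test_monotone_in_loss_rates(self):
        """Both fate factors are non-increasing in every loss rate."""
        base = fate_factors(make_params(), ParticleGeometry("sphere", 100.0))
        for bump in (dict(k_burial=0.02), dict(ssdr_water=0.2),
                     dict(ssdr_sediment=0.2)):
            ff = fate_factors(make_params(**bump), ParticleGeometry("sphere", 100.0))
            assert ff.ff_water <= base.ff_water + 1e-12
            assert ff.ff_sediment <= base.ff_sediment + 1e-12

    def test_larger_particles_linger_in_sediment(self):
        """At fixed velocity, a larger particle degrades more slowly and has
        a longer sediment residence."""
        small = fate_factors(make_params(), ParticleGeometry("sphere", 10.0))
        large = fate_factors(make_params(), ParticleGeometry("sphere", 1000.0))
        assert large.ff_sediment > small.ff_sediment


class TestTransientOracle:
    def test_matches_steady_state_on_worked_example(self):
        ff = transient_oracle(WORKED_K)
        ss = steady_state_fate_factors(WORKED_K)
        assert ff.ff_water == pytest.approx(ss.ff_water, rel=5e-3)
        assert ff.ff_sediment == pytest.approx(ss.ff_sediment, rel=5e-3)

    def test_diagonal_closed_form(self):
        K = np.diag([0.1, 0.02])
        ff = transient_oracle(K, emission=(1.0, 1.0))
        assert ff.ff_water == pytest.approx(10.0, rel=1e-4)
        assert ff.ff_sediment == pytest.approx(50.0, rel=1e-4)

    def test_zero_emission_gives_zero(self):
        ff = transient_oracle(WORKED_K, emission=(0.0, 0.0))
        assert ff.ff_water == 0.0 and ff.ff_sediment == 0.0

    def test_agreement_on_random_parameter_draws(self):
        """Matrix inverse vs time integration within 0.5% across 100
        non-degenerate random rate sets."""
        rng = np.random.default_rng(12345)
        for _ in range(100):
            params = FateParameters(
                k_sed=10 ** rng.uniform(-3, 0),
                k_resusp=10 ** rng.uniform(-5, -2),
                k_burial=10 ** rng.uniform(-5, -2),
                ssdr_water=10 ** rng.uniform(-4, -1),
            )
            geo = ParticleGeometry(
                rng.choice(["sphere", "fiber", "film"]),
                float(10 ** rng.uniform(0, 3.7)))
            k_w = degradation_rate_constant(params.ssdr_water, geo)
            k_s = degradation_rate_constant(params.ssdr_sediment, geo)
            K = build_rate_matrix(params, k_w, k_s)
            ss = steady_state_fate_factors(K)
            tr = transient_oracle(K)
            assert tr.ff_water == pytest.approx(ss.ff_water, rel=5e-3)
            assert tr.ff_sediment == pytest.approx(ss.ff_sediment, rel=5e-3)
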