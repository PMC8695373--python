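"""Forward fractionation models, their limits, and inversion round trips."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from co2fate.errors import EnvelopeError, InconsistentInputError, ValidationError
from co2fate.fractionation import (
    HybridFitResult,
    apparent_alpha,
    closed_system_residual_delta,
    consumption_partition,
    crossover_dissolution_share,
    fit_field_model,
    hybrid_residual_delta,
    invert_dissolution_share,
    rayleigh_residual_delta,
)
from co2fate.synthetic import SyntheticFieldParams, generate_field

from conftest import rayleigh_oracle


class TestRayleigh:
    def test_no_removal_and_no_fractionation(self):
        assert rayleigh_residual_delta(3.2, 1.0, 1.0038) == pytest.approx(3.2)
        assert rayleigh_residual_delta(5.0, 0.3, 1.0) == pytest.approx(5.0)

    def test_dissolution_halfway(self):
        # frozen against the 1e6-step incremental-removal oracle
        assert rayleigh_residual_delta(0.85, 0.5, 1.0038) == pytest.approx(-1.7827, abs=1e-3)

    @pytest.mark.parametrize("f", [0.05, 0.11, 0.3, 0.5, 0.9])
    @pytest.mark.parametrize("alpha", [1.0038, 1.0086])
    def test_matches_incremental_oracle(self, f, alpha):
        closed_form = rayleigh_residual_delta(0.85, f, alpha)
        assert closed_form == pytest.approx(rayleigh_oracle(0.85, f, alpha), abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            rayleigh_residual_delta(0.0, 0.0, 1.0038)
        with pytest.raises(ValidationError):
            rayleigh_residual_delta(0.0, 0.5, -1.0)


class TestClosedSystem:
    def test_limits(self):
        assert closed_system_residual_delta(12.0, 1.0, 0.9363) == 12.0
        assert closed_system_residual_delta(0.0, 0.5, 0.9363) == pytest.approx(31.85)
        assert closed_system_residual_delta(0.85, 0.0, 0.9363) == pytest.approx(64.55)

    @pytest.mark.parametrize("f", np.linspace(0.1, 0.95, 8).tolist())
    def test_first_order_isotope_mass_balance(self, f, factors):
        # the produced CH4 sits one equilibrium offset below the residual CO2;
        # pool-weighted delta must return the initial composition
        delta_i = 0.85
        d_res = closed_system_residual_delta(delta_i, f, factors.alpha_m)
        d_ch4_implied = d_res + (factors.alpha_m - 1.0) * 1000.0
        assert f * d_res + (1 - f) * d_ch4_implied == pytest.approx(delta_i, abs=0.05)


class TestHybrid:
    def test_apparent_alpha_endpoints_and_mixture(self, factors):
        assert apparent_alpha(1.0, factors) == factors.alpha_d
        assert apparent_alpha(0.0, factors) == factors.alpha_m
        assert apparent_alpha(0.794, factors) == pytest.approx(0.98990, abs=1e-5)

    def test_forward_value_at_field_conditions(self, factors):
        # ~89 % removal at ~3:1 dissolution:methanogenesis enriches the
        # residual CO2 by ~9 permil over the injectate
        assert hybrid_residual_delta(0.85, 0.11, 0.794, factors) == pytest.approx(9.87, abs=0.02)

    def test_pure_methanogenesis_limit_exact_at_zero_delta(self, factors):
        for f in (0.11, 0.5, 0.9):
            assert hybrid_residual_delta(0.0, f, 0.0, factors) == pytest.approx(
                closed_system_residual_delta(0.0, f, factors.alpha_m), abs=1e-12
            )

    def test_pure_dissolution_limit_within_scale_term(self, factors):
        # the hybrid is evaluated on the delta scale; it approaches the
        # (1000+delta)-scale Rayleigh curve to within the analytic
        # scale-convention bound 1000 (alpha_d - 1) |ln f + 1 - f|
        for f in (0.11, 0.3, 0.5, 0.9):
            bound = 1000.0 * (factors.alpha_d - 1.0) * abs(math.log(f) + 1.0 - f) + 1e-6
            diff = abs(
                hybrid_residual_delta(0.85, f, 1.0, factors)
                - rayleigh_residual_delta(0.85, f, factors.alpha_d)
            )
            assert diff <= bound

    def test_sequential_variant_tracks_default(self, factors):
        # robustness check: the partitioned two-step evaluation stays within
        # the same analytic scale bound of the blended default
        for f in (0.11, 0.3, 0.6, 0.9):
            for f_d in (0.0, 0.5, 0.794, 1.0):
                a = hybrid_residual_delta(0.85, f, f_d, factors, "apparent")
                s = hybrid_residual_delta(0.85, f, f_d, factors, "sequential")
                assert abs(a - s) <= 5.0

    def test_strictly_decreasing_in_dissolution_share(self, factors):
        for f in (0.11, 0.5, 0.9):
            vals = [hybrid_residual_delta(0.85, f, fd, factors) for fd in np.linspace(0, 1, 21)]
            assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_enrichment_grows_with_removal_below_crossover(self, factors):
        f_star = crossover_dissolution_share(factors)
        f_d = 0.5 * f_star  # below the crossover, alpha_A < 1
        vals = [hybrid_residual_delta(0.85, f, f_d, factors) for f in (0.9, 0.6, 0.3, 0.11)]
        assert all(x < y for x, y in zip(vals, vals[1:]))


class TestInversion:
    @pytest.mark.parametrize("f", np.arange(0.2, 0.95, 0.1).tolist())
    @pytest.mark.parametrize("f_d", np.linspace(0.0, 1.0, 5).tolist())
    def test_round_trip_on_grid(self, f, f_d, factors):
        delta_obs = hybrid_residual_delta(0.85, f, f_d, factors)
        assert invert_dissolution_share(delta_obs, 0.85, f, factors) == pytest.approx(f_d, abs=1e-6)

    def test_pure_dissolution_observation(self, factors):
        delta_obs = hybrid_residual_delta(0.85, 0.4, 1.0, factors)
        assert invert_dissolution_share(delta_obs, 0.85, 0.4, factors) == pytest.approx(1.0, abs=1e-9)

    def test_above_methanogenesis_curve_flagged(self, factors):
        top = hybrid_residual_delta(0.85, 0.4, 0.0, factors)
        with pytest.raises(EnvelopeError) as exc:
            invert_dissolution_share(top + 2.0, 0.85, 0.4, factors)
        assert exc.value.distance == pytest.approx(2.0, abs=1e-9)

    def test_below_dissolution_curve_flagged_with_negative_distance(self, factors):
        bottom = hybrid_residual_delta(0.85, 0.4, 1.0, factors)
        with pytest.raises(EnvelopeError) as exc:
            invert_dissolution_share(bottom - 1.5, 0.85, 0.4, factors)
        assert exc.value.distance == pytest.approx(-1.5, abs=1e-9)

    def test_no_removal_requires_consistent_delta(self, factors):
        with pytest.raises(InconsistentInputError):
            invert_dissolution_share(5.0, 0.85, 1.0, factors)
        assert math.isnan(invert_dissolution_share(0.85, 0.85, 1.0, factors))


class TestConsumptionPartition:
    @given(f=st.floats(0.0, 1.0), f_d=st.floats(0.0, 1.0))
    def test_conserves_removed_fraction(self, f, f_d):
        meth, diss = consumption_partition(f, f_d)
        assert meth + diss == pytest.approx(1.0 - f, abs=1e-12)
        assert meth >= 0 and diss >= 0

    def test_field_conditions_example(self):
        meth, diss = consumption_partition(0.11, 0.794)
        assert meth == pytest.approx(0.183, abs=5e-4)
        assert diss == pytest.approx(0.707, abs=5e-4)

    def test_degenerate_cases(self):
        assert consumption_partition(1.0, 0.5) == (0.0, 0.0)
        meth, diss = consumption_partition(0.3, 1.0)
        assert meth == 0.0 and diss == pytest.approx(0.7)

    def test_result_object_conserves(self):
        r = HybridFitResult(sample_id="s", f=0.11, f_d=0.794, alpha_a=0.98990)
        assert r.meth_fraction + r.diss_fraction == pytest.approx(1 - r.f, abs=1e-12)
        assert r.m_to_d == pytest.approx((1 - 0.794) / 0.794)


class TestFieldFit:
    def test_zero_noise_recovery(self, noiseless_field, config):
        samples, truth = noiseless_field
        results, summary = fit_field_model(samples, config=config)
        assert summary.reference_id == truth["reference_id"]
        truth_f = {r["sample_id"]: r["f"] for r in truth["per_sample"]}
        for r in results:
            assert r.f == pytest.approx(truth_f[r.sample_id], abs=1e-6)
            assert r.f_d == pytest.approx(truth["true_f_d"], abs=1e-6)

    def test_summary_ratio_is_definitional(self, noisy_field, config):
        samples, _ = noisy_field
        _, summary = fit_field_model(samples, config=config)
        assert summary.m_to_d == pytest.approx((1 - summary.mean_f_d) / summary.mean_f_d)
        assert summary.d_to_m == pytest.approx(1.0 / summary.m_to_d)

    def test_single_sample_field_warns_and_returns_empty(self, noiseless_field, config):
        samples, _ = noiseless_field
        with pytest.warns(UserWarning, match="single-sample"):
            results, summary = fit_field_model(samples[:1], config=config)
        assert results == [] and summary.n_fitted == 0

    def test_negative_apparent_removal_excluded(self, noiseless_field, config):
        import copy

        samples = copy.deepcopy(noiseless_field[0])
        gained = samples[1]
        gained.co2_he3 = samples[0].co2_he3 * 1.3  # CO2 gain relative to reference
        results, summary = fit_field_model(samples, reference_id="SYN-REF", config=config)
        fitted_ids = {r.sample_id for r in results}
        assert gained.sample_id not in fitted_ids
        assert "negative apparent removal" in summary.flagged[gained.sample_id]

    def test_concentration_based_f_agrees_at_zero_noise(self, noiseless_params):
        from co2fate import AnalysisConfig

        samples, truth = generate_field(noiseless_params)
        cfg = AnalysisConfig(rng_seed=1, f_source="co2_molpct")
        results, summary = fit_field_model(samples, config=cfg)
        for r in results:
            assert r.f_d == pytest.approx(truth["true_f_d"], abs=1e-6)
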