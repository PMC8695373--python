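"""Equilibrium thermometer curves, inversion, and Monte-Carlo uncertainty."""

import numpy as np
import pytest

from co2fate.errors import CalibrationRangeError, PoorlyConstrainedError, ValidationError
from co2fate.samples import CalibrationCoefficients, GasSample
from co2fate.thermometry import (
    AOM_EQUILIBRATING_LABEL,
    THERMOMETERS,
    _eval_curve,
    apparent_temperature,
    calibration_checksum,
    carbon_exchange_delta,
    clumped_equilibrium_values,
    disequilibrium_vector,
    equilibrium_1000lnalpha_co2_ch4,
    invert_carbon_equilibrium_t,
    invert_equilibrium_t,
    load_default_calibrations,
)


class TestCurves:
    def test_co2_ch4_reference_value(self, calibrations):
        # regression fixture recorded from the bundled carbon-exchange calibration
        assert equilibrium_1000lnalpha_co2_ch4(323.15, calibrations) == pytest.approx(61.455, abs=1e-3)

    def test_clumped_reference_values(self, calibrations):
        d13, d12 = clumped_equilibrium_values(300.0, calibrations)
        assert d13 == pytest.approx(5.6872, abs=1e-3)
        assert d12 == pytest.approx(20.0716, abs=1e-3)

    def test_strictly_decreasing_in_t_at_1k_steps(self, calibrations):
        t = np.arange(*calibrations.valid_t_range, 1.0)
        for therm in THERMOMETERS:
            vals = _eval_curve(calibrations.coeffs_for(therm), t)
            assert np.all(np.diff(vals) < 0), therm

    def test_stochastic_limit_is_zero(self, calibrations):
        # the clumped excesses vanish at very high temperature by construction
        for therm in ("d13ch3d", "d12ch2d2"):
            assert abs(_eval_curve(calibrations.coeffs_for(therm), 1e6)) < 1e-6

    def test_zero_coefficients_give_zero_everywhere(self):
        cal = CalibrationCoefficients(
            co2_ch4_coeffs=(0.0,),
            d13ch3d_coeffs=(0.0,),
            d12ch2d2_coeffs=(0.0,),
        )
        assert equilibrium_1000lnalpha_co2_ch4(300.0, cal) == 0.0
        assert clumped_equilibrium_values(500.0, cal) == (0.0, 0.0)

    def test_out_of_range_temperature_rejected(self, calibrations):
        with pytest.raises(CalibrationRangeError):
            equilibrium_1000lnalpha_co2_ch4(100.0, calibrations)

    def test_checksum_identifies_calibration(self, calibrations):
        other = CalibrationCoefficients(
            co2_ch4_coeffs=(0.16, 0.0, 11.8, -2.37, 0.206),
            d13ch3d_coeffs=calibrations.d13ch3d_coeffs,
            d12ch2d2_coeffs=calibrations.d12ch2d2_coeffs,
        )
        assert calibration_checksum(calibrations) != calibration_checksum(other)
        assert calibration_checksum(calibrations) == calibration_checksum(load_default_calibrations())


class TestInversion:
    @pytest.mark.parametrize("therm", THERMOMETERS)
    @pytest.mark.parametrize("t_true", [300.0, 350.0, 450.0])
    def test_round_trip_below_hundredth_kelvin(self, therm, t_true, calibrations):
        delta = float(_eval_curve(calibrations.coeffs_for(therm), t_true))
        assert invert_equilibrium_t(delta, therm, calibrations) == pytest.approx(t_true, abs=0.01)

    def test_carbon_pair_round_trip(self, calibrations):
        sep = equilibrium_1000lnalpha_co2_ch4(350.0, calibrations)
        d_ch4 = -50.0
        d_co2 = (1000.0 + d_ch4) * np.exp(sep / 1000.0) - 1000.0
        at = invert_carbon_equilibrium_t(d_co2, d_ch4, calibrations)
        assert at.t_central == pytest.approx(350.0 - 273.15, abs=0.01)
        assert at.ci_low == at.t_central == at.ci_high

    def test_ln_scale_vs_raw_difference(self):
        assert carbon_exchange_delta(13.5, -47.7, "difference") == pytest.approx(61.2)
        ln = carbon_exchange_delta(13.5, -47.7, "ln")
        assert 0 < ln - 61.2 < 2.0  # ln-ratio slightly exceeds the raw difference here

    def test_equal_deltas_unattainable(self, calibrations):
        with pytest.raises(CalibrationRangeError, match="attainable"):
            invert_carbon_equilibrium_t(-30.0, -30.0, calibrations)

    def test_field_separation_range_maps_to_low_temperatures(self, calibrations):
        # the injected-field CO2-CH4 separations (raw differences 53.7-64.4
        # permil) invert to apparent temperatures overlapping the 29.2-50.7 degC
        # reservoir window at the warm end and ~77 degC at the dry end,
        # consistent with isotopic equilibration at reservoir conditions
        t_low = invert_equilibrium_t(carbon_exchange_delta(16.7, -47.7), "co2_ch4", calibrations) - 273.15
        t_high = invert_equilibrium_t(carbon_exchange_delta(6.0, -47.7), "co2_ch4", calibrations) - 273.15
        assert 29.2 <= t_low <= 50.7
        assert t_high == pytest.approx(76.3, abs=3.0)


class TestMonteCarlo:
    def test_zero_sigma_collapses_ci(self, calibrations):
        at = apparent_temperature(4.5, 0.0, "d13ch3d", calibrations, mc_draws=1000, seed=1)
        assert at.ci_low == at.t_central == at.ci_high

    def test_fixed_seed_is_bit_identical(self, calibrations):
        a = apparent_temperature(4.5, 0.3, "d13ch3d", calibrations, mc_draws=20000, seed=9)
        b = apparent_temperature(4.5, 0.3, "d13ch3d", calibrations, mc_draws=20000, seed=9)
        assert (a.t_central, a.ci_low, a.ci_high) == (b.t_central, b.ci_low, b.ci_high)

    def test_ci_brackets_central_and_is_asymmetric_upward(self, calibrations):
        # the calibration flattens toward high T, so symmetric delta noise maps
        # to a longer upper temperature tail
        at = apparent_temperature(4.5, 0.4, "d13ch3d", calibrations, mc_draws=50000, seed=2)
        assert at.ci_low < at.t_central < at.ci_high
        assert (at.ci_high - at.t_central) >= (at.t_central - at.ci_low)

    def test_mostly_rejected_draws_raise(self, calibrations):
        lo = float(_eval_curve(calibrations.d13ch3d_coeffs, calibrations.valid_t_range[1]))
        with pytest.raises(PoorlyConstrainedError):
            apparent_temperature(lo + 0.001, 10.0, "d13ch3d", calibrations, mc_draws=5000, seed=3)

    def test_negative_sigma_rejected(self, calibrations):
        with pytest.raises(ValidationError):
            apparent_temperature(4.5, -0.1, "d13ch3d", calibrations)


def _sample_with_clumped(d13ch3d, d12ch2d2, t_res=45.0):
    return GasSample(
        sample_id="s", field_name="f", co2_molpct=15.0, ch4_molpct=80.0,
        d13c_co2=13.0, d13c_ch4=-48.0, r_over_ra=1.8, he4_ne20=4000.0,
        co2_he3=1e9, reservoir_t=t_res, d13ch3d=d13ch3d, d12ch2d2=d12ch2d2,
    )


class TestDisequilibrium:
    def test_equilibrium_observation_gives_zero_offsets(self, calibrations):
        eq13, eq12 = clumped_equilibrium_values(45.0 + 273.15, calibrations)
        (o13, o12), label = disequilibrium_vector(_sample_with_clumped(eq13, eq12), calibrations)
        assert o13 == pytest.approx(0.0, abs=1e-12)
        assert o12 == pytest.approx(0.0, abs=1e-12)
        assert label == "equilibrium at reservoir temperature"

    def test_d12_deficit_labelled_methanogenesis_aom(self, calibrations):
        eq13, eq12 = clumped_equilibrium_values(45.0 + 273.15, calibrations)
        (_, o12), label = disequilibrium_vector(
            _sample_with_clumped(eq13 + 0.2, eq12 - 6.0), calibrations
        )
        assert o12 == pytest.approx(-6.0)
        assert label == AOM_EQUILIBRATING_LABEL

    def test_missing_clumped_data_not_computable(self, calibrations):
        s = _sample_with_clumped(4.5, None)
        assert disequilibrium_vector(s, calibrations) is None
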