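"""Assay conversion, Michaelis-Menten fitting and apparent constants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxescape.errors import ConfigError, DataError
from oxescape.kinetics import (ATM_PA, AssayConfig, KineticParams,
                               OxygenState, absorbance_to_rate,
                               apparent_constants, dilution_series,
                               fit_assay_table, fit_michaelis_menten,
                               kcat_from_vmax, oxygen_concentration,
                               simulate_assay)


class TestAbsorbanceToRate:
    def test_zero_slope_zero_rate(self):
        cfg = AssayConfig(pathlength_cm=1.0)
        assert absorbance_to_rate(0.0, cfg) == 0.0

    def test_beer_lambert_arithmetic(self):
        cfg = AssayConfig(pathlength_cm=1.0)
        # 0.294 A/min over epsilon 29400 and 1 cm = 1e-5 M/min = 0.01 mM/min
        assert absorbance_to_rate(0.294, cfg) == pytest.approx(0.01)

    def test_doubling_pathlength_halves_rate(self):
        r1 = absorbance_to_rate(0.5, AssayConfig(pathlength_cm=0.5))
        r2 = absorbance_to_rate(0.5, AssayConfig(pathlength_cm=1.0))
        assert r1 == pytest.approx(2 * r2)

    def test_missing_pathlength_fatal(self):
        with pytest.raises(ConfigError, match="pathlength"):
            absorbance_to_rate(0.1, AssayConfig())


class TestMichaelisMentenFit:
    def test_noiseless_exact_recovery(self):
        S = dilution_series()
        v = 1.0 * S / (2.0 + S)
        fit = fit_michaelis_menten(np.column_stack([S, v]),
                                   exclusion_threshold_mM=None)
        assert fit.Vmax == pytest.approx(1.0, rel=1e-6)
        assert fit.KM_mM == pytest.approx(2.0, rel=1e-6)

    def test_inhibited_concentrations_excluded(self):
        S = dilution_series()          # 128 down to 0.25
        v = 1.0 * S / (2.0 + S)
        fit = fit_michaelis_menten(np.column_stack([S, v]), 16.0)
        assert fit.excluded_S_mM == [128.0, 64.0, 32.0]
        assert fit.n_used == 7

    def test_too_few_points_fatal(self):
        with pytest.raises(DataError):
            fit_michaelis_menten([(128.0, 1.0), (64.0, 0.9), (32.0, 0.8),
                                  (16.0, 0.7)], 16.0)
        # 16.0 itself is retained: "above 16 mM" excludes strictly

    def test_r_squared_perfect_for_exact_data(self):
        S = dilution_series(n=8)
        v = 3.0 * S / (5.0 + S)
        fit = fit_michaelis_menten(np.column_stack([S, v]), None)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)


class TestApparentConstants:
    def test_saturating_oxygen_limit(self):
        for mech in ("ping_pong", "independent_sites"):
            p = KineticParams(10.0, 1.0, 0.33, mech)
            ap = apparent_constants(p, 1e9)
            assert ap.Vmax_app == pytest.approx(10.0, rel=1e-6)
            assert ap.KM_app_mM == pytest.approx(1.0, rel=1e-6)

    def test_ping_pong_at_half_saturating_oxygen(self):
        p = KineticParams(10.0, 1.0, 0.33, "ping_pong")
        ap = apparent_constants(p, 0.33)
        assert ap.Vmax_app == pytest.approx(5.0)
        assert ap.KM_app_mM == pytest.approx(0.5)

    def test_ping_pong_efficiency_invariant(self):
        p = KineticParams(10.0, 1.0, 0.33, "ping_pong")
        effs = [apparent_constants(p, O).efficiency_app
                for O in (0.05, 0.27, 1.2)]
        np.testing.assert_allclose(effs, effs[0], rtol=1e-12)

    def test_independent_sites_efficiency_rises_with_oxygen(self):
        p = KineticParams(10.0, 1.0, 0.33, "independent_sites")
        effs = [apparent_constants(p, O).efficiency_app
                for O in (0.1, 0.27, 1.2)]
        assert effs[0] < effs[1] < effs[2]

    @given(st.floats(0.01, 10.0), st.floats(0.02, 5.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_apparent_constants_increase_toward_asymptote(self, o1, o2):
        p = KineticParams(7.0, 3.0, 0.33, "ping_pong")
        lo, hi = sorted((o1, o2))
        a, b = apparent_constants(p, lo), apparent_constants(p, hi)
        assert b.Vmax_app >= a.Vmax_app
        assert b.KM_app_mM >= a.KM_app_mM
        assert b.Vmax_app <= p.Vmax and b.KM_app_mM <= p.KM_S_mM


class TestOxygenConcentration:
    def test_zero_saturation(self):
        assert oxygen_concentration(OxygenState(saturation_percent=0.0)) == 0.0

    def test_pure_oxygen_at_one_atmosphere(self):
        c = oxygen_concentration(OxygenState(partial_pressure_Pa=ATM_PA))
        assert c == pytest.approx(1.216, abs=5e-4)

    def test_full_saturation_equals_pure_oxygen_pressure(self):
        c1 = oxygen_concentration(OxygenState(saturation_percent=100.0))
        c2 = oxygen_concentration(OxygenState(partial_pressure_Pa=ATM_PA))
        assert c1 == pytest.approx(c2)

    def test_ambient_air_near_literature_value(self):
        # 21% O2 in air: ~0.255 mM, within 10% of the ~270 uM benchmark
        c = oxygen_concentration(OxygenState(partial_pressure_Pa=0.21 * ATM_PA))
        assert c == pytest.approx(0.270, rel=0.10)

    def test_linear_in_partial_pressure(self):
        c1 = oxygen_concentration(OxygenState(partial_pressure_Pa=1000.0))
        c5 = oxygen_concentration(OxygenState(partial_pressure_Pa=5000.0))
        assert c5 == pytest.approx(5 * c1)

    def test_both_or_neither_inputs_fatal(self):
        with pytest.raises(ConfigError):
            oxygen_concentration(OxygenState())
        with pytest.raises(ConfigError):
            oxygen_concentration(OxygenState(partial_pressure_Pa=1.0,
                                             saturation_percent=50.0))


class TestKcat:
    def test_turnover_from_molar_concentration(self):
        # 0.1 mg/mL of a 50 kDa enzyme = 2e-3 mM; Vmax 1 mM/min -> 500/min
        assert kcat_from_vmax(1.0, 0.1, 50_000.0) == pytest.approx(500.0)

    def test_requires_positive_inputs(self):
        with pytest.raises(ConfigError):
            kcat_from_vmax(1.0, 0.0, 50_000.0)


class TestSimulateAssay:
    def test_noiseless_rates_follow_rate_law(self):
        p = KineticParams(2.0, 4.0, 0.33, "ping_pong")
        cfg = AssayConfig()
        t = simulate_assay(p, [0.27], cfg)
        np.testing.assert_allclose(
            t["rate"], p.rate(t["S_mM"].to_numpy(), 0.27), rtol=1e-12)

    def test_same_seed_identical_tables(self):
        p = KineticParams(2.0, 4.0, 0.33)
        cfg = AssayConfig()
        a = simulate_assay(p, [0.27, 1.2], cfg, noise_sigma=0.05, seed=3)
        b = simulate_assay(p, [0.27, 1.2], cfg, noise_sigma=0.05, seed=3)
        assert a.equals(b)

    def test_round_trip_apparent_km_rises_with_oxygen(self):
        """Simulate at three oxygenation levels, fit each: under ping-pong
        both apparent constants increase with dissolved oxygen."""
        p = KineticParams(1.0, 5.0, 0.33, "ping_pong")
        cfg = AssayConfig()
        t = simulate_assay(p, [0.1, 0.27, 1.2], cfg)
        fits = fit_assay_table(t)
        assert fits["KM_app_mM"].is_monotonic_increasing
        assert fits["Vmax_app"].is_monotonic_increasing
        # and the fitted values match the algebraic projection
        for row in fits.itertuples():
            ap = apparent_constants(p, row.O2_mM)
            assert row.Vmax_app == pytest.approx(ap.Vmax_app, rel=1e-6)
            assert row.KM_app_mM == pytest.approx(ap.KM_app_mM, rel=1e-6)
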