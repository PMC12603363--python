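"""Unit and property tests for the FvCB model, curve fitting, Laisk
intersection and variable-J mesophyll conductance."""

import numpy as np
import pytest
from scipy.optimize import brentq

from oakleaf.gas_exchange import (
    GAMMA_STAR_30C,
    AciCurve,
    FluorescenceConfig,
    FvcbParams,
    GasExchangeError,
    amax_and_normalize,
    detect_tpu_limitation,
    extract_at_ca,
    fit_aci,
    fluorescence_gm_profile,
    fvcb_rates,
    jflu,
    laisk_rd_cistar,
    variable_j_gm,
)
from oakleaf.synthetic import SimSpec, full_protocol_setpoints, simulate_aci

from conftest import make_curve


class TestFvcbRates:
    def test_rubisco_rate_hand_arithmetic(self):
        # 100 * (400 - 54.9) / (400 + 1093.6) - 1
        p = FvcbParams(vcmax=100, jmax=500, rd=1.0)
        out = fvcb_rates(p, 400.0)
        assert out["a_c"] == pytest.approx(100 * 345.1 / 1493.6 - 1, rel=1e-12)
        assert out["a_c"] == pytest.approx(22.105, abs=5e-4)

    def test_rubp_rate_hand_arithmetic(self):
        # 150 * (400 - 54.9) / (4*400 + 8*54.9) - 1
        p = FvcbParams(vcmax=500, jmax=150, rd=1.0)
        out = fvcb_rates(p, 400.0)
        assert out["a_j"] == pytest.approx(150 * 345.1 / 2039.2 - 1, rel=1e-12)
        assert out["a_j"] == pytest.approx(24.385, abs=5e-4)

    def test_compensation_point_gives_minus_rd(self):
        p = FvcbParams(vcmax=100, jmax=150, rd=1.3)
        out = fvcb_rates(p, GAMMA_STAR_30C)
        assert out["a_c"] == pytest.approx(-1.3)
        assert out["a_j"] == pytest.approx(-1.3)

    def test_tpu_rate_direct_substitution(self):
        p = FvcbParams(vcmax=100, jmax=150, tpu=8.0, rd=1.0)
        assert fvcb_rates(p, 800.0)["a_p"] == pytest.approx(23.0)

    def test_tpu_absent_excluded_from_minimum(self):
        p = FvcbParams(vcmax=100, jmax=150, rd=1.0)
        out = fvcb_rates(p, 2000.0)
        assert np.isnan(out["a_p"])
        assert out["a_n"] == min(out["a_c"], out["a_j"])

    def test_negative_cc_rejected(self):
        p = FvcbParams(vcmax=100, jmax=150)
        with pytest.raises(GasExchangeError):
            fvcb_rates(p, -5.0)

    def test_monotone_in_cc_and_min_property(self):
        p = FvcbParams(vcmax=90, jmax=140, tpu=9.0, rd=0.7)
        cc = np.linspace(GAMMA_STAR_30C + 1, 1500, 300)
        out = fvcb_rates(p, cc)
        assert np.all(np.diff(out["a_c"]) >= 0)
        assert np.all(np.diff(out["a_j"]) >= 0)
        for key in ("a_c", "a_j", "a_p"):
            assert np.all(out["a_n"] <= out[key] + 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(GasExchangeError):
            FvcbParams(vcmax=-1, jmax=100)
        with pytest.raises(GasExchangeError):
            FvcbParams(vcmax=100, jmax=100, rd=-0.1)
        with pytest.raises(GasExchangeError):
            FvcbParams(vcmax=100, jmax=100, tpu=0.0)


class TestJflu:
    def test_hand_arithmetic(self):
        cfg = FluorescenceConfig(alpha=0.863)
        assert jflu(0.25, 1500, cfg) == pytest.approx(161.8125)
        cfg2 = FluorescenceConfig(alpha=0.844)
        assert jflu(0.20, 1500, cfg2) == pytest.approx(126.6)

    def test_zero_yield(self):
        assert jflu(0.0, 1500, FluorescenceConfig(alpha=0.9)) == 0.0

    def test_domain_errors(self):
        cfg = FluorescenceConfig(alpha=0.9)
        with pytest.raises(GasExchangeError):
            jflu(1.2, 1500, cfg)
        with pytest.raises(GasExchangeError):
            FluorescenceConfig(alpha=1.5)


class TestVariableJGm:
    def test_hand_arithmetic_oracle(self):
        # gm = an / (ci - gamma* (j + 8x) / (j - 4x)), x = an + rd
        an, ci, j, rd, gs = 20.0, 300.0, 160.0, 0.71, 49.60
        x = an + rd
        expected = an / (ci - gs * (j + 8 * x) / (j - 4 * x))
        got = variable_j_gm(an, ci, j, rd, gamma_star=gs)
        assert got == pytest.approx(expected, rel=1e-14)
        assert got == pytest.approx(0.2206, abs=5e-4)

    def test_zero_assimilation_zero_respiration(self):
        assert variable_j_gm(0.0, 300.0, 100.0, 0.0) == 0.0

    def test_electron_transport_domain_error(self):
        with pytest.raises(GasExchangeError):
            variable_j_gm(20.0, 300.0, 4 * 20.71, 0.71)

    def test_invalid_bracket_reported(self):
        # Ci below the photocompensation term -> invalid, not silently negative
        with pytest.raises(GasExchangeError):
            variable_j_gm(20.0, 60.0, 160.0, 0.71)

    def test_agrees_with_numeric_inversion(self):
        """Forward-solving An from gm via the same relation and inverting
        numerically must agree with the closed form to 1e-9 relative."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            an = rng.uniform(1, 30)
            rd = rng.uniform(0.2, 2.0)
            ci = rng.uniform(150, 1200)
            j = 4 * (an + rd) * rng.uniform(1.2, 4.0)
            try:
                gm = variable_j_gm(an, ci, j, rd)
            except GasExchangeError:
                continue
            if not 1e-4 < gm < 10:
                continue

            def resid(a):
                x = a + rd
                return a - gm * (ci - GAMMA_STAR_30C * (j + 8 * x) / (j - 4 * x))

            an_back = brentq(resid, 1e-9, (j / 4 - rd) * (1 - 1e-12),
                             xtol=1e-14, rtol=1e-15)
            assert an_back == pytest.approx(an, rel=1e-9)
            checked += 1


class TestFitAci:
    def test_noiseless_round_trip(self, identifiable_params, noiseless_curve):
        fit = fit_aci(noiseless_curve, gm=0.25)
        p = identifiable_params
        assert fit.params.vcmax == pytest.approx(p.vcmax, rel=1e-2)
        assert fit.params.jmax == pytest.approx(p.jmax, rel=1e-2)
        assert fit.params.tpu == pytest.approx(p.tpu, rel=1e-2)
        assert fit.params.rd == pytest.approx(p.rd, rel=1e-2)
        assert fit.tpu_evident
        assert fit.rmse < 1e-6
        assert fit.unidentifiable == ()

    def test_predictions_are_minimum_and_amax_bounds_observed(self, noiseless_curve):
        fit = fit_aci(noiseless_curve, gm=0.25)
        stacked = np.stack([fit.a_c, fit.a_j, fit.a_p])
        assert np.allclose(fit.a_n, np.nanmin(stacked, axis=0))
        assert fit.amax >= np.max(noiseless_curve.an) - 1e-12

    def test_too_few_points(self):
        c = make_curve([100, 300, 800], [5, 15, 25])
        with pytest.raises(GasExchangeError):
            fit_aci(c, gm=0.25)

    def test_truncated_curve_flags_jmax_unidentifiable(self, identifiable_params):
        spec = SimSpec(params=identifiable_params,
                       ca_setpoints=(50.0, 100.0, 150.0, 200.0, 250.0),
                       noise_sd=0.0)
        curve = simulate_aci(spec)[0]
        assert np.all(curve.ci <= 250)
        fit = fit_aci(curve, gm=0.25)
        assert "jmax" in fit.unidentifiable
        assert fit.params.vcmax == pytest.approx(identifiable_params.vcmax,
                                                 rel=1e-2)

    def test_unbounded_gm_equals_fit_on_cc(self):
        """With gm unbounded Cc = Ci, so fitting a curve simulated without
        a mesophyll resistance recovers the generating parameters."""
        p = FvcbParams(vcmax=100, jmax=150, tpu=11.0, rd=1.0, gm=None)
        curve = simulate_aci(SimSpec(params=p,
                                     ca_setpoints=full_protocol_setpoints(),
                                     noise_sd=0.0))[0]
        fit = fit_aci(curve, gm=None)
        assert fit.params.vcmax == pytest.approx(100, rel=1e-2)
        assert fit.params.jmax == pytest.approx(150, rel=1e-2)

    def test_noisy_replicates_recover_within_ten_percent(self, identifiable_params):
        spec = SimSpec(params=identifiable_params,
                       ca_setpoints=full_protocol_setpoints(),
                       noise_sd=0.5, replicates=30, seed=7)
        errs_v, errs_j = [], []
        for curve in simulate_aci(spec):
            fit = fit_aci(curve, gm=0.25)
            errs_v.append(abs(fit.params.vcmax / 100.0 - 1))
            errs_j.append(abs(fit.params.jmax / 150.0 - 1))
        assert np.median(errs_v) < 0.10
        assert np.median(errs_j) < 0.10


class TestDetectTpu:
    def test_plateau_detected(self, noiseless_curve):
        fit = fit_aci(noiseless_curve, gm=0.25, detect_tpu=False)
        assert detect_tpu_limitation(noiseless_curve, fit, gm=0.25)

    def test_increasing_tail_not_detected(self):
        p = FvcbParams(vcmax=100, jmax=150, rd=1.0, gm=0.25)
        curve = simulate_aci(SimSpec(params=p, noise_sd=0.0))[0]
        fit = fit_aci(curve, gm=0.25, detect_tpu=False)
        assert not detect_tpu_limitation(curve, fit, gm=0.25)

    def test_two_point_curve_errors(self):
        c = make_curve([800, 1200], [20, 20])
        fit_stub = None
        with pytest.raises(GasExchangeError):
            detect_tpu_limitation(c, fit_stub, k=2)


class TestAmax:
    def test_maximum_and_normalizations(self):
        c = make_curve([100, 300, 700, 1000], [5, 12, 20, 19])
        out = amax_and_normalize(c, l_leaf=200.0, lma=10.0)
        assert out["amax"] == 20.0
        assert out["amax_per_thickness"] == pytest.approx(0.10)
        assert out["amax_per_mass"] == pytest.approx(2.0)

    def test_nonpositive_normalizers_rejected(self):
        c = make_curve([100, 300], [5, 12])
        with pytest.raises(GasExchangeError):
            amax_and_normalize(c, l_leaf=0.0)
        with pytest.raises(GasExchangeError):
            amax_and_normalize(c, lma=-3.0)


class TestLaisk:
    def test_two_line_analytic_intersection(self):
        ci = np.array([40.0, 80.0, 120.0, 150.0])
        c1 = make_curve(ci, 0.05 * ci - 3.0, species="s1")
        c2 = make_curve(ci, 0.10 * ci - 5.5, species="s2")
        res = laisk_rd_cistar([c1, c2])
        assert res.ci_star == pytest.approx(50.0, abs=1e-9)
        assert res.rd == pytest.approx(0.5, abs=1e-9)
        assert res.intercept_an == pytest.approx(-0.5, abs=1e-9)

    def test_three_exact_lines_machine_precision_and_zero_se(self):
        ci = np.array([30.0, 70.0, 110.0, 140.0])
        curves = [make_curve(ci, m * (ci - 50.0) - 0.5, species=f"s{i}")
                  for i, m in enumerate((0.04, 0.07, 0.10))]
        res = laisk_rd_cistar(curves)
        assert res.ci_star == pytest.approx(50.0, abs=1e-10)
        assert res.rd == pytest.approx(0.5, abs=1e-10)
        assert res.se_ci_star == pytest.approx(0.0, abs=1e-7)
        assert res.se_rd == pytest.approx(0.0, abs=1e-8)

    def test_parallel_lines_error(self):
        ci = np.array([40.0, 80.0, 120.0])
        c1 = make_curve(ci, 0.05 * ci - 3.0)
        c2 = make_curve(ci, 0.05 * ci - 3.0)
        with pytest.raises(GasExchangeError):
            laisk_rd_cistar([c1, c2])

    def test_curve_without_low_ci_points_excluded(self):
        ci_low = np.array([40.0, 80.0, 120.0])
        good = [make_curve(ci_low, m * (ci_low - 50.0) - 0.5, species=f"g{i}")
                for i, m in enumerate((0.04, 0.08))]
        bad = make_curve(np.array([300.0, 500.0]), np.array([10.0, 15.0]))
        with pytest.warns(UserWarning):
            res = laisk_rd_cistar(good + [bad])
        assert res.n_lines == 2


class TestExtractAtCa:
    def test_exact_and_tolerant_match(self):
        c = make_curve([300, 360, 550], [10, 12, 18])
        c.ca_setpoint = np.array([340.0, 410.0, 600.0])
        out = extract_at_ca(c, 400.0)
        assert out["ca_setpoint"] == 410.0
        assert out["an"] == 12.0

    def test_no_setpoint_within_tolerance(self):
        c = make_curve([500, 900], [15, 20])
        c.ca_setpoint = np.array([600.0, 1000.0])
        with pytest.raises(GasExchangeError):
            extract_at_ca(c, 400.0)


class TestGmProfile:
    def test_noiseless_profile_recovers_true_gm(self, identifiable_params):
        spec = SimSpec(params=identifiable_params,
                       ca_setpoints=full_protocol_setpoints(), noise_sd=0.0)
        curve = simulate_aci(spec)[0]
        prof = fluorescence_gm_profile(
            curve, identifiable_params.rd,
            FluorescenceConfig.for_habit("deciduous"))
        valid = prof[np.isfinite(prof)]
        assert valid.size >= 5
        assert np.allclose(valid, 0.25, rtol=1e-6)
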