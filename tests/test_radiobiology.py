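"""LQ fitting, iso-effect inversion, and beam-RBE / CBE estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from bnctkit.dosimetry import DoseComponents, RBEWeights, photon_equivalent
from bnctkit.radiobiology import (
    LQParams,
    analyze_clonogenic,
    bootstrap_effectiveness,
    colony_sf,
    curve_iso_dose,
    dose_at_sf,
    estimate_cbe,
    estimate_rbe_beam,
    fit_lq,
    survival_at,
)


class TestColonySF:
    def test_ratio_and_identity(self):
        assert colony_sf(50, 50) == 1.0
        assert colony_sf(5, 50) == pytest.approx(0.1)

    def test_zero_control_is_an_error(self):
        with pytest.raises(ValueError):
            colony_sf(5, 0)

    def test_zero_treated_policy(self):
        with pytest.raises(ValueError):
            colony_sf(0, 50)
        assert colony_sf(0, 50, zero_policy="floor") == pytest.approx(0.01)

    def test_above_one_warns_and_clips(self):
        with pytest.warns(UserWarning):
            assert colony_sf(60, 50) == 1.0


class TestFitLQ:
    def test_noiseless_parameter_recovery(self):
        alpha, beta = 0.2, 0.02
        doses = np.array([1.0, 2.0, 4.0, 6.0, 8.0])
        sf = np.exp(-alpha * doses - beta * doses**2)
        params = fit_lq(doses, sf)
        assert params.alpha == pytest.approx(alpha, abs=1e-6)
        assert params.beta == pytest.approx(beta, abs=1e-6)

    def test_flat_curve_gives_zero_parameters(self):
        params = fit_lq(np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0]))
        assert params.alpha == 0.0
        assert params.beta == 0.0

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            fit_lq(np.array([2.0, 2.0, 2.0]), np.array([0.5, 0.5, 0.5]))

    def test_poisson_noise_recovery_within_ten_percent(self):
        alpha, beta, control = 0.2, 0.02, 200
        doses = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
        rng = np.random.default_rng(12345)
        rel_errs = []
        for _ in range(50):
            expected = control * np.exp(-alpha * doses - beta * doses**2)
            treated = rng.poisson(expected)
            ctrl = np.maximum(rng.poisson(control, size=len(doses)), 1)
            sf = np.array([
                colony_sf(t, c, zero_policy="floor") for t, c in zip(treated, ctrl)
            ])
            p = fit_lq(doses, sf)
            rel_errs.append(abs(dose_at_sf(p, 0.1) / dose_at_sf(LQParams(alpha, beta), 0.1) - 1))
        assert np.mean(rel_errs) < 0.10


class TestDoseAtSF:
    def test_matches_bisection_oracle(self):
        params = LQParams(alpha=0.2, beta=0.02)
        analytic = dose_at_sf(params, 0.1)
        bisected = brentq(lambda d: survival_at(params, d) - 0.1, 1e-9, 100.0, xtol=1e-12)
        assert analytic == pytest.approx(bisected, abs=1e-9)
        assert analytic == pytest.approx(6.838, abs=5e-4)

    def test_pure_linear_closed_form(self):
        alpha = 1.7
        assert dose_at_sf(LQParams(alpha, 0.0), math.exp(-alpha)) == pytest.approx(1.0, rel=1e-12)

    @given(
        alpha=st.floats(0.01, 1.0),
        beta=st.floats(0.0, 0.2),
        sf=st.floats(0.001, 0.99),
    )
    def test_round_trip_inverse(self, alpha, beta, sf):
        params = LQParams(alpha, beta)
        assert survival_at(params, dose_at_sf(params, sf)) == pytest.approx(sf, abs=1e-9)

    @given(alpha=st.floats(0.05, 1.0), beta=st.floats(0.001, 0.2))
    def test_strictly_decreasing_in_level_and_parameters(self, alpha, beta):
        p = LQParams(alpha, beta)
        assert dose_at_sf(p, 0.05) > dose_at_sf(p, 0.1) > dose_at_sf(p, 0.5)
        assert dose_at_sf(LQParams(alpha * 1.5, beta), 0.1) < dose_at_sf(p, 0.1)
        assert dose_at_sf(LQParams(alpha, beta * 1.5), 0.1) < dose_at_sf(p, 0.1)

    def test_no_kill_is_an_error(self):
        with pytest.raises(ValueError):
            dose_at_sf(LQParams(0.0, 0.0), 0.1)


class TestCurveIsoDose:
    def test_lq_mode_consistent_with_direct_inversion(self):
        params = LQParams(0.3, 0.03)
        doses = np.array([0.5, 1.0, 2.0, 4.0, 6.0])
        sf = np.array([survival_at(params, d) for d in doses])
        assert curve_iso_dose(doses, sf, 0.1, method="lq") == pytest.approx(
            dose_at_sf(params, 0.1), rel=1e-9
        )

    def test_log_linear_interpolation_two_points(self):
        # ln-linear between (1 Gy, SF 0.5) and (3 Gy, SF 0.05) at SF 0.1:
        # 1 + 2 * ln(0.5/0.1) / ln(0.5/0.05)
        expected = 1.0 + 2.0 * math.log(5.0) / math.log(10.0)
        got = curve_iso_dose(
            np.array([1.0, 3.0]), np.array([0.5, 0.05]), 0.1, method="loglinear"
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_log_linear_requires_bracketing(self):
        with pytest.raises(ValueError):
            curve_iso_dose(
                np.array([1.0, 2.0]), np.array([0.9, 0.5]), 0.1, method="loglinear"
            )

    def test_non_monotone_curve_warns_and_smooths(self):
        doses = np.array([1.0, 2.0, 3.0, 4.0])
        sf = np.array([0.8, 0.3, 0.4, 0.05])
        with pytest.warns(UserWarning):
            iso = curve_iso_dose(doses, sf, 0.1, method="loglinear")
        assert 3.0 < iso < 4.0


class TestEffectivenessAlgebra:
    def test_rbe_beam_fixture(self):
        comps = DoseComponents(d_b=0.0, d_n=0.99, d_h=1.0, d_gamma=0.48)
        assert estimate_rbe_beam(6.45, comps) == pytest.approx(3.0)

    def test_rbe_beam_gamma_free_limit(self):
        comps = DoseComponents(0.0, 1.0, 1.0, 0.0)
        assert estimate_rbe_beam(6.0, comps) == pytest.approx(3.0)

    def test_rbe_beam_scale_invariance(self):
        # scaling the beam components with a matching photon-equivalent
        # requirement leaves the estimate unchanged
        comps = DoseComponents(0.0, 0.4, 0.8, 0.5)
        rbe = estimate_rbe_beam(4.1, comps)
        k = 2.5
        scaled = DoseComponents(0.0, k * 0.4, k * 0.8, k * 0.5)
        lq_iso_scaled = rbe * k * 1.2 + k * 0.5
        assert estimate_rbe_beam(lq_iso_scaled, scaled) == pytest.approx(rbe, rel=1e-12)

    def test_rbe_beam_errors(self):
        with pytest.raises(ValueError):
            estimate_rbe_beam(6.45, DoseComponents(0.1, 0.5, 0.5, 0.1))
        with pytest.raises(ValueError):
            estimate_rbe_beam(6.45, DoseComponents(0.0, 0.0, 0.0, 0.5))

    @given(
        d_b=st.floats(0.05, 5.0),
        d_n=st.floats(0.0, 2.0),
        d_h=st.floats(0.0, 2.0),
        d_g=st.floats(0.0, 2.0),
        cbe=st.floats(0.5, 12.0),
        rbe=st.floats(0.5, 5.0),
    )
    def test_cbe_is_exact_inverse_of_photon_equivalent(self, d_b, d_n, d_h, d_g, cbe, rbe):
        comps = DoseComponents(d_b, d_n, d_h, d_g)
        lq_iso = photon_equivalent(comps, RBEWeights(cbe, rbe, rbe))
        assert estimate_cbe(lq_iso, comps, rbe) == pytest.approx(cbe, abs=1e-9)

    def test_cbe_planted_value_recovered(self):
        rbe, cbe_true, lq_iso = 3.0, 8.43, 6.45
        non_boron = DoseComponents(0.0, 0.1, 0.2, 0.3)
        d_b = (lq_iso - rbe * 0.3 - 0.3) / cbe_true
        comps = DoseComponents(d_b, 0.1, 0.2, 0.3)
        assert estimate_cbe(lq_iso, comps, rbe) == pytest.approx(cbe_true, abs=1e-9)

    def test_cbe_boron_only_limit(self):
        assert estimate_cbe(6.0, DoseComponents(2.0, 0.0, 0.0, 0.0), 3.0) == pytest.approx(3.0)

    def test_cbe_errors(self):
        with pytest.raises(ValueError):
            estimate_cbe(6.45, DoseComponents(0.0, 0.5, 0.5, 0.5), 3.0)
        with pytest.raises(ValueError):
            estimate_cbe(1.0, DoseComponents(0.5, 1.0, 1.0, 1.0), 3.0)


class TestAnalyzeClonogenic:
    def test_noiseless_pipeline_recovers_planted_truth(self, gen_config, noiseless_effectiveness):
        cfg = gen_config.clonogenic
        est = noiseless_effectiveness
        assert est.lq_iso == pytest.approx(cfg.lq_iso_gy, rel=1e-9)
        assert est.rbe_beam == pytest.approx(cfg.rbe_beam, rel=1e-9)
        for compound in cfg.compounds:
            assert est.iso_doses[compound.label] == pytest.approx(compound.iso_gy, rel=1e-9)
            assert est.cbe_by_compound[compound.label] == pytest.approx(compound.cbe, rel=1e-9)

    def test_missing_condition_rejected(self, noiseless_clonogenic):
        df = noiseless_clonogenic[noiseless_clonogenic.condition != "X-ray"]
        with pytest.raises(ValueError):
            analyze_clonogenic(df)

    def test_bootstrap_intervals_cover_planted_truth(self, gen_config):
        from bnctkit.synthetic import gen_clonogenic

        df = gen_clonogenic(gen_config.clonogenic, np.random.default_rng(11))
        est = analyze_clonogenic(df, zero_policy="floor")
        boot = bootstrap_effectiveness(df, n_boot=200, seed=3)
        lo, hi = boot["cbe:DPA-BSTPG"]["ci"]
        assert lo < 8.43 < hi
        # percentile interval brackets the point estimate it resamples around
        lo, hi = boot["rbe_beam"]["ci"]
        assert lo < est.rbe_beam < hi
        assert boot["_meta"]["failures"] < 20
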