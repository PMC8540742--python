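"""Inner-filter correction, Stern-Volmer / double-log regressions and the
mechanism / site-competition classification rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import albind as ab
from albind.errors import FitError, ValidationError

from conftest import make_series


class TestInnerFilter:
    @pytest.mark.parametrize(
        "F, aex, aem, expected",
        [
            (100.0, 0.0, 0.0, 100.0),
            (100.0, 0.2, 0.1, 141.2538),  # 100 * 10**0.15
            (50.0, 0.4, 0.4, 125.5943),  # 50 * 10**0.4
        ],
    )
    def test_correction_values(self, F, aex, aem, expected):
        assert ab.correct_inner_filter(F, aex, aem) == pytest.approx(expected, abs=1e-4)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValidationError):
            ab.correct_inner_filter(100.0, -0.1, 0.0)

    @given(
        F=st.floats(1e-3, 1e6),
        aex=st.floats(0.0, 2.0),
        aem=st.floats(0.0, 2.0),
    )
    def test_monotone_and_invertible(self, F, aex, aem):
        corr = ab.correct_inner_filter(F, aex, aem)
        assert corr >= F
        # applying the exact inverse recovers the observation
        back = corr / 10.0 ** ((aex + aem) / 2.0)
        assert back == pytest.approx(F, rel=1e-12)
        # monotone in total absorbance
        assert ab.correct_inner_filter(F, aex + 0.1, aem) > corr


class TestSternVolmer:
    def test_exact_line_recovery(self):
        series = make_series(Ksv=1e5, conc=np.arange(2e-7, 2.01e-6, 2e-7))
        fit = ab.fit_stern_volmer(series)
        assert fit.K_SV == pytest.approx(1e5, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert not fit.intercept_warning

    def test_constant_intensity_gives_zero_slope(self):
        points = [ab.TitrationPoint(0.0, 500.0)] + [
            ab.TitrationPoint(q, 500.0) for q in (1e-7, 2e-7, 3e-7, 4e-7)
        ]
        fit = ab.fit_stern_volmer(ab.TitrationSeries(297.0, points))
        assert fit.K_SV == 0.0

    def test_noisy_slope_equals_normal_equation_solution(self):
        rng = np.random.default_rng(11)
        conc = np.arange(2e-7, 2.01e-6, 2e-7)
        F0 = 1000.0
        F = F0 / (1.0 + 1e5 * conc) + rng.normal(0, 0.005 * F0, conc.shape)
        points = [ab.TitrationPoint(0.0, F0)] + [
            ab.TitrationPoint(float(q), float(f)) for q, f in zip(conc, F)
        ]
        fit = ab.fit_stern_volmer(ab.TitrationSeries(297.0, points))
        # independent oracle: normal equations via lstsq on the same data
        A = np.column_stack([conc, np.ones_like(conc)])
        slope, intercept = np.linalg.lstsq(A, F0 / F, rcond=None)[0]
        assert fit.K_SV == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)

    def test_kq_scales_inversely_with_tau0(self):
        series = make_series()
        kq1 = ab.fit_stern_volmer(series, tau0=1e-8).k_q
        kq2 = ab.fit_stern_volmer(series, tau0=5e-9).k_q
        assert kq2 == pytest.approx(2.0 * kq1, rel=1e-12)

    def test_too_few_points_is_a_fit_error(self):
        points = [
            ab.TitrationPoint(0.0, 1000.0),
            ab.TitrationPoint(1e-7, 990.0),
            ab.TitrationPoint(2e-7, 980.0),
        ]
        with pytest.raises(FitError):
            ab.fit_stern_volmer(ab.TitrationSeries(297.0, points))

    @given(st.integers(0, 2**31 - 1))
    def test_ols_matches_lstsq_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0.1, 10.0, size=8))
        y = rng.normal(size=8)
        from albind.quenching import _ols

        slope, intercept, r2, _ = _ols(x, y)
        A = np.column_stack([x, np.ones_like(x)])
        s2, i2 = np.linalg.lstsq(A, y, rcond=None)[0]
        assert slope == pytest.approx(s2, rel=1e-9, abs=1e-12)
        assert intercept == pytest.approx(i2, rel=1e-9, abs=1e-12)
        assert 0.0 <= r2 <= 1.0 + 1e-12


class TestMechanism:
    def _fit(self, ksv, T, tau0=1e-8):
        return ab.SternVolmerFit(
            K_SV=ksv, intercept=1.0, tau0=tau0, r2=1.0, stderr_KSV=0.0, temperature=T
        )

    def test_decreasing_ksv_and_high_kq_is_static(self):
        fits = [self._fit(k, T) for k, T in zip((1.2e5, 1.0e5, 0.8e5), (297, 303, 308))]
        call = ab.classify_mechanism(fits)
        assert call.verdict == "static"
        assert call.ksv_trend == "decreasing"
        assert all(call.kq_exceeds_threshold)

    def test_increasing_ksv_and_low_kq_is_dynamic(self):
        # k_q = K_SV/tau0 = 1e9 < 2e10 with tau0 = 1e-4 s
        fits = [self._fit(k, T, tau0=1e-4) for k, T in zip((0.8e5, 1.0e5, 1.2e5), (297, 303, 308))]
        call = ab.classify_mechanism(fits)
        assert call.verdict == "dynamic"
        assert not any(call.kq_exceeds_threshold)

    def test_non_monotone_ksv_is_ambiguous(self):
        fits = [self._fit(k, T) for k, T in zip((1.0e5, 1.2e5, 0.8e5), (297, 303, 308))]
        assert ab.classify_mechanism(fits).verdict == "ambiguous"

    def test_mixed_evidence_is_ambiguous(self):
        # decreasing K_SV but k_q below the scatter-collision limit
        fits = [self._fit(k, T, tau0=1e-4) for k, T in zip((1.2e5, 1.0e5), (297, 308))]
        assert ab.classify_mechanism(fits).verdict == "ambiguous"

    def test_duplicate_temperatures_rejected(self):
        fits = [self._fit(1e5, 297), self._fit(9e4, 297)]
        with pytest.raises(ValidationError):
            ab.classify_mechanism(fits)


class TestDoubleLog:
    @pytest.mark.parametrize(
        "Kb, n, rel",
        [(1e5, 1.0, 1e-3), (5e4, 1.2, 5e-3)],
    )
    def test_generator_round_trip(self, Kb, n, rel):
        conc = np.arange(1e-7, 2.01e-6, 2e-7)
        F0 = 1000.0
        points = [ab.TitrationPoint(0.0, F0)] + [
            ab.TitrationPoint(float(q), F0 / (1.0 + Kb * q**n)) for q in conc
        ]
        fit = ab.fit_double_log(ab.TitrationSeries(297.0, points))
        assert fit.Kb == pytest.approx(Kb, rel=rel)
        assert fit.n_sites == pytest.approx(n, rel=rel)
        assert fit.Kb == pytest.approx(10.0**fit.log10_Kb, rel=1e-12)

    def test_unquenched_series_is_a_fit_error(self):
        points = [ab.TitrationPoint(0.0, 1000.0)] + [
            ab.TitrationPoint(q, 1000.0) for q in (1e-7, 2e-7, 3e-7, 4e-7)
        ]
        with pytest.raises(FitError):
            ab.fit_double_log(ab.TitrationSeries(297.0, points))

    def test_non_quenched_points_excluded_with_warning(self):
        conc = np.arange(1e-7, 1.01e-6, 1e-7)
        F0 = 1000.0
        F = F0 / (1.0 + 1e5 * conc)
        F[0] = F0 + 5.0  # apparent negative quenching at the first addition
        points = [ab.TitrationPoint(0.0, F0)] + [
            ab.TitrationPoint(float(q), float(f)) for q, f in zip(conc, F)
        ]
        with pytest.warns(UserWarning, match="excluded"):
            fit = ab.fit_double_log(ab.TitrationSeries(297.0, points))
        assert fit.n_points_excluded == 1
        assert fit.n_points_used == len(conc) - 1

    def test_stern_volmer_equals_kb_for_one_to_one_static_model(self):
        # with n = 1 the static-quenching model is exactly the SV line
        series = make_series(Ksv=7.5e4)
        sv = ab.fit_stern_volmer(series)
        dl = ab.fit_double_log(series)
        assert sv.K_SV == pytest.approx(dl.Kb, rel=1e-3)
        assert dl.n_sites == pytest.approx(1.0, rel=1e-3)


class TestSiteCompetition:
    def _fit(self, kb, marker, T=297.0):
        return ab.BindingFit(
            log10_Kb=np.log10(kb), n_sites=1.0, r2=1.0, n_points_used=10,
            temperature=T, marker=marker,
        )

    def test_stronger_ibp_suppression_implicates_site_II(self):
        call = ab.assess_site_competition(
            self._fit(1.0e5, "none"), self._fit(0.9e5, "PHB"), self._fit(0.5e5, "IBP")
        )
        assert call.site == "site_II_IIIA"

    def test_stronger_phb_suppression_implicates_site_I(self):
        call = ab.assess_site_competition(
            self._fit(1.0e5, "none"), self._fit(0.4e5, "PHB"), self._fit(0.9e5, "IBP")
        )
        assert call.site == "site_I_IIA"

    def test_marker_enhanced_binding_is_indeterminate(self):
        call = ab.assess_site_competition(
            self._fit(1.0e5, "none"), self._fit(1.2e5, "PHB"), self._fit(0.9e5, "IBP")
        )
        assert call.site == "indeterminate"

    def test_mismatched_temperatures_rejected(self):
        with pytest.raises(ValidationError):
            ab.assess_site_competition(
                self._fit(1e5, "none", 297.0),
                self._fit(9e4, "PHB", 303.0),
                self._fit(5e4, "IBP", 297.0),
            )
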