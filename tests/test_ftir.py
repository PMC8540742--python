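"""Amide-I region extraction, component seeding, Gaussian fitting and
structure-class quantification."""

import math

import numpy as np
import pytest

import albind as ab
from albind.errors import AnalysisError, ValidationError
from albind.ftir import GAUSS_AREA_FACTOR, assign_structure

_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # fwhm per sigma


def gaussian_sum(x, bands):
    """bands: list of (center, fwhm, area)."""
    y = np.zeros_like(x)
    for center, fwhm, area in bands:
        sigma = fwhm / _SIGMA
        height = area / (fwhm * GAUSS_AREA_FACTOR)
        y += height * np.exp(-((x - center) ** 2) / (2 * sigma**2))
    return y


def ir_spectrum(bands, lo=1580.0, hi=1720.0, baseline=0.0, tilt=0.0):
    x = np.arange(lo, hi + 0.25, 0.5)
    y = gaussian_sum(x, bands) + baseline + tilt * (x - lo)
    return ab.Spectrum(x, y, "wavenumber_cm-1")


class TestExtractRegion:
    def test_window_slice_has_unit_integral(self):
        spec = ir_spectrum([(1655.0, 14.0, 1.0)], lo=600.0, hi=4000.0)
        region = ab.extract_amide_region(spec)
        assert region.x[0] >= 1600.0 and region.x[-1] <= 1700.0
        assert np.trapezoid(region.y, region.x) == pytest.approx(1.0, rel=1e-9)

    def test_flat_spectrum_has_near_zero_baseline_slope(self):
        spec = ir_spectrum([(1655.0, 14.0, 1.0)], baseline=0.3)
        region = ab.extract_amide_region(spec)
        assert region.baseline_params[0] == pytest.approx(0.0, abs=1e-6)

    def test_linear_tilt_is_removed(self):
        flat = ab.extract_amide_region(ir_spectrum([(1655.0, 14.0, 1.0)]))
        tilted = ab.extract_amide_region(
            ir_spectrum([(1655.0, 14.0, 1.0)], tilt=2e-4, baseline=0.05)
        )
        assert tilted.y == pytest.approx(flat.y, abs=1e-6)

    def test_window_not_covered_rejected(self):
        x = np.arange(1620.0, 1700.5, 0.5)
        spec = ab.Spectrum(x, np.exp(-((x - 1655.0) ** 2) / 50.0), "wavenumber_cm-1")
        with pytest.raises(ValidationError):
            ab.extract_amide_region(spec)


class TestLocateComponents:
    def test_single_gaussian_seed_at_its_center(self):
        region = ab.extract_amide_region(ir_spectrum([(1655.0, 14.0, 1.0)]))
        seeds = ab.locate_components(region)
        assert len(seeds) == 1
        assert seeds[0] == pytest.approx(1655.0, abs=1.0)

    def test_two_gaussians_seed_near_both_centers(self):
        region = ab.extract_amide_region(
            ir_spectrum([(1632.0, 15.0, 0.5), (1658.0, 15.0, 0.5)])
        )
        seeds = ab.locate_components(region)
        assert len(seeds) >= 2
        assert min(abs(seeds - 1632.0)) <= 2.0
        assert min(abs(seeds - 1658.0)) <= 2.0

    def test_featureless_region_is_an_analysis_error(self):
        x = np.arange(1580.0, 1720.5, 0.5)
        rng = np.random.default_rng(3)
        # broad hump with faint noise: no second-derivative minimum survives
        y = 1.0 + 1e-9 * rng.normal(size=x.shape) + 1e-4 * (x - 1580.0)
        spec = ab.Spectrum(x, y, "wavenumber_cm-1")
        with pytest.raises((AnalysisError, ValidationError)):
            region = ab.extract_amide_region(spec)
            ab.locate_components(region)


class TestFitBandComponents:
    BANDS = [(1632.0, 16.0, 0.292), (1658.0, 14.0, 0.538), (1685.0, 10.0, 0.170)]

    def test_noiseless_three_band_recovery_within_two_percent(self):
        region = ab.extract_amide_region(ir_spectrum(self.BANDS))
        seeds = ab.locate_components(region)
        fit = ab.fit_band_components(region, seeds)
        assert len(fit) == 3
        got = sorted((c.center, c.area) for c in fit)
        total = sum(a for _, a in got)
        for (center, _, area), (c_fit, a_fit) in zip(sorted(self.BANDS), got):
            assert c_fit == pytest.approx(center, abs=1.0)
            assert a_fit / total == pytest.approx(area, rel=0.02)

    def test_single_component_fits_to_machine_precision(self):
        region = ab.extract_amide_region(ir_spectrum([(1655.0, 14.0, 1.0)]))
        fit = ab.fit_band_components(region, [1655.0])
        assert len(fit) == 1
        assert fit.residual_rms <= 1e-8

    def test_refit_from_fitted_centers_is_a_fixed_point(self):
        region = ab.extract_amide_region(ir_spectrum(self.BANDS))
        first = ab.fit_band_components(region, ab.locate_components(region))
        second = ab.fit_band_components(region, [c.center for c in first])
        for a, b in zip(first, second):
            assert b.center == pytest.approx(a.center, abs=1e-6)
            assert b.area == pytest.approx(a.area, rel=1e-6)

    def test_component_area_matches_gaussian_closed_form(self):
        region = ab.extract_amide_region(ir_spectrum(self.BANDS))
        fit = ab.fit_band_components(region, ab.locate_components(region))
        for c in fit:
            assert c.area == pytest.approx(
                c.amplitude * c.fwhm * GAUSS_AREA_FACTOR, rel=1e-9
            )
            assert 5.0 <= c.fwhm <= 25.0

    def test_seed_outside_window_rejected(self):
        region = ab.extract_amide_region(ir_spectrum(self.BANDS))
        with pytest.raises(ValidationError):
            ab.fit_band_components(region, [1590.0])


class TestQuantifyStructure:
    def _component(self, center, area, fwhm=12.0):
        height = area / (fwhm * GAUSS_AREA_FACTOR)
        cls, flagged = assign_structure(center)
        return ab.BandComponent(center=center, fwhm=fwhm, amplitude=height,
                                assignment=cls, flagged=flagged)

    def test_free_bsa_composition(self):
        comps = [
            self._component(1655.0, 0.538),
            self._component(1632.0, 0.292),
            self._component(1685.0, 0.170),
        ]
        structure = ab.quantify_structure(comps)
        assert structure.percent_by_class["alpha_helix"] == pytest.approx(53.8, abs=1e-9)
        assert structure.percent_by_class["beta_sheet"] == pytest.approx(29.2, abs=1e-9)
        assert structure.percent_by_class["beta_turn"] == pytest.approx(17.0, abs=1e-9)

    def test_single_component_is_100_percent(self):
        structure = ab.quantify_structure([self._component(1645.0, 0.7)])
        assert structure.percent_by_class == {"random_coil": pytest.approx(100.0)}

    @pytest.mark.parametrize(
        "center, cls",
        [
            (1615.0, "beta_sheet"),
            (1645.0, "random_coil"),
            (1655.0, "alpha_helix"),
            (1685.0, "beta_turn"),
            (1695.0, "beta_antiparallel"),
            (1640.0, "random_coil"),  # half-open boundaries
            (1650.0, "alpha_helix"),
        ],
    )
    def test_assignment_ranges(self, center, cls):
        assert assign_structure(center)[0] == cls

    def test_gap_region_is_flagged_beta_turn(self):
        cls, flagged = assign_structure(1670.0)
        assert cls == "beta_turn" and flagged

    def test_center_outside_window_rejected(self):
        with pytest.raises(ValidationError):
            assign_structure(1705.0)

    def test_percentages_sum_to_100(self):
        comps = [self._component(c, a) for c, a in
                 [(1615.0, 0.2), (1645.0, 0.1), (1655.0, 0.4), (1695.0, 0.3)]]
        structure = ab.quantify_structure(comps)
        assert sum(structure.percent_by_class.values()) == pytest.approx(100.0, abs=1e-6)


class TestEndToEnd:
    def test_default_composition_recovered_within_two_points(self):
        scenario = ab.StructureScenario(seed=5)  # 0.2% noise
        result = ab.AmideIModel(ab.simulate_ftir_spectrum(scenario)).fit()
        pct = result.structure.percent_by_class
        assert pct["alpha_helix"] == pytest.approx(53.8, abs=2.0)
        assert pct["beta_sheet"] == pytest.approx(29.2, abs=2.0)
        assert pct["beta_turn"] == pytest.approx(17.0, abs=2.0)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)

    def test_intensity_scale_invariance(self):
        scenario = ab.StructureScenario(noise_sigma=0.0)
        spec = ab.simulate_ftir_spectrum(scenario)
        scaled = ab.Spectrum(spec.x, 7.3 * spec.y, "wavenumber_cm-1")
        a = ab.AmideIModel(spec).fit().structure.percent_by_class
        b = ab.AmideIModel(scaled).fit().structure.percent_by_class
        for cls in a:
            assert b[cls] == pytest.approx(a[cls], rel=1e-6)

    def test_single_class_spectrum_reads_100_percent(self):
        scenario = ab.StructureScenario(
            class_fractions={"alpha_helix": 1.0}, noise_sigma=0.0
        )
        result = ab.AmideIModel(ab.simulate_ftir_spectrum(scenario)).fit()
        assert result.structure.percent_by_class["alpha_helix"] == pytest.approx(
            100.0, abs=1e-6
        )
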