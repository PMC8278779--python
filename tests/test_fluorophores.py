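"""Fluorophore bases, the linear forward model, and phenotype templates."""

import numpy as np
import pytest

from dermafluor.fluorophores import (
    DEFAULT_TEMPLATE_WEIGHTS,
    SK_MELANIN_WEIGHT,
    Phenotype,
    basis_gaussian,
    basis_melanin,
    basis_shg,
    calibrate_sk_melanin_weight,
    compose,
    compose_template,
)
from dermafluor.classify import RuleBasedSpectralTyper, SpectralFeaturizer
from dermafluor.preprocess import _moving_average


class TestBases:
    def test_shg_line_sits_at_half_the_excitation(self, grid):
        assert basis_shg(800.0, 5.0, grid=grid).peak_nm == 400.0
        assert basis_shg(760.0, 5.0, grid=grid).peak_nm == 380.0

    def test_shg_line_is_negligible_far_from_center(self, grid):
        b = basis_shg(800.0, 5.0, grid=grid)
        # 475 nm is 15 sigma from the line center
        assert b.values[grid.index_of(475.0)] < 1e-6

    def test_shg_center_off_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside"):
            basis_shg(700.0, 5.0, grid=grid)  # 350 nm < grid start

    @pytest.mark.parametrize("name,peak,fwhm", [("NADH", 450.0, 60.0),
                                                ("KERATIN", 470.0, 80.0)])
    def test_gaussian_band_peaks_where_told(self, grid, name, peak, fwhm):
        b = basis_gaussian(name, peak, fwhm, grid=grid)
        assert grid.wavelengths[np.argmax(b.values)] == peak
        assert b.values.max() == 1.0

    def test_gaussian_band_is_symmetric(self, grid):
        b = basis_gaussian("NADH", 450.0, 60.0, grid=grid)
        i = grid.index_of(450.0)
        np.testing.assert_allclose(b.values[i - 30:i], b.values[i + 30:i:-1])

    def test_melanin_tail_strictly_rises_through_the_red(self, grid):
        b = basis_melanin(grid=grid)
        sl = grid.band_slice(430.0, 650.0)
        assert np.all(np.diff(b.values[sl]) > 0)
        # every 10 nm step increases
        v = b.values[sl][::10]
        assert np.all(np.diff(v) > 0)

    def test_melanin_tail_normalized_at_red_edge(self, grid):
        b = basis_melanin(grid=grid)
        assert b.values[-1] == 1.0
        assert b.values[grid.index_of(400.0)] < b.values[grid.index_of(650.0)]

    def test_all_bases_nonnegative_unit_max(self, bases):
        for b in bases.values():
            assert np.all(b.values >= 0)
            assert np.isclose(b.values.max(), 1.0)


class TestCompose:
    def test_zero_weights_give_zero_spectrum(self, bases, grid):
        s = compose({name: 0.0 for name in bases}, bases, grid)
        assert np.all(s.intensities == 0)

    def test_unit_weight_reproduces_the_basis(self, bases, grid):
        s = compose({"KERATIN": 1.0}, bases, grid)
        np.testing.assert_array_equal(s.intensities, bases["KERATIN"].values)

    def test_compose_is_linear_in_weights(self, bases, grid, rng):
        names = list(bases)
        w1 = {n: float(rng.uniform(0, 2)) for n in names}
        w2 = {n: float(rng.uniform(0, 2)) for n in names}
        w12 = {n: w1[n] + w2[n] for n in names}
        lhs = compose(w1, bases, grid).intensities + compose(w2, bases, grid).intensities
        np.testing.assert_allclose(lhs, compose(w12, bases, grid).intensities,
                                   rtol=1e-12)

    def test_negative_weight_rejected(self, bases, grid):
        with pytest.raises(ValueError, match="negative"):
            compose({"NADH": -0.1}, bases, grid)


class TestTemplates:
    def test_sk_composite_peaks_at_475(self, grid, templates):
        sk = templates[Phenotype.SK].intensities
        sl = grid.band_slice(430.0, 520.0)
        assert grid.wavelengths[sl][np.argmax(sk[sl])] == 475.0
        smoothed = _moving_average(sk, 40)
        assert grid.wavelengths[sl][np.argmax(smoothed[sl])] == 475.0

    def test_sk_melanin_weight_matches_documented_search(self):
        assert calibrate_sk_melanin_weight() == pytest.approx(SK_MELANIN_WEIGHT)

    def test_pure_reference_templates_peak_at_measured_wavelengths(self, grid,
                                                                   templates):
        nadh = templates[Phenotype.PURE_NADH].intensities
        ker = templates[Phenotype.PURE_KERATIN].intensities
        assert grid.wavelengths[np.argmax(nadh)] == 450.0
        assert grid.wavelengths[np.argmax(ker)] == 470.0

    def test_sk_blue_band_is_up_to_ten_times_the_nevus_blue_band(self, grid,
                                                                 templates):
        sl = grid.band_slice(450.0, 490.0)
        ratio = templates[Phenotype.SK].intensities[sl].mean() / \
            templates[Phenotype.NEVUS].intensities[sl].mean()
        assert ratio <= 10.0 + 1e-6
        assert ratio > 8.0  # the calibration pins it at the upper end

    def test_sk_blue_band_dominates_nevus_red_band(self, grid, templates):
        blue = grid.band_slice(450.0, 490.0)
        red = grid.band_slice(550.0, 650.0)
        assert templates[Phenotype.SK].intensities[blue].mean() >= \
            5.0 * templates[Phenotype.NEVUS].intensities[red].mean()

    def test_cm_template_rises_monotonically_over_430_650(self, grid, templates):
        from scipy.stats import spearmanr

        cm = templates[Phenotype.CM].intensities
        sl = grid.band_slice(430.0, 650.0)
        assert np.all(np.diff(cm[sl]) > 0)
        smoothed = _moving_average(cm, 40)
        rho = spearmanr(smoothed[sl], grid.wavelengths[sl]).statistic
        assert rho == pytest.approx(1.0)

    def test_cm_shg_is_lower_than_nevus_shg(self, grid, templates):
        sl = grid.band_slice(395.0, 405.0)
        cm = templates[Phenotype.CM].intensities
        nev = templates[Phenotype.NEVUS].intensities
        assert cm[sl].mean() / cm.max() < nev[sl].mean() / nev.max()

    def test_nevus_shg_band_is_the_global_maximum(self, grid, templates):
        nev = templates[Phenotype.NEVUS].intensities
        sl = grid.band_slice(395.0, 405.0)
        outside = np.ones(grid.n_points, dtype=bool)
        outside[grid.band_slice(390.0, 410.0)] = False
        assert nev[sl].mean() > nev[outside].max()
        assert grid.wavelengths[np.argmax(nev)] == 400.0

    def test_hyperkeratotic_template_peaks_in_the_keratin_band(self, grid,
                                                               templates):
        hk = templates[Phenotype.HYPERKERATOTIC].intensities
        sl = grid.band_slice(430.0, 520.0)
        assert 460.0 <= grid.wavelengths[sl][np.argmax(hk[sl])] <= 490.0

    def test_healthy_forearm_shows_an_intense_shg_line(self, grid, templates):
        fa = templates[Phenotype.HEALTHY_FOREARM].intensities
        assert grid.wavelengths[np.argmax(fa)] == 400.0

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            compose_template("BASAL_CELL")

    def test_templates_classify_as_their_own_type(self, grid, templates):
        """Cross-module consistency: the CM rule accepts the CM template and
        rejects SK and nevus templates."""
        X = np.vstack([templates[p].intensities
                       for p in (Phenotype.SK, Phenotype.CM, Phenotype.NEVUS)])
        sm = _moving_average(X, 40)
        norm = sm / sm.max(axis=1, keepdims=True)
        F = SpectralFeaturizer(grid).fit(norm).transform(norm)
        types = RuleBasedSpectralTyper().fit(F).predict(F)
        assert list(types) == ["SK_TYPE", "CM_TYPE", "NEVUS_TYPE"]
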