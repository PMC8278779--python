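"""Feature extraction and spectral typing (rule-based and surrogate)."""

import numpy as np
import pytest

from dermafluor.classify import (
    RuleBasedSpectralTyper,
    SpectralFeaturizer,
    SurrogateSpectralTyper,
    TypingThresholds,
    classify_rule,
    extract_features,
    is_malignant_type,
    train_surrogate,
)
from dermafluor.fluorophores import Phenotype
from dermafluor.preprocess import _moving_average
from dermafluor.simulate import generate_spectrum
from dermafluor.spectra import SpectralType, Spectrum, Stage


def _smoothed_normalized(values):
    sm = _moving_average(np.asarray(values, dtype=float), 40)
    return sm / sm.max()


def _template_features(grid, templates, phenotype, snr=np.inf):
    values = _smoothed_normalized(templates[phenotype].intensities)
    s = Spectrum(grid, values, stage=Stage.NORMALIZED)
    return extract_features(s, snr=snr)


class TestFeatures:
    def test_nevus_template_shg_band_dominates(self, grid, templates):
        f = _template_features(grid, templates, Phenotype.NEVUS)
        assert f.shg_band > f.blue_band and f.shg_band > f.red_band

    def test_cm_template_monotonicity_is_one(self, grid, templates):
        f = _template_features(grid, templates, Phenotype.CM)
        assert f.monotonicity == pytest.approx(1.0)

    def test_sk_template_peaks_at_475(self, grid, templates):
        f = _template_features(grid, templates, Phenotype.SK)
        assert f.peak_nm == 475.0

    def test_raw_spectrum_refused(self, grid, templates):
        with pytest.raises(ValueError, match="normalized"):
            extract_features(templates[Phenotype.SK])

    def test_band_means_nonnegative_and_peak_in_window(self, grid,
                                                       small_sk_scan):
        X = small_sk_scan.intensity_matrix()
        norm = np.vstack([_smoothed_normalized(x + 1e-9) for x in X])
        F = SpectralFeaturizer(grid).fit(norm).transform(norm)
        assert np.all(F[:, :3] >= 0)
        assert np.all((F[:, 4] >= 430.0) & (F[:, 4] <= 520.0))
        assert np.all((F[:, 3] >= -1.0) & (F[:, 3] <= 1.0))


class TestRuleClassifier:
    @pytest.mark.parametrize("phenotype,expected", [
        (Phenotype.SK, SpectralType.SK_TYPE),
        (Phenotype.CM, SpectralType.CM_TYPE),
        (Phenotype.NEVUS, SpectralType.NEVUS_TYPE),
        (Phenotype.BACKGROUND, SpectralType.UNINFORMATIVE),
    ])
    def test_noise_free_templates_get_their_own_type(self, grid, templates,
                                                     phenotype, expected):
        f = _template_features(grid, templates, phenotype)
        assert classify_rule(f) is expected

    def test_flat_spectrum_is_uninformative(self, grid):
        flat = Spectrum(grid, np.ones(grid.n_points), stage=Stage.NORMALIZED)
        f = extract_features(flat)
        assert classify_rule(f) is SpectralType.UNINFORMATIVE

    def test_every_spectrum_receives_exactly_one_type(self, grid, rng):
        """Totality: random feature vectors always map to a valid type."""
        F = np.column_stack([
            rng.uniform(0, 1.2, 500),          # shg
            rng.uniform(0, 1.2, 500),          # blue
            rng.uniform(0, 1.2, 500),          # red
            rng.uniform(-1, 1, 500),           # monotonicity
            rng.uniform(430, 520, 500),        # peak
            rng.uniform(0, 50, 500),           # snr
        ])
        types = RuleBasedSpectralTyper().fit(F).predict(F)
        valid = {t.value for t in SpectralType} - {"REJECTED_LOW_SNR"}
        assert set(types) <= valid
        assert len(types) == 500

    def test_scale_invariance(self, grid, templates):
        """Rescaling the underlying spectrum leaves the assigned type
        unchanged (features come from normalized spectra)."""
        for c in (0.01, 1.0, 250.0):
            values = _smoothed_normalized(c * templates[Phenotype.SK].intensities)
            s = Spectrum(grid, values, stage=Stage.NORMALIZED)
            assert classify_rule(extract_features(s)) is SpectralType.SK_TYPE

    def test_threshold_ordering_validated(self):
        with pytest.raises(ValueError, match="shg_low"):
            TypingThresholds(shg_high=0.3, shg_low=0.4)


class TestMalignancy:
    def test_only_the_melanoma_type_counts(self):
        assert is_malignant_type(SpectralType.CM_TYPE) is True
        assert is_malignant_type(SpectralType.SK_TYPE) is False
        assert is_malignant_type(SpectralType.NEVUS_TYPE) is False
        assert is_malignant_type(SpectralType.UNINFORMATIVE) is False

    def test_rejected_spectra_carry_no_evidence(self):
        with pytest.raises(ValueError, match="rejected"):
            is_malignant_type(SpectralType.REJECTED_LOW_SNR)


def _labeled_features(grid, templates, n_per_class, seed):
    """Noisy feature rows with generator-truth labels."""
    rng = np.random.default_rng(seed)
    feat = SpectralFeaturizer(grid)
    label_of = {Phenotype.SK: "SK_TYPE", Phenotype.CM: "CM_TYPE",
                Phenotype.NEVUS: "NEVUS_TYPE",
                Phenotype.BACKGROUND: "UNINFORMATIVE"}
    Fs, ys = [], []
    for p, label in label_of.items():
        X = np.vstack([
            generate_spectrum(templates[p], 1.0, 2000.0, rng).intensities
            for _ in range(n_per_class)
        ])
        sm = _moving_average(X, 40)
        norm = sm / sm.max(axis=1, keepdims=True)
        Fs.append(feat.fit(norm).transform(norm))
        ys.append(np.full(n_per_class, label))
    return np.vstack(Fs), np.concatenate(ys)


class TestSurrogate:
    def test_heldout_accuracy_at_default_noise(self, grid, templates):
        F_train, y_train = _labeled_features(grid, templates, 500, seed=10)
        F_test, y_test = _labeled_features(grid, templates, 500, seed=11)
        clf = train_surrogate(F_train, y_train, seed=0)
        pred = clf.predict(F_test)
        for c in np.unique(y_test):
            assert (pred[y_test == c] == c).mean() >= 0.95

    def test_noise_free_templates_predicted_perfectly(self, grid, templates):
        F_train, y_train = _labeled_features(grid, templates, 100, seed=12)
        clf = train_surrogate(F_train, y_train, seed=0)
        rows, labels = [], []
        for p, label in [(Phenotype.SK, "SK_TYPE"), (Phenotype.CM, "CM_TYPE"),
                         (Phenotype.NEVUS, "NEVUS_TYPE")]:
            rows.append(_template_features(grid, templates, p).as_array())
            labels.append(label)
        assert list(clf.predict(np.vstack(rows))) == labels

    def test_permuted_labels_give_chance_accuracy(self, grid, templates):
        F_train, y_train = _labeled_features(grid, templates, 200, seed=13)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y_train)
        clf = train_surrogate(F_train, y_perm, seed=0)
        F_test, y_test = _labeled_features(grid, templates, 200, seed=14)
        acc = (clf.predict(F_test) == y_test).mean()
        k, n = 4, len(y_test)
        se = np.sqrt((1 / k) * (1 - 1 / k) / n)
        assert abs(acc - 1 / k) < 5 * se

    def test_missing_class_rejected(self, grid, templates):
        F, y = _labeled_features(grid, templates, 60, seed=15)
        keep = y != "CM_TYPE"
        clf = SurrogateSpectralTyper()
        with pytest.raises(ValueError, match="class"):
            clf.fit(F[~keep][:10], y[~keep][:10])  # one class, too few rows

    def test_agrees_with_rule_backend_on_generator_spectra(self, grid,
                                                           templates):
        F_train, y_train = _labeled_features(grid, templates, 300, seed=16)
        clf = train_surrogate(F_train, y_train, seed=0)
        F_test, _ = _labeled_features(grid, templates, 300, seed=17)
        rule = RuleBasedSpectralTyper().fit(F_test).predict(F_test)
        agreement = (clf.predict(F_test) == rule).mean()
        assert agreement >= 0.90
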