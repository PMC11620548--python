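"""Mangrove extraction and the two-species-group Random-Forests step."""

import numpy as np
import pytest

from cmri.classification import (classify, extract_mangrove_mask,
                                 train_species_classifier)
from cmri.compositing import annual_max, bimonthly_max
from cmri.grids import IndexRaster, RHIZOPHORA, OTHER_MANGROVE
from cmri.indices import compute_cmri
from cmri import synthetic


def index_raster(values):
    values = np.atleast_2d(np.asarray(values, float))
    return IndexRaster(values=values, index_name="CMRI_annual_max",
                       valid=np.isfinite(values))


class TestExtractMangroveMask:
    def test_boundary_is_inclusive(self):
        out = extract_mangrove_mask(index_raster([[0.39, 0.40, 0.70]]),
                                    threshold=0.4)
        assert list(out[0]) == [False, True, True]

    def test_lowest_threshold_keeps_all_valid(self):
        r = index_raster([[-1.5, 0.0, np.nan]])
        out = extract_mangrove_mask(r, threshold=-2)
        assert list(out[0]) == [True, True, False]

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-2, 2\]"):
            extract_mangrove_mask(index_raster([[0.5]]), threshold=2.5)

    def test_otsu_mode_splits_bimodal_histogram(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0.1, 0.03, 500)
        high = rng.normal(0.7, 0.05, 500)
        vals = np.concatenate([low, high]).reshape(50, 20)
        mask = extract_mangrove_mask(index_raster(vals), method="otsu")
        assert mask.sum() == pytest.approx(500, abs=10)


def _separable_training_set(sd, n_per_class, seed):
    profiles = synthetic.default_profiles(mangrove_sd=sd)
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, cls in ((synthetic.MANGROVE_RM, RHIZOPHORA),
                       (synthetic.MANGROVE_OTHER, OTHER_MANGROVE)):
        mu = np.array(profiles[label].bimonthly_cmri_means)
        X.append(mu + sd * rng.standard_normal((n_per_class, 6)))
        y.append(np.full(n_per_class, cls))
    return np.concatenate(X), np.concatenate(y)


class TestTrainSpeciesClassifier:
    def test_separable_profiles_fit_perfectly(self):
        X, y = _separable_training_set(0.0, 50, seed=0)
        model = train_species_classifier(X, y, n_trees=50, seed=0)
        assert (model.model.predict(X) == y).all()

    def test_single_class_rejected(self):
        X = np.zeros((10, 6))
        with pytest.raises(ValueError, match="single class"):
            train_species_classifier(X, np.ones(10), n_trees=10, seed=0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            train_species_classifier(np.zeros((10, 6)), np.ones(9),
                                     n_trees=10, seed=0)

    def test_nan_features_rejected(self):
        X, y = _separable_training_set(0.0, 5, seed=0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="invalid"):
            train_species_classifier(X, y, n_trees=10, seed=0)

    def test_held_out_accuracy_on_noisy_fixture(self):
        """sd = 0.05, 500 px/class: held-out accuracy >= 95%."""
        X, y = _separable_training_set(0.05, 500, seed=0)
        Xt, yt = _separable_training_set(0.05, 250, seed=1)
        model = train_species_classifier(X, y, n_trees=2000, seed=0)
        acc = (model.model.predict(Xt) == yt).mean()
        assert acc >= 0.95
        assert model.model.oob_score_ >= 0.95

    def test_serialization_round_trip(self):
        X, y = _separable_training_set(0.05, 50, seed=0)
        model = train_species_classifier(X, y, n_trees=20, seed=0)
        clone = model.roundtrip()
        assert clone.feature_layout == model.feature_layout
        np.testing.assert_array_equal(clone.model.predict(X),
                                      model.model.predict(X))


@pytest.fixture(scope="module")
def noisefree_products():
    """64x64 noise-free world composited and classified."""
    truth = synthetic.build_landscape(seed=3, shape=(64, 64), patch_scale=6)
    profiles = {k: synthetic.PhenologyProfile(k, p.bimonthly_cmri_means, 0.0)
                for k, p in synthetic.default_profiles().items()}
    scenes = synthetic.render_scenes(truth, profiles, years=[2020],
                                     scenes_per_period=1,
                                     cloud_fraction_range=(0, 0), seed=5)
    series = bimonthly_max([(s.date, compute_cmri(s)) for s in scenes],
                           years=[2020])
    amax = annual_max(series, 2020)
    return truth, series, amax


class TestClassify:
    def test_noise_free_mask_recovery_exact(self, noisefree_products):
        """Mangrove means >= 0.5, all others <= 0.2: threshold 0.35
        recovers the truth mask exactly."""
        truth, _, amax = noisefree_products
        mask = extract_mangrove_mask(amax, threshold=0.35)
        expected = np.isin(truth.label_grid, synthetic.MANGROVE_LABELS)
        np.testing.assert_array_equal(mask, expected)

    def test_noise_free_labels_match_truth(self, noisefree_products):
        truth, series, amax = noisefree_products
        mask = extract_mangrove_mask(amax, threshold=0.35)
        X, y = _separable_training_set(0.0, 100, seed=0)
        model = train_species_classifier(X, y, n_trees=100, seed=0)
        periods, annual = classify(model, series, mask, 2020)
        expected = synthetic.landscape_to_scheme(truth.label_grid)
        np.testing.assert_array_equal(annual.labels, expected)
        for p in periods:
            np.testing.assert_array_equal(p.labels[mask], expected[mask])

    def test_labels_never_outside_mask(self, noisefree_products):
        _, series, amax = noisefree_products
        mask = extract_mangrove_mask(amax, threshold=0.35)
        X, y = _separable_training_set(0.05, 100, seed=0)
        model = train_species_classifier(X, y, n_trees=50, seed=0)
        periods, annual = classify(model, series, mask, 2020)
        assert not annual.labels[~mask].any()
        for p in periods:
            assert not p.labels[~mask].any()

    def test_deterministic_given_seed(self, noisefree_products):
        _, series, amax = noisefree_products
        mask = extract_mangrove_mask(amax, threshold=0.35)
        X, y = _separable_training_set(0.05, 100, seed=0)
        runs = []
        for _ in range(2):
            model = train_species_classifier(X, y, n_trees=50, seed=7)
            _, annual = classify(model, series, mask, 2020)
            runs.append(annual.labels)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_mismatched_mask_shape_rejected(self, noisefree_products):
        _, series, amax = noisefree_products
        X, y = _separable_training_set(0.0, 20, seed=0)
        model = train_species_classifier(X, y, n_trees=10, seed=0)
        with pytest.raises(ValueError, match="mask"):
            classify(model, series, np.zeros((8, 8), bool), 2020)


def test_per_class_area_recovery_within_5pct():
    """Default landscape, sd = 0.05, one change-free year: mapped
    per-class areas match the truth areas within 5%."""
    truth = synthetic.build_landscape(seed=2, shape=(128, 128))
    profiles = synthetic.default_profiles(mangrove_sd=0.05)
    scenes = synthetic.render_scenes(truth, profiles, years=[2020],
                                     scenes_per_period=3,
                                     cloud_fraction_range=(0, 0.08), seed=2)
    series = bimonthly_max([(s.date, compute_cmri(s)) for s in scenes],
                           years=[2020])
    mask = extract_mangrove_mask(annual_max(series, 2020), threshold=0.35)
    X, y = _separable_training_set(0.05, 300, seed=0)
    model = train_species_classifier(X, y, n_trees=200, seed=0)
    _, annual = classify(model, series, mask, 2020)
    for scheme_label, truth_label in ((RHIZOPHORA, synthetic.MANGROVE_RM),
                                      (OTHER_MANGROVE,
                                       synthetic.MANGROVE_OTHER)):
        mapped = int((annual.labels == scheme_label).sum())
        true = int((truth.label_grid == truth_label).sum())
        assert abs(mapped - true) / true < 0.05
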