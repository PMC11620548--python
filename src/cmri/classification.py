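"""Mangrove extraction and two-class species-group classification.

Mangrove is separated from all other cover by thresholding the annual
maximum CMRI (the maximum value of the index is an established mangrove
threshold in arid regions; the default 0.35 is calibrated on the
synthetic fixtures, and an automatic Otsu split of the annual-max
histogram is available).  Mangrove pixels are then assigned to one of
two species groups — Rhizophora mangle vs. the other dominant mangrove
species (Avicennia germinans / Laguncularia racemosa, pooled because
they are spectrally inseparable) — by a Random-Forests ensemble with
2000 trees whose features are the six bimonthly CMRI values of the
classified year: the groups separate on phenology, not on any single
date.

Per-period products gate the species label by that period's composite:
a pixel counts as mangrove in a period only if it belongs to the annual
mangrove mask AND its CMRI that period reaches the mangrove threshold.
This yields the bimonthly presence series the change-detection stage
accumulates.
"""

from __future__ import annotations

import io
import logging
import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .grids import (ClassRaster, IndexRaster, NON_MANGROVE, OTHER_MANGROVE,
                    RHIZOPHORA)
from .compositing import CompositeSeries, PERIODS_PER_YEAR

__all__ = ["TrainedModel", "extract_mangrove_mask",
           "train_species_classifier", "classify",
           "DEFAULT_MANGROVE_THRESHOLD", "DEFAULT_N_TREES"]

log = logging.getLogger(__name__)

DEFAULT_MANGROVE_THRESHOLD = 0.35
DEFAULT_N_TREES = 2000


def extract_mangrove_mask(annual_max: IndexRaster,
                          threshold: float = DEFAULT_MANGROVE_THRESHOLD,
                          method: str = "fixed") -> np.ndarray:
    """Boolean mangrove mask: valid pixels whose annual max CMRI >= threshold.

    ``method="otsu"`` ignores ``threshold`` and splits the annual-max
    histogram automatically (useful when no calibrated threshold exists).
    """
    if method not in ("fixed", "otsu"):
        raise ValueError(f"unknown extraction method {method!r}")
    if method == "otsu":
        from skimage.filters import threshold_otsu
        vals = annual_max.values[annual_max.valid]
        if vals.size == 0:
            raise ValueError("annual maximum has no valid pixels")
        threshold = float(threshold_otsu(vals))
        log.info("Otsu mangrove threshold: %.4f", threshold)
    if not -2.0 <= threshold <= 2.0:
        raise ValueError(f"mangrove threshold {threshold} outside [-2, 2]")
    return annual_max.valid & (annual_max.values >= threshold)


@dataclass
class TrainedModel:
    """Fitted species-group ensemble plus the feature layout it expects.

    ``feature_layout`` is the ordered list of (year, period) CMRI
    features used at fit time; prediction on a composite series with a
    different layout is rejected.  The layout's year entries are treated
    as *relative* — a model trained on one year's six bimonthly features
    applies to any other year's six periods in the same order.
    """

    model: RandomForestClassifier
    feature_layout: tuple
    classes: tuple
    n_trees: int
    seed: int

    def periods(self):
        return tuple(p for _, p in self.feature_layout)

    def dump(self, path):
        with open(path, "wb") as fh:
            pickle.dump({"format": "cmri-rf-v1", "model": self}, fh)

    @classmethod
    def load(cls, path):
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "cmri-rf-v1":
            raise ValueError(f"{path} is not a serialized species model")
        return payload["model"]

    def roundtrip(self) -> "TrainedModel":
        buf = io.BytesIO()
        pickle.dump(self, buf)
        buf.seek(0)
        return pickle.load(buf)


def train_species_classifier(features: np.ndarray, labels: np.ndarray,
                             n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                             feature_layout=None) -> TrainedModel:
    """Fit the Random-Forests species-group ensemble.

    Parameters
    ----------
    features : (n_samples, n_periods) array
        Bimonthly CMRI vectors, one row per training pixel.
    labels : (n_samples,) array of {1, 2}
        Species-group labels (1 = R. mangle, 2 = other dominant species).
    n_trees : int
        Ensemble size; 2000 by default.
    seed : int
        Makes bootstrap and feature subsampling deterministic.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (samples x periods) array")
    if len(X) != len(y):
        raise ValueError(
            f"feature/label length mismatch: {len(X)} vs {len(y)}")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain invalid (NaN/inf) values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class; "
                         "need both species groups")
    if feature_layout is None:
        feature_layout = tuple((0, p) for p in range(1, X.shape[1] + 1))
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                random_state=seed, n_jobs=1)
    rf.fit(X, y)
    log.info("species ensemble: %d trees, %d samples, OOB accuracy %.3f",
             n_trees, len(y), rf.oob_score_)
    return TrainedModel(model=rf, feature_layout=tuple(feature_layout),
                        classes=tuple(int(c) for c in classes),
                        n_trees=n_trees, seed=seed)


def _year_feature_matrix(series: CompositeSeries, year: int):
    """Stack the year's six composites into an (H, W, 6) feature cube."""
    rasters = series.year_composites(year)
    if len(rasters) != PERIODS_PER_YEAR:
        raise ValueError(f"year {year} does not have "
                         f"{PERIODS_PER_YEAR} composites")
    cube = np.stack([r.values for r in rasters], axis=-1)
    valid = np.stack([r.valid for r in rasters], axis=-1)
    return cube, valid


def classify(model: TrainedModel, series: CompositeSeries,
             mangrove_mask: np.ndarray, year: int,
             threshold: float = DEFAULT_MANGROVE_THRESHOLD):
    """Classify one year of composites inside the mangrove mask.

    Returns ``(period_rasters, annual_raster)``: six per-period
    ClassRasters in which a pixel carries its species group only when it
    is mangrove that period (annual mask AND period CMRI >= threshold),
    and an annual product from a majority vote across the periods, ties
    broken by the ensemble's mean class probability.

    Species labels never appear outside the mangrove mask.
    """
    if model.periods() != tuple(range(1, PERIODS_PER_YEAR + 1)):
        raise ValueError("model feature layout does not match the "
                         "bimonthly composite layout")
    cube, valid = _year_feature_matrix(series, year)
    mask = np.asarray(mangrove_mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mangrove mask shape does not match composites")

    # annual species prediction from the 6-vector; pixels with cloud
    # gaps keep NaN in the missing periods (the forest handles missing
    # features), so a gap never erases a pixel's presence record
    predictable = mask & valid.any(axis=-1)
    species = np.zeros(mask.shape, dtype=np.uint8)
    proba = None
    if predictable.any():
        X = np.where(valid, cube, np.nan)[predictable]
        proba = model.model.predict_proba(X)
        pred = np.asarray(model.model.classes_)[np.argmax(proba, axis=1)]
        species[predictable] = pred

    period_rasters = []
    votes = {c: np.zeros(mask.shape, dtype=np.int16) for c in model.classes}
    for i, p in enumerate(range(1, PERIODS_PER_YEAR + 1)):
        pvalid = valid[..., i]
        present = mask & pvalid & (cube[..., i] >= threshold) & predictable
        labels = np.where(present, species, NON_MANGROVE).astype(np.uint8)
        raster = ClassRaster(labels=labels, valid=pvalid,
                             period_label=(year, p), georef=series.georef)
        assert not np.any(raster.labels[~mask]), \
            "species label leaked outside the mangrove mask"
        period_rasters.append(raster)
        for c in model.classes:
            votes[c] += (labels == c)

    annual = np.zeros(mask.shape, dtype=np.uint8)
    if predictable.any():
        vote_stack = np.stack([votes[c] for c in model.classes], axis=-1)
        top = vote_stack.max(axis=-1)
        winner_idx = vote_stack.argmax(axis=-1)
        tie = (vote_stack == top[..., None]).sum(axis=-1) > 1
        annual[predictable] = np.asarray(model.classes)[
            winner_idx[predictable]]
        # ties (including pixels never above threshold in any period)
        # fall back to the ensemble's direct prediction
        tie_px = predictable & tie
        if tie_px.any():
            annual[tie_px] = species[tie_px]
    annual_raster = ClassRaster(labels=annual, valid=valid.any(axis=-1),
                                period_label="annual", georef=series.georef)
    assert not np.any(annual_raster.labels[~mask]), \
        "species label leaked outside the mangrove mask"
    return period_rasters, annual_raster
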