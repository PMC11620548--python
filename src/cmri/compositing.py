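"""Scene filtering and maximum-value compositing of CMRI time series.

Scenes are first filtered at the scene level (cloud cover strictly below
a threshold, 10% by default) and then reduced per pixel: within each
bimonthly period the composite is the maximum CMRI over all valid
(clear, finite-denominator) observations.  Cloud-masked observations are
additionally excluded per pixel, so a cloudy observation can never win
the maximum even in a scene that passed the scene-level filter.

Bimonthly periods are the calendar bimonths Jan-Feb (period 1) through
Nov-Dec (period 6).
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grids import GridGeoref, IndexRaster, SceneStack

__all__ = ["CompositeSeries", "filter_scenes", "bimonthly_max",
           "annual_max", "period_of_date", "PERIODS_PER_YEAR"]

PERIODS_PER_YEAR = 6


def period_of_date(date: _dt.date) -> int:
    """Bimonthly period index 1..6 (Jan-Feb = 1, ..., Nov-Dec = 6)."""
    return (date.month - 1) // 2 + 1


@dataclass
class CompositeSeries:
    """Ordered bimonthly maximum-CMRI grids with per-pixel coverage counts.

    ``period_labels`` are (year, period) pairs in strict chronological
    order, six per covered year; ``coverage`` counts the valid
    observations behind each composite pixel (0 exactly where the
    composite is invalid).  Periods that had no scene at all are listed
    in ``missing_periods``.
    """

    composites: list  # of IndexRaster
    period_labels: list  # of (year, period)
    coverage: list  # of int ndarray
    georef: GridGeoref = field(default_factory=GridGeoref)
    missing_periods: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.composites) != len(self.period_labels) or \
                len(self.coverage) != len(self.period_labels):
            raise ValueError("composites, labels and coverage lengths differ")
        order = sorted(self.period_labels)
        if order != self.period_labels:
            raise ValueError("period labels not chronological")

    @property
    def years(self):
        return sorted({y for y, _ in self.period_labels})

    def get(self, year: int, period: int) -> IndexRaster:
        idx = self.period_labels.index((year, period))
        return self.composites[idx]

    def year_composites(self, year: int):
        return [c for c, (y, _) in zip(self.composites, self.period_labels)
                if y == year]


def filter_scenes(scenes: Sequence[SceneStack],
                  max_cloud_fraction: float = 0.10):
    """Keep scenes whose cloud-mask fraction is strictly below the threshold.

    Order is preserved.  An empty result is legal and surfaced as a
    warning, never an error.
    """
    kept = [s for s in scenes if s.cloud_fraction < max_cloud_fraction]
    if scenes and not kept:
        warnings.warn(
            f"all {len(scenes)} scenes at or above the "
            f"{max_cloud_fraction:.0%} cloud-cover threshold; nothing kept",
            stacklevel=2)
    return kept


def bimonthly_max(cmri_scenes: Sequence[tuple], years) -> CompositeSeries:
    """Per-pixel maximum CMRI within each bimonthly period.

    Parameters
    ----------
    cmri_scenes : sequence of (date, IndexRaster)
        Dated CMRI rasters (invalid pixels already NaN-flagged).
    years : iterable of int
        Calendar years to composite.  A year with no scene in any of its
        six periods raises a ValueError naming the year.
    """
    years = sorted(years)
    if not cmri_scenes:
        raise ValueError("no scenes supplied")
    georef = cmri_scenes[0][1].georef
    shape = cmri_scenes[0][1].shape
    buckets = {}
    for date, raster in cmri_scenes:
        if raster.shape != shape:
            raise ValueError("scene rasters have mismatched shapes")
        buckets.setdefault((date.year, period_of_date(date)), []).append(raster)

    composites, labels, coverage, missing = [], [], [], []
    for year in years:
        if not any((year, p) in buckets for p in range(1, PERIODS_PER_YEAR + 1)):
            raise ValueError(f"no scenes available in any period of {year}")
        for p in range(1, PERIODS_PER_YEAR + 1):
            rasters = buckets.get((year, p), [])
            vals = np.full(shape, -np.inf)
            count = np.zeros(shape, dtype=np.int32)
            for r in rasters:
                v = np.where(r.valid, r.values, -np.inf)
                vals = np.maximum(vals, v)
                count += r.valid
            valid = count > 0
            values = np.where(valid, vals, np.nan)
            if not rasters:
                missing.append((year, p))
            composites.append(IndexRaster(values=values, index_name="CMRI",
                                          valid=valid, georef=georef))
            labels.append((year, p))
            coverage.append(count)
    return CompositeSeries(composites=composites, period_labels=labels,
                           coverage=coverage, georef=georef,
                           missing_periods=missing)


def annual_max(series: CompositeSeries, year: int) -> IndexRaster:
    """Pixelwise maximum across one year's six bimonthly composites."""
    if year not in series.years:
        raise ValueError(f"year {year} not covered by the composite series")
    rasters = series.year_composites(year)
    vals = np.full(rasters[0].shape, -np.inf)
    valid = np.zeros(rasters[0].shape, dtype=bool)
    for r in rasters:
        vals = np.maximum(vals, np.where(r.valid, r.values, -np.inf))
        valid |= r.valid
    values = np.where(valid, vals, np.nan)
    return IndexRaster(values=values, index_name="CMRI_annual_max",
                       valid=valid, georef=series.georef)
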