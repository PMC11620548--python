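"""Accumulated-anomaly change detection over bimonthly class series.

For each pixel let x_t in {0, 1} be the mangrove indicator of the
bimonthly classification at period t, and let x-bar be the mean of x
over the baseline year's periods.  The accumulated anomaly is

    A = sum over all post-baseline periods t of (x_t - x-bar),

so a pixel that behaves exactly as it did in the baseline accumulates 0,
a cleared mangrove pixel (x-bar = 1, x_t = 0 thereafter) accumulates -1
per period, and a colonized pixel accumulates +1 per period: the
cumulative differences grow bimonthly wherever the cover is genuinely
changing, while one-period phenological flickers contribute at most
+/-1 and are suppressed by the persistence threshold.  Loss is called
where A <= -threshold and gain where A >= +threshold (default 4
periods, about 8 months of persistent deviation).

A variant that accumulates absolute consecutive differences
(|x_t - x_{t-1}|) is available for sensitivity checks; it measures
instability rather than signed change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .grids import ClassRaster, GridGeoref

__all__ = ["AnomalyRaster", "ChangeMap", "accumulate_anomaly", "call_change",
           "change_area_summary", "add_totals_row",
           "STABLE", "LOSS", "GAIN", "DEFAULT_PERSISTENCE"]

STABLE, LOSS, GAIN = 0, 1, 2
DEFAULT_PERSISTENCE = 4


@dataclass
class AnomalyRaster:
    """Per-pixel accumulated anomaly in units of bimonthly periods."""

    accumulated: np.ndarray
    n_periods: np.ndarray      # valid post-baseline periods per pixel
    valid: np.ndarray          # pixels with a defined baseline mean
    baseline_year: int
    final_year: int
    georef: GridGeoref = field(default_factory=GridGeoref)
    statistic: str = "baseline_deviation"

    def __post_init__(self):
        ok = self.valid & (self.n_periods > 0)
        if np.any(np.abs(self.accumulated[ok]) > self.n_periods[ok] + 1e-9):
            raise ValueError("|accumulated| exceeds the number of "
                             "accumulated periods")


@dataclass
class ChangeMap:
    """Categorical gain/loss/stable grid derived from the anomaly."""

    labels: np.ndarray  # uint8 {0 stable, 1 loss, 2 gain}
    valid: np.ndarray
    persistence_threshold: int
    georef: GridGeoref = field(default_factory=GridGeoref)


def _split_periods(bimonthly_classes, baseline_year):
    baseline, post = [], []
    for cr in bimonthly_classes:
        if not isinstance(cr.period_label, tuple):
            raise ValueError("bimonthly class rasters must carry "
                             "(year, period) labels")
        year, _ = cr.period_label
        if year == baseline_year:
            baseline.append(cr)
        elif year > baseline_year:
            post.append(cr)
    post.sort(key=lambda cr: cr.period_label)
    return baseline, post


def accumulate_anomaly(bimonthly_classes: Sequence[ClassRaster],
                       baseline_year: int,
                       min_baseline_periods: int = 6,
                       statistic: str = "baseline_deviation") -> AnomalyRaster:
    """Accumulate per-pixel deviations from the baseline year's mean.

    Invalid periods are skipped per pixel and excluded from ``n_periods``.
    ``statistic="consecutive_abs"`` accumulates |x_t - x_{t-1}| over the
    post-baseline series instead (unsigned instability measure).
    """
    if statistic not in ("baseline_deviation", "consecutive_abs"):
        raise ValueError(f"unknown anomaly statistic {statistic!r}")
    baseline, post = _split_periods(bimonthly_classes, baseline_year)
    years = {cr.period_label[0] for cr in bimonthly_classes}
    if len(years) < 2 or not post:
        raise ValueError("need at least two years of bimonthly products "
                         "(baseline plus one post-baseline year)")
    if len(baseline) < min_baseline_periods:
        raise ValueError(
            f"baseline year {baseline_year} has {len(baseline)} periods, "
            f"fewer than the required {min_baseline_periods}")

    shape = baseline[0].shape
    georef = baseline[0].georef
    bsum = np.zeros(shape)
    bcount = np.zeros(shape, dtype=np.int32)
    for cr in baseline:
        x = cr.mangrove_indicator()
        bsum += np.where(cr.valid, x, 0)
        bcount += cr.valid
    valid = bcount > 0
    xbar = np.divide(bsum, bcount, out=np.zeros(shape), where=valid)

    acc = np.zeros(shape)
    n = np.zeros(shape, dtype=np.int32)
    if statistic == "baseline_deviation":
        for cr in post:
            x = cr.mangrove_indicator()
            acc += np.where(cr.valid, x - xbar, 0)
            n += cr.valid
    else:
        prev, prev_valid = None, None
        for cr in post:
            x = cr.mangrove_indicator()
            if prev is not None:
                both = cr.valid & prev_valid
                acc += np.where(both, np.abs(x - prev), 0)
                n += both
            prev, prev_valid = x, cr.valid
    final_year = max(cr.period_label[0] for cr in post)
    return AnomalyRaster(accumulated=acc, n_periods=n, valid=valid,
                         baseline_year=baseline_year, final_year=final_year,
                         georef=georef, statistic=statistic)


def call_change(anomaly: AnomalyRaster,
                persistence_threshold: int = DEFAULT_PERSISTENCE) -> ChangeMap:
    """Call loss/gain where the anomaly persists beyond the threshold."""
    if persistence_threshold < 1:
        raise ValueError("persistence threshold must be >= 1")
    max_n = int(anomaly.n_periods.max()) if anomaly.n_periods.size else 0
    if persistence_threshold > max_n:
        raise ValueError(
            f"persistence threshold {persistence_threshold} exceeds the "
            f"{max_n} accumulated periods: no pixel could ever be called")
    labels = np.full(anomaly.accumulated.shape, STABLE, dtype=np.uint8)
    ok = anomaly.valid
    labels[ok & (anomaly.accumulated <= -persistence_threshold)] = LOSS
    labels[ok & (anomaly.accumulated >= persistence_threshold)] = GAIN
    return ChangeMap(labels=labels, valid=ok,
                     persistence_threshold=persistence_threshold,
                     georef=anomaly.georef)


def add_totals_row(table: pd.DataFrame, key_column: str,
                   label: str = "Total") -> pd.DataFrame:
    """Append a totals row that is exactly the column sums of the table."""
    totals = {key_column: label}
    for col in table.columns:
        if col != key_column:
            totals[col] = table[col].sum()
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def change_area_summary(change: ChangeMap, zones, pixel_size: float = None,
                        zone_crs: str = None) -> pd.DataFrame:
    """Per-zone gain/loss areas in hectares, with a column-sum totals row.

    Parameters
    ----------
    zones : sequence of (zone_id, shapely geometry)
        Zone polygons in the raster's CRS; a pixel belongs to the zone
        containing its center.
    pixel_size : float, optional
        Pixel edge in metres (defaults to the raster's georeference).

    1 pixel of 10 m is 100 m^2 = 0.01 ha.
    """
    if zone_crs is not None and zone_crs != change.georef.crs:
        raise ValueError(f"zone CRS {zone_crs} does not match raster CRS "
                         f"{change.georef.crs}")
    px = pixel_size if pixel_size is not None else change.georef.pixel_size
    ha_per_px = px * px / 10000.0
    rows = []
    changed = change.labels != STABLE
    r, c = np.nonzero(changed & change.valid)
    if r.size:
        x, y = change.georef.pixel_center(r, c)
        pts = shapely.points(x, y)
    for zone_id, geom in zones:
        if r.size:
            inside = shapely.contains(geom, pts)
            lab = change.labels[r[inside], c[inside]]
            gain_px = int(np.count_nonzero(lab == GAIN))
            loss_px = int(np.count_nonzero(lab == LOSS))
        else:
            gain_px = loss_px = 0
        rows.append({"zone": zone_id,
                     "gain_ha": round(gain_px * ha_per_px, 4),
                     "loss_ha": round(loss_px * ha_per_px, 4)})
    table = pd.DataFrame(rows, columns=["zone", "gain_ha", "loss_ha"])
    return add_totals_row(table, "zone")
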