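"""Raster-to-polygon conversion and the minimum-mappable-area rule.

Class maps are vectorized one maximal connected component at a time
(4-connectivity by default, so diagonal chains do not inflate patch
size), and splinter polygons below the minimum mappable area — 0.2 ha,
i.e. exactly 20 pixels at 10 m — are eliminated.  A patch of exactly
0.2 ha is retained.  All areas are computed in the raster's projected
CRS; geographic (degree-unit) rasters are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .change import add_totals_row
from .grids import ClassRaster, GridGeoref

__all__ = ["PolygonSet", "raster_to_polygons", "filter_min_area",
           "zonal_area_table", "DEFAULT_MIN_MAPPABLE_HA"]

log = logging.getLogger(__name__)

DEFAULT_MIN_MAPPABLE_HA = 0.2
_AREA_EPS = 1e-9

_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class PolygonSet:
    """Vectorized class patches with per-polygon areas in hectares."""

    table: pd.DataFrame  # columns: geometry, class_label, pixels, area_ha
    georef: GridGeoref = field(default_factory=GridGeoref)
    min_mappable_ha: float = 0.0

    def __len__(self):
        return len(self.table)

    def class_area_ha(self) -> pd.Series:
        return self.table.groupby("class_label")["area_ha"].sum()

    def to_geojson(self, path):
        import json
        feats = []
        for _, row in self.table.iterrows():
            feats.append({
                "type": "Feature",
                "geometry": shapely.geometry.mapping(row.geometry),
                "properties": {"class_label": int(row.class_label),
                               "pixels": int(row.pixels),
                               "area_ha": float(row.area_ha)},
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection",
                       "crs_name": self.georef.crs,
                       "features": feats}, fh)


def _component_polygon(rows, cols, georef: GridGeoref):
    """Union of pixel squares, merged row-wise into run rectangles first."""
    px = georef.pixel_size
    boxes = []
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    for r in np.unique(rows):
        cc = cols[rows == r]
        # split sorted columns into consecutive runs
        breaks = np.nonzero(np.diff(cc) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [cc.size - 1]])
        for s, e in zip(starts, ends):
            x0 = georef.x0 + cc[s] * px
            x1 = georef.x0 + (cc[e] + 1) * px
            y1 = georef.y0 - r * px
            y0 = georef.y0 - (r + 1) * px
            boxes.append(shapely.box(x0, y0, x1, y1))
    return shapely.unary_union(boxes)


def raster_to_polygons(classes: ClassRaster, connectivity: int = 4,
                       include_labels=None,
                       allow_geographic: bool = False) -> PolygonSet:
    """One polygon per maximal connected component per class (unfiltered).

    Total polygon area per class equals class pixel count times pixel
    area, exactly, before any filtering.
    """
    if connectivity not in _STRUCTURE:
        raise ValueError("connectivity must be 4 or 8")
    if classes.georef.is_geographic and not allow_geographic:
        raise ValueError("raster CRS is geographic (degree units); areas "
                         "require a projected CRS")
    labels_present = np.unique(classes.labels[classes.valid])
    if include_labels is None:
        include_labels = [int(v) for v in labels_present if v != 0]
    px = classes.georef.pixel_size
    ha_per_px = px * px / 10000.0
    records = []
    for lab in include_labels:
        mask = (classes.labels == lab) & classes.valid
        comp, n = ndimage.label(mask, structure=_STRUCTURE[connectivity])
        for i in range(1, n + 1):
            rr, cc = np.nonzero(comp == i)
            geom = _component_polygon(rr, cc, classes.georef)
            records.append({"geometry": geom, "class_label": lab,
                            "pixels": rr.size,
                            "area_ha": rr.size * ha_per_px})
    table = pd.DataFrame(records,
                         columns=["geometry", "class_label", "pixels",
                                  "area_ha"])
    return PolygonSet(table=table, georef=classes.georef, min_mappable_ha=0.0)


def filter_min_area(polys: PolygonSet,
                    min_ha: float = DEFAULT_MIN_MAPPABLE_HA) -> PolygonSet:
    """Drop splinter polygons below the minimum mappable area.

    The boundary is inclusive: a patch of exactly ``min_ha`` stays.
    Removed area is logged per class.
    """
    if min_ha < 0:
        raise ValueError("minimum mappable area must be non-negative")
    keep = polys.table["area_ha"] >= min_ha - _AREA_EPS
    removed = polys.table[~keep]
    if len(removed):
        for lab, area in removed.groupby("class_label")["area_ha"].sum().items():
            log.info("minimum-mappable-area filter removed %.4f ha of "
                     "class %s (%d polygons)", area, lab,
                     (removed.class_label == lab).sum())
    return PolygonSet(table=polys.table[keep].reset_index(drop=True),
                      georef=polys.georef, min_mappable_ha=min_ha)


def zonal_area_table(polys: PolygonSet, zones) -> pd.DataFrame:
    """Per-zone, per-class hectares from polygon-zone intersection.

    ``zones`` is a sequence of (zone_id, shapely geometry) in the
    raster's CRS; zones must not overlap.  The totals row is exactly the
    column sums.
    """
    class_labels = sorted(polys.table["class_label"].unique()) \
        if len(polys.table) else []
    rows = []
    for zone_id, geom in zones:
        rec = {"zone": zone_id}
        for lab in class_labels:
            sub = polys.table[polys.table.class_label == lab]
            area_m2 = sum(shapely.intersection(g, geom).area
                          for g in sub.geometry)
            rec[f"class_{lab}_ha"] = area_m2 / 10000.0
        rows.append(rec)
    cols = ["zone"] + [f"class_{lab}_ha" for lab in class_labels]
    table = pd.DataFrame(rows, columns=cols)
    return add_totals_row(table, "zone")
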