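"""Raster containers and georeferenced I/O.

All grids in the pipeline are plain numpy arrays tied to a north-up
geotransform.  Rasters are written as (Geo)TIFFs via :mod:`tifffile`,
with the georeferencing and acquisition metadata serialized as JSON in
the TIFF ``ImageDescription`` tag so that every product round-trips
through the file formats declared by the pipeline.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = [
    "GridGeoref",
    "SceneStack",
    "IndexRaster",
    "ClassRaster",
    "write_raster",
    "read_raster",
]


@dataclass(frozen=True)
class GridGeoref:
    """North-up georeference: origin at the top-left corner of pixel (0, 0).

    Parameters
    ----------
    x0, y0 : float
        Projected coordinates (metres) of the grid's top-left corner.
    pixel_size : float
        Square pixel edge in metres (10 m for the highest-resolution bands).
    crs : str
        CRS identifier, e.g. ``"EPSG:32612"``.  Geographic (degree-unit)
        systems are rejected by area-sensitive stages.
    """

    x0: float = 0.0
    y0: float = 0.0
    pixel_size: float = 10.0
    crs: str = "EPSG:32612"

    def pixel_center(self, row, col):
        """(x, y) of pixel centers; accepts arrays."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.x0 + (col + 0.5) * self.pixel_size
        y = self.y0 - (row + 0.5) * self.pixel_size
        return x, y

    def world_to_pixel(self, x, y):
        """(row, col) integer indices containing the points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.pixel_size).astype(int)
        row = np.floor((self.y0 - y) / self.pixel_size).astype(int)
        return row, col

    @property
    def is_geographic(self) -> bool:
        return self.crs.upper() in ("EPSG:4326", "CRS:84", "OGC:CRS84")

    def to_dict(self):
        return {"x0": self.x0, "y0": self.y0,
                "pixel_size": self.pixel_size, "crs": self.crs}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


@dataclass
class SceneStack:
    """One dated multiband surface-reflectance scene with a cloud mask.

    Bands are unitless reflectances in [0, 1] on clear pixels; the cloud
    mask is True where the pixel is contaminated.
    """

    red: np.ndarray
    green: np.ndarray
    nir: np.ndarray
    swir: np.ndarray
    cloud_mask: np.ndarray
    date: _dt.date
    georef: GridGeoref = field(default_factory=GridGeoref)

    def __post_init__(self):
        shapes = {b.shape for b in (self.red, self.green, self.nir,
                                    self.swir, self.cloud_mask)}
        if len(shapes) != 1:
            raise ValueError(f"scene bands have mismatched shapes: {shapes}")
        self.cloud_mask = np.asarray(self.cloud_mask, dtype=bool)
        clear = ~self.cloud_mask
        for name in ("red", "green", "nir", "swir"):
            band = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, band)
            vals = band[clear]
            if vals.size and (not np.all(np.isfinite(vals))
                              or vals.min() < 0 or vals.max() > 1):
                raise ValueError(
                    f"{name} reflectance outside [0, 1] on clear pixels")

    @property
    def shape(self):
        return self.red.shape

    @property
    def cloud_fraction(self) -> float:
        return float(self.cloud_mask.mean())

    def to_file(self, path):
        """Write as a 5-band float32 TIFF (Red, Green, NIR, SWIR, mask)."""
        stack = np.stack([self.red, self.green, self.nir, self.swir,
                          self.cloud_mask.astype(np.float64)])
        meta = {"kind": "scene", "date": self.date.isoformat(),
                "bands": ["red", "green", "nir", "swir", "cloud_mask"],
                "georef": self.georef.to_dict()}
        tifffile.imwrite(path, stack.astype(np.float32),
                         photometric="minisblack",
                         description=json.dumps(meta))

    @classmethod
    def from_file(cls, path):
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray().astype(np.float64)
            meta = json.loads(tif.pages[0].description)
        if meta.get("kind") != "scene":
            raise ValueError(f"{path} is not a scene raster")
        return cls(red=stack[0], green=stack[1], nir=stack[2], swir=stack[3],
                   cloud_mask=stack[4] > 0.5,
                   date=_dt.date.fromisoformat(meta["date"]),
                   georef=GridGeoref.from_dict(meta["georef"]))


@dataclass
class IndexRaster:
    """A per-pixel spectral index with an explicit validity mask.

    Invalid pixels (cloud-masked or degenerate denominators) carry NaN in
    ``values`` and False in ``valid`` — they are never silently zero.
    """

    values: np.ndarray
    index_name: str
    valid: np.ndarray
    georef: GridGeoref = field(default_factory=GridGeoref)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")

    @property
    def shape(self):
        return self.values.shape

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.valid] = np.nan
        return out

    def copy(self) -> "IndexRaster":
        return replace(self, values=self.values.copy(),
                       valid=self.valid.copy())


# class codes of the two-mangrove-class legend
NON_MANGROVE = 0
RHIZOPHORA = 1
OTHER_MANGROVE = 2
CLASS_NAMES = {NON_MANGROVE: "non-mangrove",
               RHIZOPHORA: "Rhizophora mangle",
               OTHER_MANGROVE: "other dominant mangrove species"}
MANGROVE_INDICATOR = {NON_MANGROVE: 0, RHIZOPHORA: 1, OTHER_MANGROVE: 1}


@dataclass
class ClassRaster:
    """Categorical grid over {0 non-mangrove, 1 R. mangle, 2 other mangrove}."""

    labels: np.ndarray
    valid: np.ndarray
    period_label: object = "annual"  # (year, period) or "annual"
    georef: GridGeoref = field(default_factory=GridGeoref)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.labels.shape != self.valid.shape:
            raise ValueError("labels and valid mask shapes differ")
        known = np.isin(self.labels[self.valid],
                        [NON_MANGROVE, RHIZOPHORA, OTHER_MANGROVE])
        if not known.all():
            raise ValueError("unknown class code in label grid")

    @property
    def shape(self):
        return self.labels.shape

    def mangrove_indicator(self) -> np.ndarray:
        """Binary mangrove-presence grid (invalid pixels are 0; consult valid)."""
        return np.isin(self.labels, [RHIZOPHORA, OTHER_MANGROVE]).astype(np.int8)


def write_raster(path, array, georef: GridGeoref, *, kind="raster",
                 nodata=None, date=None, extra=None):
    """Write a single- or multi-band array with JSON-tagged georeferencing."""
    arr = np.asarray(array)
    meta = {"kind": kind, "georef": georef.to_dict()}
    if nodata is not None:
        meta["nodata"] = nodata
    if date is not None:
        meta["date"] = date.isoformat() if hasattr(date, "isoformat") else date
    if extra:
        meta.update(extra)
    tifffile.imwrite(path, arr, photometric="minisblack",
                     description=json.dumps(meta))


def read_raster(path):
    """Read an array and its metadata dict; returns (array, meta, georef)."""
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    georef = GridGeoref.from_dict(meta["georef"]) if "georef" in meta \
        else GridGeoref()
    return arr, meta, georef
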