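"""Spectral vegetation/water indices: NDVI, NDWI and the CMRI.

The Combined Mangrove Recognition Index (CMRI) is the difference between
a greenness term and a wetness term,

    CMRI = NDVI - NDWI
         = (NIR - Red)/(NIR + Red) - (NIR - SWIR)/(NIR + SWIR),

so it ranges over [-2, 2] and peaks over dense, wet mangrove canopy.
The default wetness term is the SWIR-based normalized difference; the
original green-band NDWI, (Green - NIR)/(Green + NIR), is available via
``ndwi_variant="green"`` for sensitivity checks.

Pixels under cloud or with a zero denominator are flagged invalid and
carry NaN — downstream maximum composites must be able to ignore them.
"""

from __future__ import annotations

import numpy as np

from .grids import IndexRaster, SceneStack

__all__ = ["compute_cmri", "compute_component", "normalized_difference"]

NDWI_VARIANTS = ("swir", "green")


def normalized_difference(a: np.ndarray, b: np.ndarray):
    """(a - b)/(a + b) with zero denominators flagged, not propagated.

    Returns (values, ok) where ``ok`` is False exactly where a + b == 0;
    values are NaN there.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    denom = a + b
    ok = denom != 0
    out = np.full(a.shape, np.nan)
    np.divide(a - b, denom, out=out, where=ok)
    return out, ok


def _check_scene(scene: SceneStack):
    if len({scene.red.shape, scene.nir.shape, scene.swir.shape,
            scene.green.shape}) != 1:
        raise ValueError("scene bands have mismatched shapes")


def compute_component(scene: SceneStack, which: str) -> IndexRaster:
    """Compute one component index of the CMRI.

    Parameters
    ----------
    which : {"NDVI", "NDWI_swir", "NDWI_green"}
        ``NDVI`` is (NIR-Red)/(NIR+Red); ``NDWI_swir`` is
        (NIR-SWIR)/(NIR+SWIR); ``NDWI_green`` is (Green-NIR)/(Green+NIR).
    """
    _check_scene(scene)
    if which == "NDVI":
        values, ok = normalized_difference(scene.nir, scene.red)
    elif which == "NDWI_swir":
        values, ok = normalized_difference(scene.nir, scene.swir)
    elif which == "NDWI_green":
        values, ok = normalized_difference(scene.green, scene.nir)
    else:
        raise ValueError(f"unknown index component {which!r}")
    valid = ok & ~scene.cloud_mask & np.isfinite(values)
    values = np.where(valid, values, np.nan)
    return IndexRaster(values=values, index_name=which, valid=valid,
                       georef=scene.georef)


def compute_cmri(scene: SceneStack, ndwi_variant: str = "swir") -> IndexRaster:
    """Per-pixel CMRI = NDVI - NDWI on clear pixels.

    A pixel is invalid if it is cloud-masked or either component has a
    zero denominator.
    """
    if ndwi_variant not in NDWI_VARIANTS:
        raise ValueError(f"ndwi_variant must be one of {NDWI_VARIANTS}")
    ndvi = compute_component(scene, "NDVI")
    ndwi = compute_component(scene, f"NDWI_{ndwi_variant}")
    valid = ndvi.valid & ndwi.valid
    values = np.where(valid, ndvi.values - ndwi.values, np.nan)
    return IndexRaster(values=values, index_name="CMRI", valid=valid,
                       georef=scene.georef)
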