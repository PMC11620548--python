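"""Seeded synthetic multitemporal scenes with known ground truth.

This module replaces the Sentinel-2 archive at desk scale.  It builds a
contiguous-patch coastal landscape over five cover classes (water,
terrestrial vegetation, bare/aquaculture, Rhizophora mangle, other
dominant mangrove species), injects dated loss/gain patches of known
area, and renders bimonthly reflectance scenes whose CMRI — when
computed from the rendered Red/NIR/SWIR bands — recovers a per-class
bimonthly phenology mean plus zero-mean Gaussian noise.  Random cloud
blobs exercise both scene-level filtering and per-pixel masking.

Band synthesis inverts the CMRI: Red and SWIR are fixed per class and
the NIR value solving

    c = (NIR - Red)/(NIR + Red) - (NIR - SWIR)/(NIR + SWIR)

is obtained in closed form (the equation reduces to a quadratic in
NIR), so only the index value is physically meaningful — no
atmospheric, BRDF or sensor physics is emulated.

The default phenology profiles are plausible fixtures for an
arid-region coast, not reconstructions of any measured trajectory:
mangrove classes sit well above the 0.35 extraction threshold in every
period and separate from each other on the shape of their seasonal
cycle; all other classes stay below it.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .grids import GridGeoref, SceneStack, RHIZOPHORA, OTHER_MANGROVE
from .accuracy import ValidationSet
from .compositing import PERIODS_PER_YEAR

__all__ = ["PhenologyProfile", "LandscapeTruth", "ChangeEvent",
           "build_landscape", "inject_change", "render_scenes",
           "default_profiles", "sample_validation_points",
           "pairwise_bayes_error",
           "WATER", "TERRESTRIAL", "BARE", "MANGROVE_RM", "MANGROVE_OTHER",
           "LANDSCAPE_CLASS_NAMES", "MANGROVE_LABELS", "landscape_to_scheme"]

# landscape truth codes (distinct from the 3-code classification scheme)
WATER, TERRESTRIAL, BARE, MANGROVE_RM, MANGROVE_OTHER = 0, 1, 2, 3, 4
LANDSCAPE_CLASS_NAMES = {WATER: "water", TERRESTRIAL: "terrestrial",
                         BARE: "bare", MANGROVE_RM: "rhizophora",
                         MANGROVE_OTHER: "other_mangrove"}
MANGROVE_LABELS = (MANGROVE_RM, MANGROVE_OTHER)
#: landscape code -> classification-scheme code
_SCHEME = {WATER: 0, TERRESTRIAL: 0, BARE: 0,
           MANGROVE_RM: RHIZOPHORA, MANGROVE_OTHER: OTHER_MANGROVE}


def landscape_to_scheme(label_grid: np.ndarray) -> np.ndarray:
    """Map landscape truth codes to {0, R. mangle=1, other mangrove=2}."""
    out = np.zeros_like(label_grid, dtype=np.uint8)
    for k, v in _SCHEME.items():
        out[label_grid == k] = v
    return out


@dataclass(frozen=True)
class PhenologyProfile:
    """Seasonal CMRI trajectory of one cover class.

    ``bimonthly_cmri_means`` holds six unitless values in [-2, 2], one
    per bimonthly period; ``bimonthly_sd`` the per-period noise standard
    deviation.
    """

    class_id: int
    bimonthly_cmri_means: tuple
    bimonthly_sd: tuple

    def __post_init__(self):
        means = tuple(float(m) for m in self.bimonthly_cmri_means)
        sd = self.bimonthly_sd
        if np.isscalar(sd):
            sd = (float(sd),) * PERIODS_PER_YEAR
        else:
            sd = tuple(float(s) for s in sd)
        object.__setattr__(self, "bimonthly_cmri_means", means)
        object.__setattr__(self, "bimonthly_sd", sd)
        if len(means) != PERIODS_PER_YEAR:
            raise ValueError("exactly 6 bimonthly means required")
        if len(sd) != PERIODS_PER_YEAR:
            raise ValueError("exactly 6 bimonthly sd values required")
        if any(s < 0 for s in sd):
            raise ValueError("noise sd must be non-negative")
        if any(not -2 <= m <= 2 for m in means):
            raise ValueError("CMRI means must lie in [-2, 2]")


def pairwise_bayes_error(p1: PhenologyProfile, p2: PhenologyProfile) -> float:
    """Bayes error of the two classes' 6-vectors under spherical noise.

    For equal-prior Gaussians with common spherical sd the optimal error
    is Phi(-d / (2 sigma)) with d the Euclidean distance of the means;
    a pooled rms sd is used when the per-period sds differ.
    """
    d = np.linalg.norm(np.subtract(p1.bimonthly_cmri_means,
                                   p2.bimonthly_cmri_means))
    sigma = np.sqrt(np.mean(np.square(p1.bimonthly_sd) +
                            np.square(p2.bimonthly_sd)) / 2.0)
    if sigma == 0:
        return 0.0 if d > 0 else 0.5
    return float(norm.sf(d / (2.0 * sigma)))


def default_profiles(mangrove_sd: float = 0.05) -> dict:
    """The study-condition phenology fixtures, keyed by landscape code.

    Mangrove means sit in [0.5, 0.8] (above the 0.35 threshold in every
    period) with opposed seasonal cycles; terrestrial vegetation peaks
    at 0.20, bare ground and water stay far below.  At the default sd
    of 0.05 the two mangrove trajectories have a Bayes error around
    2e-4, comfortably separable.
    """
    profiles = {
        WATER: PhenologyProfile(WATER,
                                (-0.60, -0.62, -0.65, -0.63, -0.61, -0.60),
                                0.02),
        TERRESTRIAL: PhenologyProfile(TERRESTRIAL,
                                      (0.12, 0.15, 0.18, 0.20, 0.17, 0.13),
                                      0.04),
        BARE: PhenologyProfile(BARE,
                               (0.08, 0.08, 0.09, 0.10, 0.09, 0.08),
                               0.03),
        MANGROVE_RM: PhenologyProfile(MANGROVE_RM,
                                      (0.55, 0.60, 0.70, 0.80, 0.75, 0.62),
                                      mangrove_sd),
        MANGROVE_OTHER: PhenologyProfile(MANGROVE_OTHER,
                                         (0.70, 0.62, 0.55, 0.58, 0.65, 0.75),
                                         mangrove_sd),
    }
    err = pairwise_bayes_error(profiles[MANGROVE_RM],
                               profiles[MANGROVE_OTHER])
    if err >= 0.05:
        raise ValueError(f"mangrove profiles not separable: Bayes error "
                         f"{err:.3f} >= 0.05")
    return profiles


@dataclass(frozen=True)
class ChangeEvent:
    mask: np.ndarray          # boolean patch
    kind: str                 # "loss" or "gain"
    date: _dt.date
    new_label: int

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class LandscapeTruth:
    """Ground-truth label grid plus dated change events.

    ``label_grid`` is the pre-change state; :meth:`labels_at` applies
    every event dated on or before the query date.
    """

    label_grid: np.ndarray
    pixel_size: float = 10.0
    georef: GridGeoref = field(default_factory=GridGeoref)
    change_events: list = field(default_factory=list)

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid)
        known = np.isin(self.label_grid, list(LANDSCAPE_CLASS_NAMES))
        if not known.all():
            raise ValueError("label grid contains unknown class codes")
        claimed = np.zeros(self.label_grid.shape, dtype=bool)
        for ev in self.change_events:
            if (claimed & ev.mask).any():
                raise ValueError("a pixel carries more than one change event")
            claimed |= ev.mask

    @property
    def shape(self):
        return self.label_grid.shape

    def labels_at(self, date: _dt.date) -> np.ndarray:
        grid = self.label_grid.copy()
        for ev in sorted(self.change_events, key=lambda e: e.date):
            if ev.date <= date:
                grid[ev.mask] = ev.new_label
        return grid

    def mangrove_area_ha(self, date: _dt.date) -> float:
        n = int(np.isin(self.labels_at(date), MANGROVE_LABELS).sum())
        return n * self.pixel_size ** 2 / 10000.0

    def class_fractions_at(self, date: _dt.date) -> dict:
        grid = self.labels_at(date)
        n = grid.size
        return {k: float((grid == k).sum()) / n for k in LANDSCAPE_CLASS_NAMES}

    def events_to_geojson(self, path):
        """Write change-event footprints as GeoJSON polygons with
        ``event`` and ``date`` properties."""
        import json
        import shapely
        from .vectorize import _component_polygon
        feats = []
        for ev in self.change_events:
            rr, cc = np.nonzero(ev.mask)
            geom = _component_polygon(rr, cc, self.georef)
            feats.append({"type": "Feature",
                          "geometry": shapely.geometry.mapping(geom),
                          "properties": {"event": ev.kind,
                                         "date": ev.date.isoformat(),
                                         "area_px": ev.area_px}})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection",
                       "crs_name": self.georef.crs, "features": feats}, fh)


def build_landscape(seed: int, shape=(256, 256), class_fractions=None,
                    patch_scale: int = 12, pixel_size: float = 10.0,
                    georef: GridGeoref = None) -> LandscapeTruth:
    """Contiguous-patch landscape with near-exact class fractions.

    A Gaussian-smoothed random field (correlation length ``patch_scale``
    pixels) is ranked and cut at the cumulative class fractions, so
    per-class pixel counts match the request to rounding (far inside the
    +/-2 percentage-point contract) and every class forms contiguous
    blobs.  Classes are assigned to field quantiles in a coast-like
    order: water in the lowest band, then the two mangrove classes,
    then terrestrial vegetation and bare ground.
    """
    if class_fractions is None:
        class_fractions = {WATER: 0.30, MANGROVE_RM: 0.20,
                           MANGROVE_OTHER: 0.20, TERRESTRIAL: 0.20,
                           BARE: 0.10}
    total = sum(class_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions sum to {total}, not 1")
    shape = tuple(shape)
    if min(shape) < 32:
        raise ValueError("landscape must be at least 32x32")
    if patch_scale >= min(shape):
        raise ValueError("patch_scale larger than the grid")
    rng = np.random.default_rng(seed)
    fieldv = ndimage.gaussian_filter(rng.standard_normal(shape),
                                     sigma=patch_scale, mode="wrap")
    order = np.argsort(fieldv, axis=None, kind="stable")
    n = fieldv.size
    grid = np.empty(n, dtype=np.uint8)
    start = 0
    items = list(class_fractions.items())
    for i, (label, frac) in enumerate(items):
        stop = n if i == len(items) - 1 else start + int(round(frac * n))
        grid[order[start:stop]] = label
        start = stop
    grid = grid.reshape(shape)
    if georef is None:
        georef = GridGeoref(pixel_size=pixel_size)
    return LandscapeTruth(label_grid=grid, pixel_size=pixel_size,
                          georef=georef)


def _grow_patch(eligible: np.ndarray, area_px: int, rng) -> np.ndarray:
    """Grow one contiguous patch of area_px inside the eligible mask."""
    rows, cols = np.nonzero(eligible)
    if rows.size < area_px:
        raise ValueError(
            f"insufficient eligible area: {rows.size} px available, "
            f"{area_px} requested")
    h, w = eligible.shape
    for _ in range(50):
        k = rng.integers(rows.size)
        seed_px = (int(rows[k]), int(cols[k]))
        patch = np.zeros_like(eligible)
        frontier = [seed_px]
        patch[seed_px] = True
        count = 1
        while frontier and count < area_px:
            r, c = frontier.pop(rng.integers(len(frontier)))
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and eligible[rr, cc] \
                        and not patch[rr, cc]:
                    patch[rr, cc] = True
                    frontier.append((rr, cc))
                    count += 1
                    if count == area_px:
                        break
        if count == area_px:
            return patch
    raise ValueError(f"could not grow a contiguous {area_px}-px patch "
                     "in the eligible area")


def inject_change(truth: LandscapeTruth, n_loss: int, n_gain: int,
                  area_px: int, event_year: int, seed: int,
                  loss_label: int = BARE,
                  gain_label: int = MANGROVE_OTHER,
                  gain_substrate=(BARE,),
                  event_date: _dt.date = None) -> LandscapeTruth:
    """Add dated contiguous loss/gain patches of known pixel area.

    Loss patches (clearance) convert mangrove pixels to ``loss_label``;
    gain patches (seedling colonization) convert eligible non-mangrove
    substrate (bare ground by default) to ``gain_label``.  Events take
    effect from ``event_date`` (default: 1 January of ``event_year``).
    The input truth is not modified.
    """
    if event_date is None:
        event_date = _dt.date(event_year, 1, 1)
    rng = np.random.default_rng(seed)
    out = replace(truth, change_events=list(truth.change_events))
    if n_loss == 0 and n_gain == 0:
        return out
    state = truth.labels_at(event_date)
    claimed = np.zeros(truth.shape, dtype=bool)
    for ev in out.change_events:
        claimed |= ev.mask
    for kind, count, elig_labels, new_label in (
            ("loss", n_loss, MANGROVE_LABELS, loss_label),
            ("gain", n_gain, tuple(gain_substrate), gain_label)):
        for _ in range(count):
            eligible = np.isin(state, elig_labels) & ~claimed
            patch = _grow_patch(eligible, area_px, rng)
            claimed |= patch
            out.change_events.append(ChangeEvent(mask=patch, kind=kind,
                                                 date=event_date,
                                                 new_label=new_label))
    return out


# per-class fixed (Red, SWIR) pairs for the CMRI inversion; the positive
# branch needs SWIR > Red, the negative branch the reverse
_BANDS_POS = (0.02, 0.40)
_BANDS_NEG = (0.50, 0.05)
_GREEN = {WATER: 0.06, TERRESTRIAL: 0.07, BARE: 0.12,
          MANGROVE_RM: 0.05, MANGROVE_OTHER: 0.05}
_CLOUD_REFLECTANCE = 0.9


def _cmri_of_nir(N, R, S):
    return (N - R) / (N + R) - (N - S) / (N + S)


def _invert_cmri(c: np.ndarray, R: float, S: float) -> np.ndarray:
    """NIR reflectance whose CMRI (with fixed Red, SWIR) equals c.

    The defining equation reduces to the quadratic
    c N^2 + (c(R+S) - 2(S-R)) N + c R S = 0; the smaller positive root
    always lies in (0, sqrt(RS)] for attainable c, and one Newton step
    polishes it to machine precision.
    """
    c = np.asarray(c, dtype=np.float64)
    a = c
    b = c * (R + S) - 2.0 * (S - R)
    d = c * R * S
    disc = np.maximum(b * b - 4.0 * a * d, 0.0)
    sq = np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = (-b + sq) / (2.0 * a)
        r2 = (-b - sq) / (2.0 * a)
    roots = np.stack([r1, r2])
    valid = (roots > 0) & (roots <= 1) & np.isfinite(roots)
    N = np.where(valid, roots, np.inf).min(axis=0)
    if not np.all(np.isfinite(N)):
        raise ValueError("CMRI value outside the invertible range for the "
                         "class band constants")
    # Newton polish: f(N) = cmri(N) - c
    for _ in range(2):
        f = _cmri_of_nir(N, R, S) - c
        fp = 2.0 * R / (N + R) ** 2 - 2.0 * S / (N + S) ** 2
        step = np.where(fp != 0, f / np.where(fp != 0, fp, 1.0), 0.0)
        N = np.clip(N - step, 1e-12, 1.0)
    return N


def _attainable_range(R: float, S: float):
    n_star = np.sqrt(R * S)
    extreme = _cmri_of_nir(n_star, R, S)
    if extreme > 0:
        return 1e-6, 0.99 * extreme
    return 0.99 * extreme, -1e-6


def _cloud_blob_mask(shape, fraction: float, rng, blob_scale: float = 6.0):
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    fieldv = ndimage.gaussian_filter(rng.standard_normal(shape),
                                     sigma=blob_scale)
    cut = np.quantile(fieldv, 1.0 - fraction)
    return fieldv >= cut


def _period_dates(year: int, period: int, k: int, rng):
    """k dates drawn uniformly within the bimonthly period."""
    m0 = 2 * period - 1
    start = _dt.date(year, m0, 1)
    end = _dt.date(year, m0 + 1, calendar.monthrange(year, m0 + 1)[1])
    span = (end - start).days
    offsets = np.sort(rng.integers(0, span + 1, size=k))
    return [start + _dt.timedelta(days=int(o)) for o in offsets]


def render_scenes(truth: LandscapeTruth, profiles: dict, years,
                  scenes_per_period: int = 5,
                  cloud_fraction_range=(0.0, 0.12), seed: int = 0,
                  start_year: int = 2019) -> list:
    """Render 6 x years x scenes_per_period dated reflectance scenes.

    ``years`` may be a count (calendar years start at ``start_year``) or
    an explicit list of calendar years.  Per scene, a cloud fraction is
    drawn uniformly from ``cloud_fraction_range`` and realized as
    contiguous bright blobs flagged in the cloud mask; on clear pixels
    the CMRI computed from the rendered bands equals the class/period
    profile mean plus zero-mean noise with the profile sd (values are
    clipped to the invertible CMRI range of the class band constants,
    a negligible correction for the default profiles).
    """
    if np.isscalar(years):
        if years < 1:
            raise ValueError("years must be >= 1")
        years = [start_year + i for i in range(int(years))]
    years = sorted(years)
    present = np.unique(truth.label_grid)
    for ev in truth.change_events:
        present = np.union1d(present, [ev.new_label])
    missing = [int(lab) for lab in present if lab not in profiles]
    if missing:
        raise ValueError(f"no phenology profile for truth labels {missing}")
    rng = np.random.default_rng(seed)
    lo, hi = cloud_fraction_range
    scenes = []
    for year in years:
        for period in range(1, PERIODS_PER_YEAR + 1):
            for date in _period_dates(year, period, scenes_per_period, rng):
                labels = truth.labels_at(date)
                red = np.empty(truth.shape)
                swir = np.empty(truth.shape)
                nir = np.empty(truth.shape)
                green = np.empty(truth.shape)
                for lab in np.unique(labels):
                    prof = profiles[int(lab)]
                    sel = labels == lab
                    mean = prof.bimonthly_cmri_means[period - 1]
                    sd = prof.bimonthly_sd[period - 1]
                    c = mean + sd * rng.standard_normal(int(sel.sum()))
                    R, S = _BANDS_POS if mean > 0 else _BANDS_NEG
                    cmin, cmax = _attainable_range(R, S)
                    c = np.clip(c, cmin, cmax)
                    red[sel], swir[sel] = R, S
                    nir[sel] = _invert_cmri(c, R, S)
                    green[sel] = _GREEN.get(int(lab), 0.08)
                frac = rng.uniform(lo, hi)
                cloud = _cloud_blob_mask(truth.shape, frac, rng)
                for band in (red, green, nir, swir):
                    band[cloud] = _CLOUD_REFLECTANCE
                scenes.append(SceneStack(red=red, green=green, nir=nir,
                                         swir=swir, cloud_mask=cloud,
                                         date=date, georef=truth.georef))
    return scenes


def sample_validation_points(truth: LandscapeTruth, date: _dt.date,
                             n_per_class: int = 240,
                             min_patch_px: int = 4, seed: int = 0,
                             connectivity: int = 4) -> ValidationSet:
    """Equal-proportion mangrove validation points from the truth labels.

    Points are drawn only inside truth patches of at least
    ``min_patch_px`` pixels (4 pixels of 10 m is about 400 m^2, the
    minimum footprint interpretable on a validation photograph) and are
    placed at pixel centers.
    """
    rng = np.random.default_rng(seed)
    labels = truth.labels_at(date)
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4
                                                  else 2)
    records = []
    for lab in MANGROVE_LABELS:
        mask = labels == lab
        comp, n = ndimage.label(mask, structure=structure)
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        big = np.isin(comp, 1 + np.nonzero(sizes >= min_patch_px)[0])
        rows, cols = np.nonzero(big)
        if rows.size < n_per_class:
            raise ValueError(
                f"only {rows.size} eligible pixels for class {lab}, "
                f"{n_per_class} points requested")
        pick = rng.choice(rows.size, size=n_per_class, replace=False)
        x, y = truth.georef.pixel_center(rows[pick], cols[pick])
        records.append(pd.DataFrame({"x": x, "y": y,
                                     "label": _SCHEME[lab]}))
    points = pd.concat(records, ignore_index=True)
    return ValidationSet(points=points, epoch=date.isoformat(),
                         min_unit_m2=min_patch_px *
                         truth.pixel_size ** 2)
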