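"""Thematic accuracy assessment: error matrix, accuracy metrics, kappa.

The assessment follows the traditional confusion-matrix approach for
the two mangrove classes only.  Orientation is fixed as rows =
reference data, columns = mapped class, so for class c

    user's accuracy    = 100 * counts[c][c] / column_total(c)
    producer's accuracy = 100 * counts[c][c] / row_total(c)
    commission error    = 100 - user's accuracy
    omission error      = 100 - producer's accuracy

and overall accuracy = 100 * trace / n.  The kappa coefficient is the
chance-corrected agreement

    kappa = (p_o - p_e) / (1 - p_e),
    p_o = trace / n,   p_e = sum_c row_total(c) * col_total(c) / n^2.

Because the two-class matrix is nearly symmetric, reports print both
orientations to avoid ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClassRaster, RHIZOPHORA, OTHER_MANGROVE, CLASS_NAMES

__all__ = ["ValidationSet", "ConfusionMatrix", "build_confusion",
           "accuracy_metrics", "kappa", "MIN_INTERPRETATION_UNIT_M2"]

log = logging.getLogger(__name__)

#: smallest footprint interpretable on a validation photograph: 4 pixels
#: of 10 m, approximately 400 m^2
MIN_INTERPRETATION_UNIT_M2 = 400.0


@dataclass
class ValidationSet:
    """Reference points restricted to the two mangrove classes."""

    points: pd.DataFrame  # columns: x, y, label (1 or 2)
    epoch: str = ""
    min_unit_m2: float = MIN_INTERPRETATION_UNIT_M2

    def __post_init__(self):
        required = {"x", "y", "label"}
        if not required <= set(self.points.columns):
            raise ValueError(f"validation points need columns {required}")
        labs = set(self.points["label"].unique())
        if not labs <= {RHIZOPHORA, OTHER_MANGROVE}:
            raise ValueError("validation labels must be the two mangrove "
                             f"classes {{1, 2}}, got {labs}")

    def __len__(self):
        return len(self.points)

    @classmethod
    def from_csv(cls, path, **kw):
        return cls(points=pd.read_csv(path), **kw)

    def to_csv(self, path):
        self.points.to_csv(path, index=False)


@dataclass
class ConfusionMatrix:
    """2x2 error matrix; rows = reference class, columns = mapped class."""

    counts: np.ndarray
    labels: tuple = (RHIZOPHORA, OTHER_MANGROVE)
    excluded: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape does not match the class list")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_counts(cls, counts, labels=(RHIZOPHORA, OTHER_MANGROVE)):
        return cls(counts=np.asarray(counts), labels=tuple(labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_totals(self):
        return self.counts.sum(axis=1)

    def col_totals(self):
        return self.counts.sum(axis=0)

    def as_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES[c] for c in self.labels]
        df = pd.DataFrame(self.counts, index=names, columns=names)
        df.index.name = "reference"
        df.columns.name = "mapped"
        return df


def build_confusion(class_map: ClassRaster,
                    validation: ValidationSet) -> ConfusionMatrix:
    """Cross-tabulate reference labels against the mapped class.

    Points falling on non-mangrove or invalid pixels are excluded with a
    warning (their count is recorded on the matrix).
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    pts = validation.points
    rows, cols = class_map.georef.world_to_pixel(pts["x"].to_numpy(),
                                                 pts["y"].to_numpy())
    h, w = class_map.shape
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    mapped = np.zeros(len(pts), dtype=int)
    mapped[inside] = class_map.labels[rows[inside], cols[inside]]
    usable = inside.copy()
    usable[inside] &= class_map.valid[rows[inside], cols[inside]]
    usable &= np.isin(mapped, list((RHIZOPHORA, OTHER_MANGROVE)))
    excluded = int((~usable).sum())
    if excluded:
        log.warning("%d validation points on non-mangrove or invalid "
                    "pixels excluded from the error matrix", excluded)
    labels = (RHIZOPHORA, OTHER_MANGROVE)
    counts = np.zeros((2, 2), dtype=np.int64)
    ref = pts["label"].to_numpy()
    for i, r in enumerate(labels):
        for j, m in enumerate(labels):
            counts[i, j] = np.count_nonzero(usable & (ref == r) &
                                            (mapped == m))
    if counts.sum() == 0:
        raise ValueError("no usable validation points fell on mapped "
                         "mangrove pixels")
    return ConfusionMatrix(counts=counts, labels=labels, excluded=excluded)


def accuracy_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Overall, user's and producer's accuracies and the error rates.

    Values are reported at one decimal (``pct``) and at integer percent
    (``pct_rounded``).  A zero row or column total leaves the class's
    metrics NaN and is flagged in the log.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    rt, ct = cm.row_totals(), cm.col_totals()
    for i, c in enumerate(cm.labels):
        diag = cm.counts[i, i]
        user = 100.0 * diag / ct[i] if ct[i] else np.nan
        prod = 100.0 * diag / rt[i] if rt[i] else np.nan
        if not ct[i] or not rt[i]:
            log.warning("zero marginal total for class %s: metrics "
                        "undefined", CLASS_NAMES[c])
        for metric, value in (("users_accuracy", user),
                              ("producers_accuracy", prod),
                              ("commission_error", 100.0 - user),
                              ("omission_error", 100.0 - prod)):
            rows.append({"class": CLASS_NAMES[c], "metric": metric,
                         "pct": np.round(value, 1),
                         "pct_rounded": np.round(value).astype(int)
                         if np.isfinite(value) else np.nan})
    oa = 100.0 * np.trace(cm.counts) / cm.n
    rows.append({"class": "all", "metric": "overall_accuracy",
                 "pct": np.round(oa, 1), "pct_rounded": int(np.round(oa))})
    return pd.DataFrame(rows, columns=["class", "metric", "pct",
                                       "pct_rounded"])


def kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement coefficient of the error matrix."""
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    pe = float(np.sum(cm.row_totals() * cm.col_totals())) / (n * n)
    if pe == 1.0:
        raise ValueError("chance agreement p_e = 1: kappa undefined "
                         "(all mass in one class on both axes)")
    return (po - pe) / (1.0 - pe)


def report_text(cm: ConfusionMatrix) -> str:
    """Human-readable error-matrix block in both orientations."""
    metrics = accuracy_metrics(cm)
    lines = ["Error matrix (rows = reference, columns = mapped):",
             cm.as_frame().to_string(), ""]
    flipped = ConfusionMatrix(counts=cm.counts.T, labels=cm.labels) \
        .as_frame()
    flipped.index.name, flipped.columns.name = "mapped", "reference"
    lines += ["Transposed orientation (rows = mapped, columns = reference):",
              flipped.to_string(), "",
              metrics.to_string(index=False),
              f"kappa: {kappa(cm):.2f}", f"n: {cm.n}"]
    if cm.excluded:
        lines.append(f"excluded points: {cm.excluded}")
    return "\n".join(lines)
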