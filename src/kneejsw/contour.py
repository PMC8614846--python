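"""Articular margin extraction and the normalized tibial-plateau frame.

From a bone label mask, the joint space is bounded above by the inferior
femoral margin (bottommost femur pixel per column) and below by the superior
tibial margin (topmost tibia pixel per column).  On a binary raster these
per-column extremal boundaries coincide with what an edge detector would
trace, but are deterministic and parameter-free.  Margins use the pixel-edge
convention: pixel (r, c) occupies [r-0.5, r+0.5] x [c-0.5, c+0.5], so the
femoral margin sits at (bottom row + 0.5) and the tibial margin at
(top row - 0.5).

The horizontal extent of the tibial margin (restricted to columns where the
femur overlaps) is normalized to x in [0, 1].  All downstream measurements
place the medial compartment at high x; for a left knee the frame mirrors
the axis so this convention always holds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneratePlateauError, NoJointOverlapError, OrientationError
from .imaging import LabelMask

__all__ = ["ArticularMargin", "PlateauFrame", "extract_margins", "build_frame"]

FEMUR, TIBIA = 1, 2


@dataclass
class ArticularMargin:
    """One bone's articular boundary: one sub-pixel row per column.

    ``columns`` is a contiguous, strictly increasing integer range; ``rows``
    holds the margin position per column on the pixel-edge convention.
    """

    bone: str
    columns: np.ndarray
    rows: np.ndarray

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=int)
        self.rows = np.asarray(self.rows, dtype=float)
        if self.columns.size != self.rows.size:
            raise ValueError("columns and rows must have equal length")
        if self.columns.size and np.any(np.diff(self.columns) != 1):
            raise ValueError("margin columns must be contiguous and increasing")

    @property
    def column_range(self) -> tuple[int, int]:
        return int(self.columns[0]), int(self.columns[-1])

    def row_at(self, column: int) -> float:
        c0, c1 = self.column_range
        if not c0 <= column <= c1:
            raise KeyError(f"column {column} outside margin range [{c0}, {c1}]")
        return float(self.rows[column - c0])


@dataclass
class PlateauFrame:
    """Affine map between image columns and normalized plateau coordinate x.

    ``c0`` maps to x=0 and ``c1`` to x=1 *before* any mirroring; when
    ``mirrored`` is set (left knees), x -> 1-x so the medial compartment
    always lies at high x.  ``row_mm``/``col_mm`` carry pixel spacing.
    """

    c0: float
    c1: float
    mirrored: bool
    row_mm: float
    col_mm: float
    medial_high_x: bool = True

    def to_x(self, column) -> np.ndarray | float:
        x = (np.asarray(column, dtype=float) - self.c0) / (self.c1 - self.c0)
        if self.mirrored:
            x = 1.0 - x
        return x if np.ndim(column) else float(x)

    def to_column(self, x) -> np.ndarray | float:
        xv = np.asarray(x, dtype=float)
        if self.mirrored:
            xv = 1.0 - xv
        c = self.c0 + xv * (self.c1 - self.c0)
        return c if np.ndim(x) else float(c)


def _per_column_extreme(labels: np.ndarray, class_id: int, lowest: bool):
    """Per-column bottommost (lowest=True) or topmost row of a class."""
    present = labels == class_id
    any_col = present.any(axis=0)
    rows = np.arange(labels.shape[0])[:, None]
    if lowest:
        ext = np.where(present, rows, -1).max(axis=0)
    else:
        ext = np.where(present, rows, labels.shape[0] + 1).min(axis=0)
    return any_col, ext


def extract_margins(mask: LabelMask) -> tuple[ArticularMargin, ArticularMargin]:
    """Extract the inferior femoral and superior tibial articular margins.

    Margins are restricted to the largest contiguous run of columns where
    both bones are present.  Raises :class:`NoJointOverlapError` when femur
    and tibia share no columns and :class:`OrientationError` when the femur
    does not lie above the tibia there.
    """
    labels = mask.labels
    has_f, bottom_f = _per_column_extreme(labels, FEMUR, lowest=True)
    has_t, top_t = _per_column_extreme(labels, TIBIA, lowest=False)
    if not has_f.any() or not has_t.any():
        raise NoJointOverlapError("mask must contain both femur and tibia pixels")
    shared = has_f & has_t
    if not shared.any():
        raise NoJointOverlapError("femur and tibia share no image columns")

    # largest contiguous run of shared columns
    idx = np.flatnonzero(shared)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, idx.size - 1]
    run = int(np.argmax(ends - starts))
    cols = idx[starts[run]: ends[run] + 1]

    f_rows = bottom_f[cols].astype(float) + 0.5
    t_rows = top_t[cols].astype(float) - 0.5
    if np.median(f_rows) >= np.median(t_rows):
        raise OrientationError("femur lies below tibia; image orientation is wrong")
    femur = ArticularMargin(bone="femur", columns=cols, rows=f_rows)
    tibia = ArticularMargin(bone="tibia", columns=cols, rows=t_rows)
    return femur, tibia


def build_frame(tibia: ArticularMargin, laterality: str,
                row_mm: float, col_mm: float,
                medial_side: str | None = None) -> PlateauFrame:
    """Normalize the tibial-plateau extent to x in [0, 1], medial at high x.

    ``laterality`` 'right' places the medial compartment at high columns
    (package convention for an AP film) and 'left' mirrors it; 'unknown'
    requires an explicit ``medial_side`` override of 'high' or 'low'
    (columns).  A margin spanning fewer than 10 columns is degenerate.
    """
    c0, c1 = tibia.column_range
    if c1 - c0 + 1 < 10:
        raise DegeneratePlateauError(
            f"tibial margin spans only {c1 - c0 + 1} columns (< 10)")
    if medial_side is not None:
        if medial_side not in ("high", "low"):
            raise ValueError("medial_side must be 'high' or 'low'")
        mirrored = medial_side == "low"
    elif laterality == "right":
        mirrored = False
    elif laterality == "left":
        mirrored = True
    else:
        raise ValueError(
            "laterality is unknown; supply medial_side='high'|'low' explicitly")
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError("pixel spacing must be positive")
    return PlateauFrame(c0=float(c0), c1=float(c1), mirrored=mirrored,
                        row_mm=float(row_mm), col_mm=float(col_mm))
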