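"""Joint-space-width measurement in the normalized plateau frame.

Two complementary measurements are produced from the femoral and tibial
articular margins:

* **multi-point JSW** — the vertical (row-direction) inter-margin distance
  sampled at fixed normalized sites in the lateral ([0.10, 0.30)) and medial
  ([0.70, 0.90)) compartments.  The half-open sampling convention with equal
  compartment widths of 0.2 gives n/2 sites per compartment at spacing
  0.4/n, i.e. 0.05, 0.025, 0.0125 and 0.00625 for 8-, 16-, 32- and 64-point
  profiles, and makes dyadic grids nest exactly.
* **minimum JSW** — the smallest Euclidean distance between any femoral and
  any tibial margin point whose x lies in the medial search window
  [0.7, 0.9], found by exhaustive all-pairs search.

Widths are calibrated to millimetres via the pixel spacing carried by the
frame (vertical widths use row_mm; Euclidean distances use both axes).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contour import ArticularMargin, PlateauFrame
from .errors import MissingSiteError, ProfileInvalidError

__all__ = [
    "SamplingGrid",
    "JSWProfile",
    "MinJSW",
    "sample_sites",
    "width_at",
    "multi_jsw",
    "min_jsw",
    "calibrate",
]


@dataclass(frozen=True)
class SamplingGrid:
    """Fixed normalized sampling sites, split between the two compartments.

    ``n_points`` must be even; half the sites fall in each compartment.  The
    default ranges are half-open intervals of equal width 0.2, which is the
    unique convention under which spacings 0.05/0.025/0.0125/0.00625 give
    8/16/32/64 sites.
    """

    n_points: int = 16
    lateral_range: tuple[float, float] = (0.10, 0.30)
    medial_range: tuple[float, float] = (0.70, 0.90)

    def __post_init__(self):
        if self.n_points <= 0 or self.n_points % 2:
            raise ValueError("n_points must be a positive even count")
        la, lb = self.lateral_range
        ma, mb = self.medial_range
        if not (0 <= la < lb <= ma < mb <= 1):
            raise ValueError("ranges must be ordered, disjoint and inside [0, 1]")
        if abs((lb - la) - (mb - ma)) > 1e-12:
            raise ValueError("compartment ranges must have equal width")

    @property
    def spacing(self) -> float:
        return (self.lateral_range[1] - self.lateral_range[0]) / (self.n_points // 2)


@dataclass
class JSWProfile:
    """Widths at the grid sites, ordered by x (lateral block then medial)."""

    sites: list[tuple[float, float]]          # (x, width_mm)
    n: int
    calibration: tuple[float, float]          # (row_mm, col_mm) used
    imputed: list[bool] = field(default_factory=list)

    @property
    def x(self) -> np.ndarray:
        return np.array([s[0] for s in self.sites])

    @property
    def widths(self) -> np.ndarray:
        return np.array([s[1] for s in self.sites])

    @property
    def n_imputed(self) -> int:
        return int(sum(self.imputed))


@dataclass
class MinJSW:
    """Minimum Euclidean inter-margin distance in the medial window."""

    width: float                              # mm
    at: tuple[float, float]                   # (x_femur, x_tibia) of the pair
    search_window: tuple[float, float] = (0.7, 0.9)


def sample_sites(grid: SamplingGrid) -> np.ndarray:
    """Half-open site sets {a + k*spacing : k = 0..n/2-1}, lateral then medial."""
    k = np.arange(grid.n_points // 2)
    lat = grid.lateral_range[0] + k * grid.spacing
    med = grid.medial_range[0] + k * grid.spacing
    return np.concatenate([lat, med])


def width_at(x: float, femur: ArticularMargin, tibia: ArticularMargin,
             frame: PlateauFrame) -> float:
    """Vertical inter-margin distance (mm) at the column nearest to x.

    Raises :class:`MissingSiteError` when x maps outside the overlap of the
    two margins.  A negative gap (margins crossing, plausible for
    bone-on-bone KL4 joints) is clamped to zero with a warning.
    """
    c = int(round(frame.to_column(x)))
    f0, f1 = femur.column_range
    t0, t1 = tibia.column_range
    if not (max(f0, t0) <= c <= min(f1, t1)):
        raise MissingSiteError(x)
    w_px = tibia.row_at(c) - femur.row_at(c)
    if w_px < 0:
        warnings.warn(f"margins cross at x={x:g} (gap {w_px:.2f} px); clamping to 0",
                      stacklevel=2)
        w_px = 0.0
    return calibrate(w_px, frame.row_mm)


def multi_jsw(femur: ArticularMargin, tibia: ArticularMargin,
              frame: PlateauFrame, grid: SamplingGrid) -> JSWProfile:
    """Widths at every grid site; missing sites are imputed and flagged.

    A site whose column falls outside the margin overlap copies the width of
    the nearest valid site (by |x| distance).  More than 25% missing sites
    raise :class:`ProfileInvalidError`.
    """
    xs = sample_sites(grid)
    widths = np.full(xs.size, np.nan)
    for i, x in enumerate(xs):
        try:
            widths[i] = width_at(float(x), femur, tibia, frame)
        except MissingSiteError:
            pass
    missing = np.isnan(widths)
    if missing.sum() > 0.25 * xs.size:
        raise ProfileInvalidError(
            f"{int(missing.sum())}/{xs.size} sites missing (> 25%)")
    if missing.any():
        valid = np.flatnonzero(~missing)
        for i in np.flatnonzero(missing):
            widths[i] = widths[valid[np.argmin(np.abs(xs[valid] - xs[i]))]]
    return JSWProfile(sites=list(zip(xs.tolist(), widths.tolist())),
                      n=grid.n_points,
                      calibration=(frame.row_mm, frame.col_mm),
                      imputed=missing.tolist())


def min_jsw(femur: ArticularMargin, tibia: ArticularMargin,
            frame: PlateauFrame, search_window: tuple[float, float] = (0.7, 0.9)) -> MinJSW:
    """Exhaustive all-pairs minimum distance between the margins.

    Both margins are restricted to points with x inside the search window;
    every femoral-tibial point pair is scored by the Euclidean distance
    sqrt((drow*row_mm)^2 + (dcol*col_mm)^2) and the smallest is returned.
    """
    lo, hi = search_window

    def _window(margin: ArticularMargin):
        xs = frame.to_x(margin.columns)
        keep = (xs >= lo) & (xs <= hi)
        return margin.columns[keep], margin.rows[keep], xs[keep]

    fc, fr, fx = _window(femur)
    tc, tr, tx = _window(tibia)
    if fc.size == 0 or tc.size == 0:
        raise MissingSiteError(lo, f"no margin points inside window [{lo}, {hi}]")
    drow = (tr[None, :] - fr[:, None]) * frame.row_mm
    dcol = (tc[None, :].astype(float) - fc[:, None]) * frame.col_mm
    d2 = drow * drow + dcol * dcol
    i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
    return MinJSW(width=float(np.sqrt(d2[i, j])),
                  at=(float(fx[i]), float(tx[j])),
                  search_window=(lo, hi))


def calibrate(width_pixels: float, mm_per_pixel: float) -> float:
    """Convert a pixel distance to millimetres."""
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    return float(width_pixels) * float(mm_per_pixel)
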