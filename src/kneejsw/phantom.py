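"""Synthetic knee phantoms with analytically known joint-space geometry.

Real tibiofemoral radiographs come with no ground truth for the joint-space
gap, so every downstream stage (contour extraction, width sampling, minimum
search, agreement statistics, severity models) is validated here against
phantoms whose femoral and tibial margins are constructed from explicit
curves.  Three generators are provided:

* :func:`make_phantom` — a radiograph/label-mask pair whose per-column
  femur–tibia pixel gap encodes a prescribed gap profile g(x) in mm exactly
  (the profile is quantized to whole pixel rows at construction, and the
  quantized profile is what the truth records);
* :func:`make_observer_pairs` — paired measurements ``b = a + bias + noise``
  emulating two observers reading the same joints;
* :func:`make_cohort` — a per-knee feature/label table in which the joint
  narrows with Kellgren–Lawrence (KL) grade, for severity and progression
  experiments.

Conventions: image rows increase downward, so the femur (smaller row index)
sits above the tibia.  Normalized plateau coordinate x runs 0→1 with the
medial compartment at high x; a *right* knee renders medial at high columns
and a *left* knee is its mirror image.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import InvalidSpecError
from .imaging import LabelMask, Radiograph

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_observer_pairs",
    "make_cohort",
    "parabolic_gap",
    "constant_gap",
]

# KL-grade prevalence in a typical baseline knee-OA screening cohort
KL_PREVALENCE = np.array([0.386, 0.181, 0.264, 0.137, 0.032])
KL_PREVALENCE = KL_PREVALENCE / KL_PREVALENCE.sum()


def constant_gap(width_mm: float) -> Callable[[np.ndarray], np.ndarray]:
    """Gap profile g(x) = width_mm for all x."""
    return lambda x: np.full_like(np.asarray(x, dtype=float), width_mm)


def parabolic_gap(g_min: float, curvature: float, x_min: float) -> Callable:
    """Gap profile g(x) = g_min + curvature * (x - x_min)**2, in mm."""
    return lambda x: g_min + curvature * (np.asarray(x, dtype=float) - x_min) ** 2


@dataclass
class PhantomSpec:
    """Geometry and rendering parameters for one synthetic knee.

    ``tibia_curve_params`` are polynomial coefficients (numpy order, highest
    degree first) of the superior tibial margin row as a function of
    normalized x.  The inferior femoral margin is either derived from
    ``gap_profile`` (guaranteeing the gap by construction) or given directly
    via ``femur_curve_params``; exactly one of the two must be supplied.
    """

    image_height: int = 256
    image_width: int = 256
    tibia_curve_params: Sequence[float] = (10.0, -10.0, 150.0)  # shallow dish
    gap_profile: Callable[[np.ndarray], np.ndarray] | None = field(
        default_factory=lambda: parabolic_gap(3.0, 4.0, 0.8))
    femur_curve_params: Sequence[float] | None = None
    mm_per_pixel: float = 0.2
    plateau_span: tuple[int, int] = (32, 224)
    noise_sd: float = 0.02
    laterality: str = "right"
    bone_fraction: float = 0.3   # bone band thickness as a fraction of height
    with_fibula: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mm_per_pixel <= 0:
            raise InvalidSpecError("mm_per_pixel must be positive")
        c_min, c_max = self.plateau_span
        if not (0 <= c_min < c_max < self.image_width):
            raise InvalidSpecError(
                f"plateau_span {self.plateau_span} invalid for width {self.image_width}")
        if self.laterality not in ("left", "right"):
            raise InvalidSpecError(f"laterality must be left/right, got {self.laterality!r}")
        if (self.gap_profile is None) == (self.femur_curve_params is None):
            raise InvalidSpecError(
                "supply exactly one of gap_profile or femur_curve_params")


@dataclass
class PhantomTruth:
    """Exact geometry recorded at construction time.

    ``gap_mm`` is the per-column gap actually encoded in the rendered mask
    (the requested profile after one-pixel-row quantization); the margin rows
    follow the pixel-edge convention (femur bottom edge at row + 0.5, tibia
    top edge at row - 0.5).
    """

    columns: np.ndarray          # image columns within the plateau span
    x: np.ndarray                # normalized plateau coordinate per column
    gap_mm: np.ndarray           # rendered gap per column, mm
    min_gap_medial: float        # min of gap_mm over the medial window
    argmin_x_medial: float       # x attaining that minimum
    femur_margin: np.ndarray     # sub-pixel femoral margin row per column
    tibia_margin: np.ndarray     # sub-pixel tibial margin row per column
    mask: "LabelMask"
    medial_window: tuple[float, float] = (0.7, 0.9)


def _margins_from_spec(spec: PhantomSpec):
    """Integer margin rows per plateau column, plus the rendered gap."""
    c = np.arange(spec.plateau_span[0], spec.plateau_span[1] + 1)
    x = (c - spec.plateau_span[0]) / (spec.plateau_span[1] - spec.plateau_span[0])
    y_t_cont = np.polyval(np.asarray(spec.tibia_curve_params, dtype=float), x)
    if spec.gap_profile is not None:
        gap_mm_cont = np.asarray(spec.gap_profile(x), dtype=float)
    else:
        y_f_cont = np.polyval(np.asarray(spec.femur_curve_params, dtype=float), x)
        gap_mm_cont = (y_t_cont - y_f_cont) * spec.mm_per_pixel
    if np.any(gap_mm_cont < 0):
        raise InvalidSpecError("femoral and tibial margins intersect within the plateau span")
    r_t = np.rint(y_t_cont).astype(int)            # first tibia row
    gap_px = np.rint(gap_mm_cont / spec.mm_per_pixel).astype(int)
    r_f = r_t - gap_px - 1                          # last femur row
    if np.any(r_f < 1) or np.any(r_t >= spec.image_height - 1):
        raise InvalidSpecError("margins leave the image; enlarge the image or flatten curves")
    return c, x, r_f, r_t, gap_px, gap_mm_cont


def make_phantom(spec: PhantomSpec) -> tuple[Radiograph, LabelMask, PhantomTruth]:
    """Render a phantom radiograph, its label mask, and the exact truth.

    The mask is noise-free; only the radiograph intensity carries additive
    Gaussian noise (seeded).  For ``laterality='left'`` the rendered rasters
    are the mirror image of the right-knee construction, while the truth
    stays in the medial-at-high-x frame.
    """
    c, x, r_f, r_t, gap_px, gap_mm_cont = _margins_from_spec(spec)
    H, W = spec.image_height, spec.image_width
    rows = np.arange(H)[:, None]

    labels = np.zeros((H, W), dtype=np.uint8)
    thick = max(4, int(spec.bone_fraction * H))
    femur_top = np.maximum(r_f - thick, 0)
    tibia_bot = np.minimum(r_t + thick, H - 1)
    col_f = np.full(W, -1, dtype=int)
    col_t = np.full(W, H + 1, dtype=int)
    col_ftop = np.zeros(W, dtype=int)
    col_tbot = np.zeros(W, dtype=int)
    col_f[c] = r_f
    col_t[c] = r_t
    col_ftop[c] = femur_top
    col_tbot[c] = tibia_bot
    femur_region = (rows >= col_ftop[None, :]) & (rows <= col_f[None, :])
    tibia_region = (rows >= col_t[None, :]) & (rows <= col_tbot[None, :])
    labels[femur_region] = 1
    labels[tibia_region] = 2
    if spec.with_fibula:
        # small disjoint head lateral of the tibia, below the joint line
        fib_r = int(np.median(r_t)) + thick // 2
        fib_c = max(spec.plateau_span[0] - 16, 8)
        rr, cc = np.ogrid[:H, :W]
        fib = ((rr - fib_r) ** 2 + (cc - fib_c) ** 2) <= 8 ** 2
        labels[fib & (labels == 0)] = 3

    rng = np.random.default_rng(spec.seed)
    pixels = np.where(labels > 0, 0.75, 0.12).astype(np.float64)
    pixels += rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    np.clip(pixels, 0.0, 1.0, out=pixels)

    if spec.laterality == "left":
        pixels = pixels[:, ::-1].copy()
        labels = labels[:, ::-1].copy()

    mask = LabelMask(labels=labels)
    radiograph = Radiograph(pixels=pixels, original_bit_depth=16,
                            mm_per_pixel=(spec.mm_per_pixel, spec.mm_per_pixel),
                            laterality=spec.laterality, source_id="phantom")

    gap_mm = gap_px * spec.mm_per_pixel
    medial = (x >= 0.7) & (x <= 0.9)
    i_min = int(np.argmin(np.where(medial, gap_mm, np.inf)))
    # location from the continuous profile: quantization ties are broken at
    # the analytic minimum, not at the first tied column
    i_loc = int(np.argmin(np.where(medial, gap_mm_cont, np.inf)))
    truth = PhantomTruth(
        columns=c, x=x, gap_mm=gap_mm,
        min_gap_medial=float(gap_mm[i_min]),
        argmin_x_medial=float(x[i_loc]),
        femur_margin=r_f + 0.5, tibia_margin=r_t - 0.5,
        mask=mask,
    )
    return radiograph, mask, truth


def make_observer_pairs(n: int, bias: float, sd: float, seed: int) -> pd.DataFrame:
    """Paired joint-space measurements from two synthetic observers.

    Observer A values are drawn from a clipped normal centred at 3.5 mm with
    SD 1.35 mm (typical of medial minimum-JSW in an OA screening population);
    observer B reads the same joints with a systematic ``bias`` and random
    error SD ``sd``, both in mm.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs; agreement statistics are undefined below that")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    a = np.clip(rng.normal(3.5, 1.35, size=n), 0.2, None)
    b = a + bias + (rng.normal(0.0, sd, size=n) if sd > 0 else 0.0)
    return pd.DataFrame({"a": a, "b": b})


# -- cohort construction ----------------------------------------------------

# narrowing per KL grade, mm: a medial bump plus (optionally) a lateral bump
def _narrowing_shape(x: np.ndarray, lateral_fraction: float) -> np.ndarray:
    medial = np.exp(-((x - 0.80) / 0.10) ** 2)
    lateral = np.exp(-((x - 0.20) / 0.10) ** 2)
    return (1.0 - lateral_fraction) * medial + lateral_fraction * lateral


def _healthy_profile(x: np.ndarray) -> np.ndarray:
    """Baseline joint-space profile of a KL-0 knee, mm."""
    return 4.6 + 0.5 * np.sin(np.pi * x)


def make_cohort(n_knees: int, signal_strength: float, seed: int, *,
                lateral_fraction: float = 0.5,
                step_mm: float = 0.65,
                site_noise_mm: float = 0.08,
                knee_noise_mm: float = 0.10,
                dropout_rate: float = 0.10,
                n_points: int = 64) -> pd.DataFrame:
    """Per-knee 64-point JSW features with baseline and 48-month KL grades.

    Each knee's width profile is the healthy profile minus a severity-scaled
    narrowing shape: ``w(x) = healthy(x) - v * step_mm * shape(x)`` plus
    per-knee and per-site noise.  With ``signal_strength=1`` the severity
    driver ``v`` equals the KL grade, so grouping knees by grade gives
    strictly decreasing mean medial JSW; with ``signal_strength=0`` the
    driver is independent noise and the features carry no grade information.
    ``lateral_fraction`` sets how much of the narrowing occurs in the lateral
    compartment, which the medial minimum-JSW cannot see.

    Knees come in subject pairs (bilateral) with correlated severity;
    progression (for baseline grades 0–1) follows the same latent narrowing,
    attenuated by ``signal_strength``.  Dropout knees have a missing 48-month
    grade.  Columns: knee_id, subject_id, w_1..w_{n_points}, kl_baseline,
    kl_48mo (nullable), dropout, source.
    """
    if n_knees < 50:
        raise ValueError("need n_knees >= 50 for a usable cohort")
    if not 0.0 <= signal_strength <= 1.0:
        raise ValueError("signal_strength must lie in [0, 1]")
    from .jsw import SamplingGrid, sample_sites  # local import: avoid cycle at import time

    rng = np.random.default_rng(seed)
    s = float(signal_strength)
    x = sample_sites(SamplingGrid(n_points=n_points))

    n_subjects = (n_knees + 1) // 2
    # Gaussian copula: bilateral knees share a subject factor (rho ~ 0.7)
    # while each knee's percentile stays exactly uniform, preserving the
    # marginal KL prevalence.
    z_subj = rng.standard_normal(n_subjects)
    subj_idx = np.arange(n_knees) // 2
    z = 0.7 * z_subj[subj_idx] + np.sqrt(1 - 0.7 ** 2) * rng.standard_normal(n_knees)
    u = _stats.norm.cdf(z)
    cum = np.cumsum(KL_PREVALENCE)
    kl = np.searchsorted(cum, np.clip(u, 0, 1 - 1e-12)).astype(int)
    subject_id = np.array([f"S{s:05d}" for s in subj_idx], dtype=object)

    v_random = rng.uniform(0, 4, size=n_knees)
    v = s * kl + (1.0 - s) * v_random

    shape = _narrowing_shape(x, lateral_fraction)
    base = _healthy_profile(x)
    widths = (base[None, :]
              - v[:, None] * step_mm * shape[None, :]
              + rng.normal(0, knee_noise_mm, size=(n_knees, 1))
              + rng.normal(0, site_noise_mm, size=(n_knees, n_points)))
    widths = np.clip(widths, 0.0, None)

    # progression: latent narrowing plus noise crosses a threshold
    z = v + rng.normal(0, 0.5, size=n_knees)
    prog_prob = s * (z > 0.9).astype(float) + (1 - s) * 0.3
    progress = rng.uniform(0, 1, size=n_knees) < prog_prob
    kl48 = kl.copy()
    early = kl <= 1
    kl48[early & progress] = np.maximum(kl[early & progress] + 1, 2)
    late = kl >= 2
    kl48[late] = np.minimum(kl[late] + (rng.uniform(size=late.sum()) < 0.2), 4)

    dropout = rng.uniform(size=n_knees) < dropout_rate
    kl48_out = pd.array(kl48, dtype="Int64")
    kl48_out[dropout] = pd.NA

    table = pd.DataFrame({
        "knee_id": [f"K{i:05d}" for i in range(n_knees)],
        "subject_id": subject_id,
    })
    for j in range(n_points):
        table[f"w_{j + 1}"] = widths[:, j]
    table["kl_baseline"] = kl
    table["kl_48mo"] = kl48_out
    table["dropout"] = dropout
    table["source"] = "estimated"
    return table
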