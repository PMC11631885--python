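"""Synthetic lateral-spine phantoms with known gap widths and labels.

Phantoms stand in for clinical radiograph segmentation masks: a chain of
quadrilateral vertebral bodies is laid out along a gently curved
centerline in a 1024 x 512 grid, separated by inter-body gaps of known
width, a controllable fraction of which are narrowed by a multiplicative
factor.  Boundary jitter and small foreground specks exercise the
downstream noise filters.  Every phantom comes with full ground truth:
the gap table, the true centerline coefficients, and the per-row 3-class
label vector (0 = no disc space, 1 = normal, 2 = narrowed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quantify import (
    CURVE_DEGREE,
    LABEL_BODY,
    LABEL_NARROWED_GAP,
    LABEL_NORMAL_GAP,
    TARGET_SHAPE,
    VECTOR_LEN,
)

CLASS_NO_IVDS = 0
CLASS_NORMAL = 1
CLASS_NARROWED = 2

_EDGE_MARGIN = 24  # rows kept clear above the first and below the last body
_SIDE_MARGIN = 12  # min distance of body edges from the left/right border


class InfeasibleGeometryError(ValueError):
    """Raised when the drawn bodies and gaps cannot fit in 1024 rows."""


def _as_range(value, name: str) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    lo, hi = value
    if not (lo <= hi):
        raise ValueError(f"{name}: range must satisfy lo <= hi, got {value}")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class PhantomParams:
    """Sampling parameters for one phantom image.

    Range-valued fields accept either a scalar or a ``(lo, hi)`` pair;
    per-image values are drawn uniformly from the range.
    """

    n_vertebrae: int | tuple[int, int] = (6, 9)
    body_length_px: float | tuple[float, float] = (55.0, 85.0)
    body_height_px: float | tuple[float, float] = (90.0, 150.0)
    gap_width_px: float | tuple[float, float] = (8.0, 16.0)
    narrowed_fraction: float = 0.25
    narrowing_factor: float | tuple[float, float] = (0.3, 0.7)
    curve_coeffs: tuple[float, ...] | None = None
    max_curve_dev_px: float = 70.0  # amplitude of random gentle curvature
    jitter_px: float = 0.0
    speck_rate: int = 0
    annotate_gaps: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n_lo, n_hi = self.n_vertebrae_range
        if n_lo < 2:
            raise ValueError("need at least 2 vertebrae to have a gap")
        for name in ("body_length_px", "body_height_px", "gap_width_px"):
            lo, hi = _as_range(getattr(self, name), name)
            if lo <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.narrowed_fraction <= 1.0:
            raise ValueError("narrowed_fraction must be in [0, 1]")
        f_lo, f_hi = _as_range(self.narrowing_factor, "narrowing_factor")
        if not (0.0 < f_lo and f_hi < 1.0):
            raise ValueError("narrowing_factor must lie in the open interval (0, 1)")
        if self.curve_coeffs is not None and len(self.curve_coeffs) != CURVE_DEGREE + 1:
            raise ValueError("curve_coeffs must have exactly 5 entries")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if self.speck_rate < 0:
            raise ValueError("speck_rate must be >= 0")

    @property
    def n_vertebrae_range(self) -> tuple[int, int]:
        if np.isscalar(self.n_vertebrae):
            return (int(self.n_vertebrae), int(self.n_vertebrae))
        lo, hi = self.n_vertebrae
        return (int(lo), int(hi))


@dataclass(frozen=True)
class GapTruth:
    gap_index: int
    start_row: int
    end_row: int  # half-open
    width_px: int
    label: str  # "normal" | "narrowed"


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one phantom."""

    gaps: tuple[GapTruth, ...]
    curve_coeffs: tuple[float, float, float, float, float]
    position_labels: np.ndarray  # (1024,) values in {0, 1, 2}
    body_rows: tuple[tuple[int, int], ...]  # half-open row spans of bodies


@dataclass(frozen=True)
class _Geometry:
    body_rows: tuple[tuple[int, int], ...]
    gap_rows: tuple[tuple[int, int], ...]
    narrowed: tuple[bool, ...]
    body_half_heights: tuple[float, ...]
    curve_coeffs: tuple[float, float, float, float, float]


def _sample_curve(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Coefficients c0..c4 of x(y), gentle and centered in the image."""
    if params.curve_coeffs is not None:
        return np.asarray(params.curve_coeffs, dtype=float)
    width = TARGET_SHAPE[1]
    hh_hi = _as_range(params.body_height_px, "body_height_px")[1] / 2.0
    max_dev = min(params.max_curve_dev_px, width / 2.0 - hh_hi - _SIDE_MARGIN)
    max_dev = max(max_dev, 0.0)
    # shape in t = (y - 511.5)/511.5, normalized to unit max deviation
    b = rng.uniform(-1.0, 1.0, size=CURVE_DEGREE)
    t = np.linspace(-1.0, 1.0, 257)
    shape = sum(bk * t ** (k + 1) for k, bk in enumerate(b))
    peak = np.max(np.abs(shape))
    amp = rng.uniform(0.0, max_dev)
    coeffs_t = np.zeros(CURVE_DEGREE + 1)
    coeffs_t[0] = width / 2.0
    if peak > 0:
        coeffs_t[1:] = amp * b / peak
    # substitute t = 2y/(L-1) - 1 to express the curve in raw row coordinates
    poly_y = np.polynomial.Polynomial(coeffs_t)(
        np.polynomial.Polynomial([-1.0, 2.0 / (VECTOR_LEN - 1)])
    )
    out = np.zeros(CURVE_DEGREE + 1)
    out[: len(poly_y.coef)] = poly_y.coef
    return out


def _sample_geometry(params: PhantomParams, rng: np.random.Generator) -> _Geometry:
    n_lo, n_hi = params.n_vertebrae_range
    n = int(rng.integers(n_lo, n_hi + 1))
    len_lo, len_hi = _as_range(params.body_length_px, "body_length_px")
    hh_lo, hh_hi = _as_range(params.body_height_px, "body_height_px")
    gap_lo, gap_hi = _as_range(params.gap_width_px, "gap_width_px")
    f_lo, f_hi = _as_range(params.narrowing_factor, "narrowing_factor")

    lengths = np.maximum(
        np.round(rng.uniform(len_lo, len_hi, size=n)).astype(int), 3
    )
    heights = rng.uniform(hh_lo, hh_hi, size=n) / 2.0
    widths = rng.uniform(gap_lo, gap_hi, size=n - 1)
    narrowed = rng.random(n - 1) < params.narrowed_fraction
    factors = rng.uniform(f_lo, f_hi, size=n - 1)
    widths = np.where(narrowed, widths * factors, widths)
    widths = np.maximum(np.round(widths).astype(int), 1)

    total = int(lengths.sum() + widths.sum())
    budget = VECTOR_LEN - 2 * _EDGE_MARGIN
    if total > budget:
        raise InfeasibleGeometryError(
            f"bodies + gaps need {total} rows but only {budget} are available"
        )
    start = _EDGE_MARGIN + int(rng.integers(0, budget - total + 1))

    body_rows: list[tuple[int, int]] = []
    gap_rows: list[tuple[int, int]] = []
    row = start
    for i in range(n):
        body_rows.append((row, row + int(lengths[i])))
        row += int(lengths[i])
        if i < n - 1:
            gap_rows.append((row, row + int(widths[i])))
            row += int(widths[i])

    coeffs = _sample_curve(params, rng)
    return _Geometry(
        body_rows=tuple(body_rows),
        gap_rows=tuple(gap_rows),
        narrowed=tuple(bool(b) for b in narrowed),
        body_half_heights=tuple(heights),
        curve_coeffs=tuple(coeffs),
    )


def _ground_truth(geom: _Geometry) -> GroundTruth:
    labels = np.zeros(VECTOR_LEN, dtype=np.int64)
    gaps = []
    for i, ((s, e), narrow) in enumerate(zip(geom.gap_rows, geom.narrowed)):
        labels[s:e] = CLASS_NARROWED if narrow else CLASS_NORMAL
        gaps.append(
            GapTruth(
                gap_index=i,
                start_row=s,
                end_row=e,
                width_px=e - s,
                label="narrowed" if narrow else "normal",
            )
        )
    return GroundTruth(
        gaps=tuple(gaps),
        curve_coeffs=geom.curve_coeffs,
        position_labels=labels,
        body_rows=geom.body_rows,
    )


def _render(geom: _Geometry, params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    h, w = TARGET_SHAPE
    mask = np.zeros((h, w), dtype=np.uint8)
    ys = np.arange(h, dtype=float)
    xc = np.polynomial.polynomial.polyval(ys, np.asarray(geom.curve_coeffs))

    def paint(rows: tuple[int, int], half: float, label: int, jitter: float) -> None:
        s, e = rows
        for y in range(s, e):
            jl = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
            jr = rng.uniform(-jitter, jitter) if jitter > 0 else 0.0
            left = int(np.floor(xc[y] - half + jl + 0.5))
            right = int(np.floor(xc[y] + half + jr + 0.5))
            left = max(left, 0)
            right = min(right, w - 1)
            if right >= left:
                mask[y, left : right + 1] = label

    for (rows, half) in zip(geom.body_rows, geom.body_half_heights):
        paint(rows, half, LABEL_BODY, params.jitter_px)

    if params.annotate_gaps:
        for i, (rows, narrow) in enumerate(zip(geom.gap_rows, geom.narrowed)):
            half = min(
                geom.body_half_heights[i], geom.body_half_heights[i + 1]
            ) * 0.9
            label = LABEL_NARROWED_GAP if narrow else LABEL_NORMAL_GAP
            paint(rows, half, label, 0.0)

    for _ in range(int(params.speck_rate)):
        for _attempt in range(50):
            r = int(rng.integers(0, h))
            c = int(rng.integers(0, w))
            size = int(rng.integers(1, 4))  # side 1-3 -> 1..9 px
            r2, c2 = min(r + size, h), min(c + size, w)
            # keep specks off existing foreground so components stay separate
            rlo, rhi = max(r - 3, 0), min(r2 + 3, h)
            clo, chi = max(c - 3, 0), min(c2 + 3, w)
            if not mask[rlo:rhi, clo:chi].any():
                mask[r:r2, c:c2] = LABEL_BODY
                break
    return mask


def generate_spine_mask(
    params: PhantomParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom label mask together with its ground truth.

    Identical ``params`` (including seed) produce bit-identical output.

    Raises
    ------
    InfeasibleGeometryError
        If the drawn bodies and gaps exceed the 1024-row budget.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    geom = _sample_geometry(params, rng)
    truth = _ground_truth(geom)
    mask = _render(geom, params, rng)
    return mask, truth


def truth_vector(truth: GroundTruth) -> np.ndarray:
    """Ideal binary profile implied by a ground truth (1 on body rows)."""
    vec = np.zeros(VECTOR_LEN, dtype=np.int64)
    for s, e in truth.body_rows:
        vec[s:e] = 1
    return vec


def generate_vector_dataset(
    params: PhantomParams, n_images: int
) -> tuple[list[np.ndarray], list[np.ndarray], list[GroundTruth]]:
    """Pre-quantified (vector, label) pairs, bypassing mask rendering.

    Returns ``(vectors, labels, truths)`` with one entry per image; each
    vector is the binary body/background profile implied by the image's
    ground truth and each label vector the per-row 3-class truth.
    Geometry is drawn from independent per-image substreams of
    ``params.seed`` so the dataset is deterministic.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    seeds = np.random.SeedSequence(params.seed).spawn(n_images)
    vectors: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    for ss in seeds:
        geom = _sample_geometry(params, np.random.default_rng(ss))
        truth = _ground_truth(geom)
        vectors.append(truth_vector(truth))
        labels.append(truth.position_labels.copy())
        truths.append(truth)
    return vectors, labels, truths
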