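"""Geometric quantification of inter-vertebral gaps from segmentation masks.

The pipeline turns a 2D integer label mask (0 = background, 1 = vertebral
body, optional 2/3 = annotated normal/narrowed disc space) into a
length-1024 binary profile sampled along a fitted spine centerline, and
measures every inter-body gap by counting pixels along that profile.

Stages (see :func:`quantify_mask` for the one-call pipeline):

1. :func:`resize_mask` — nearest-neighbour resize to 1024 x 512.
2. :func:`skeletonize_components` — per-component morphological skeletons
   of the vertebral bodies, pooled into one point cloud.
3. :func:`fit_spine_curve` — 4th-order polynomial x(y) least-squares fit.
4. :func:`quantify_vector` — row-by-row centerline sampling into a 0/1
   vector of length 1024.
5. :func:`measure_gaps` — run-length gap extraction with width-to-mean
   ratios.
6. :func:`classify_by_ratio` — threshold the ratio into normal/narrowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize
from skimage.transform import resize

#: Canonical working shape (rows, cols) every mask is resized to.
TARGET_SHAPE = (1024, 512)

#: Length of the quantified profile: one element per resized-image row.
VECTOR_LEN = TARGET_SHAPE[0]

#: Allowed label alphabet of input masks.
VALID_LABELS = frozenset({0, 1, 2, 3})

LABEL_BACKGROUND = 0
LABEL_BODY = 1
LABEL_NORMAL_GAP = 2
LABEL_NARROWED_GAP = 3

#: Degree of the centerline polynomial.
CURVE_DEGREE = 4

DEFAULT_MIN_AREA_PX = 50
DEFAULT_MIN_RUN_PX = 5


class MaskValidationError(ValueError):
    """Raised when an input mask violates the label-mask contract."""


class NoVertebraeError(ValueError):
    """Raised when no vertebral-body component survives filtering."""


class DegenerateFitError(ValueError):
    """Raised when the skeleton point cloud cannot support a 4th-order fit."""


@dataclass(frozen=True)
class SpineCurve:
    """4th-order polynomial centerline x(y) = sum_k coeffs[k] * y**k.

    Coordinates are resized-image coordinates: ``y`` is the row index,
    ``x`` the column index.
    """

    coeffs: tuple[float, float, float, float, float]
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if len(self.coeffs) != CURVE_DEGREE + 1:
            raise ValueError("SpineCurve requires exactly 5 coefficients")
        if self.rss < 0:
            raise ValueError("rss must be non-negative")

    def __call__(self, y: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(y, np.asarray(self.coeffs))


@dataclass(frozen=True)
class GapRecord:
    """One measured inter-vertebral gap along the quantified profile."""

    gap_index: int
    start_row: int
    end_row: int  # half-open
    width_px: int
    ratio_to_mean: float
    label: str = "unassigned"  # "normal" | "narrowed" | "unassigned"

    def __post_init__(self) -> None:
        if self.width_px != self.end_row - self.start_row:
            raise ValueError("width_px must equal end_row - start_row")
        if self.width_px < 1:
            raise ValueError("gap width must be >= 1 px")
        if self.label not in ("normal", "narrowed", "unassigned"):
            raise ValueError(f"invalid gap label: {self.label!r}")


@dataclass(frozen=True)
class QuantifyResult:
    """Bundle returned by the full :func:`quantify_mask` pipeline."""

    curve: SpineCurve
    vector: np.ndarray
    gaps: tuple[GapRecord, ...] = field(default_factory=tuple)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check the label-mask contract; return the mask as an int array."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise MaskValidationError("mask must be a non-empty 2D array")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.round(arr)):
            raise MaskValidationError("mask values must be integers")
    arr = arr.astype(np.int64, copy=False)
    bad = np.setdiff1d(np.unique(arr), sorted(VALID_LABELS))
    if bad.size:
        raise MaskValidationError(
            f"mask contains labels outside {{0,1,2,3}}: {bad.tolist()}"
        )
    return arr


def resize_mask(mask: np.ndarray) -> np.ndarray:
    """Nearest-neighbour resize to the canonical 1024 x 512 shape.

    Nearest-neighbour interpolation preserves the integer label alphabet;
    an input already at the target shape is returned unchanged (copy).
    """
    arr = validate_mask(mask)
    if arr.shape == TARGET_SHAPE:
        return arr.copy()
    out = resize(
        arr,
        TARGET_SHAPE,
        order=0,
        preserve_range=True,
        anti_aliasing=False,
    )
    return out.astype(np.int64)


def filter_components(
    mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX
) -> np.ndarray:
    """Binary vertebral-body foreground with small components removed.

    Only label 1 counts as foreground; 8-connected components with area
    below ``min_area_px`` (segmentation specks) are discarded.
    """
    fg = np.asarray(mask) == LABEL_BODY
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(fg)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = areas >= min_area_px
    return keep[labels]


def skeletonize_components(
    mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX
) -> np.ndarray:
    """Pooled skeleton points of all surviving vertebral-body components.

    Each connected component of label 1 with area >= ``min_area_px`` is
    thinned to its morphological skeleton; the (row, col) coordinates of
    all skeleton pixels are pooled into one ``(N, 2)`` array, sorted by
    row then column.

    Raises
    ------
    NoVertebraeError
        If no component survives the area filter.
    """
    fg = filter_components(mask, min_area_px)
    if not fg.any():
        raise NoVertebraeError(
            f"no vertebrae detected (no label-1 component with area >= {min_area_px})"
        )
    skel = skeletonize(fg)
    rows, cols = np.nonzero(skel)
    order = np.lexsort((cols, rows))
    return np.stack([rows[order], cols[order]], axis=1)


# Fitting is done in the scaled domain t = (y - _T_SHIFT) / _T_SCALE to keep
# the Vandermonde matrix well conditioned, then converted back to raw row
# coordinates.  With y up to 1023, y**4 spans ~12 orders of magnitude and a
# raw-coordinate solve loses most of its significant digits.
_T_SHIFT = (VECTOR_LEN - 1) / 2.0
_T_SCALE = (VECTOR_LEN - 1) / 2.0


def fit_spine_curve(points: np.ndarray) -> SpineCurve:
    """Least-squares 4th-order polynomial x(y) through skeleton points.

    Parameters
    ----------
    points
        ``(N, 2)`` array of (row, col) skeleton coordinates.

    Raises
    ------
    DegenerateFitError
        If the points span fewer than 5 distinct rows.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (row, col)")
    y = pts[:, 0]
    x = pts[:, 1]
    if np.unique(y).size < CURVE_DEGREE + 1:
        raise DegenerateFitError(
            "degenerate fit: need points on >= 5 distinct rows for a 4th-order curve"
        )
    t = (y - _T_SHIFT) / _T_SCALE
    design = np.vander(t, CURVE_DEGREE + 1, increasing=True)
    coeffs_t, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ coeffs_t
    rss = float(resid @ resid)
    poly_t = np.polynomial.Polynomial(
        coeffs_t, domain=[-1.0, 1.0], window=[-1.0, 1.0]
    )
    # substitute t = (y - shift)/scale to get raw-row coefficients
    shift = np.polynomial.Polynomial([-_T_SHIFT / _T_SCALE, 1.0 / _T_SCALE])
    poly_y = poly_t(shift)
    coeffs = np.zeros(CURVE_DEGREE + 1)
    coeffs[: len(poly_y.coef)] = poly_y.coef
    return SpineCurve(coeffs=tuple(coeffs), rss=rss, n_points=len(pts))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantify_vector(
    mask: np.ndarray,
    curve: SpineCurve,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> np.ndarray:
    """Sample the vertebral-body foreground along the centerline.

    For each row ``y`` in 0..1023 the mask is sampled at
    ``(y, round(x(y)))``; the result is 1 iff the sample falls on a
    surviving label-1 component, 0 otherwise (including out-of-bounds
    samples).  Components below ``min_area_px`` are ignored so that
    segmentation specks cannot flip profile values.
    """
    arr = np.asarray(mask)
    if arr.shape != TARGET_SHAPE:
        raise ValueError(f"mask must be resized to {TARGET_SHAPE} first")
    fg = filter_components(arr, min_area_px)
    ys = np.arange(VECTOR_LEN)
    xs = _round_half_away(np.asarray(curve(ys.astype(float)), dtype=float))
    if not np.all(np.isfinite(xs)):
        raise ValueError("curve is not finite on [0, 1023]")
    xs = xs.astype(np.int64)
    inside = (xs >= 0) & (xs < TARGET_SHAPE[1])
    vec = np.zeros(VECTOR_LEN, dtype=np.int64)
    vec[inside] = fg[ys[inside], xs[inside]].astype(np.int64)
    return vec


def _run_lengths(vector: np.ndarray) -> list[tuple[int, int, int]]:
    """RLE of a binary vector as (value, start, end) half-open runs."""
    v = np.asarray(vector)
    boundaries = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(v)]])
    return [(int(v[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def measure_gaps(
    vector: np.ndarray, min_run_px: int = DEFAULT_MIN_RUN_PX
) -> list[GapRecord]:
    """Extract inter-vertebral gaps from a binary profile.

    A gap is a maximal zero-run flanked on both sides by one-runs of
    length >= ``min_run_px`` (short one-runs are label noise, not
    vertebrae).  Leading and trailing zero-runs are background, never
    gaps.  ``ratio_to_mean`` is each width divided by the mean gap width
    of this profile.  Fewer than two qualifying one-runs yield an empty
    list.
    """
    v = np.asarray(vector)
    if v.ndim != 1:
        raise ValueError("vector must be 1D")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("vector must be binary")
    runs = _run_lengths(v)
    gaps: list[tuple[int, int]] = []
    for i, (val, start, end) in enumerate(runs):
        if val != 0 or i == 0 or i == len(runs) - 1:
            continue
        lval, lstart, lend = runs[i - 1]
        rval, rstart, rend = runs[i + 1]
        if lend - lstart >= min_run_px and rend - rstart >= min_run_px:
            gaps.append((start, end))
    if not gaps:
        return []
    widths = np.array([e - s for s, e in gaps], dtype=float)
    mean_width = widths.mean()
    return [
        GapRecord(
            gap_index=i,
            start_row=s,
            end_row=e,
            width_px=e - s,
            ratio_to_mean=(e - s) / mean_width,
        )
        for i, (s, e) in enumerate(gaps)
    ]


def classify_by_ratio(
    gaps: Iterable[GapRecord], threshold: float
) -> list[GapRecord]:
    """Label each gap narrowed iff its ratio-to-mean is <= ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [
        replace(g, label="narrowed" if g.ratio_to_mean <= threshold else "normal")
        for g in gaps
    ]


def annotation_labels(
    mask: np.ndarray, curve: SpineCurve
) -> np.ndarray:
    """Per-row 3-class training targets from an annotated mask.

    Samples the resized mask along the centerline; rows whose sample is
    label 2 become class 1 (normal disc space), label 3 becomes class 2
    (narrowed), everything else (body, background) class 0.
    """
    arr = np.asarray(mask)
    if arr.shape != TARGET_SHAPE:
        raise ValueError(f"mask must be resized to {TARGET_SHAPE} first")
    ys = np.arange(VECTOR_LEN)
    xs = _round_half_away(np.asarray(curve(ys.astype(float)), dtype=float)).astype(np.int64)
    labels = np.zeros(VECTOR_LEN, dtype=np.int64)
    inside = (xs >= 0) & (xs < TARGET_SHAPE[1])
    sampled = arr[ys[inside], xs[inside]]
    out = np.zeros_like(sampled)
    out[sampled == LABEL_NORMAL_GAP] = 1
    out[sampled == LABEL_NARROWED_GAP] = 2
    labels[inside] = out
    return labels


def quantify_mask(
    mask: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    min_run_px: int = DEFAULT_MIN_RUN_PX,
) -> QuantifyResult:
    """Full pipeline: raw label mask -> curve, profile vector, gap table."""
    resized = resize_mask(mask)
    points = skeletonize_components(resized, min_area_px)
    curve = fit_spine_curve(points)
    vector = quantify_vector(resized, curve, min_area_px)
    gaps = tuple(measure_gaps(vector, min_run_px))
    return QuantifyResult(curve=curve, vector=vector, gaps=gaps)
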