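"""Agreement and diagnostic statistics for narrowed-gap decisions.

Cohen's kappa on a pooled 2x2 table, Fleiss' kappa for >= 2 raters,
sensitivity/specificity/PPV/NPV/accuracy, and ROC analysis with
Youden-index threshold selection on the width-to-mean ratio.  All
formulas are implemented directly; the test suite checks them against
brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 narrowed-vs-not counts; reference on rows, test on columns."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one decision")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    auc_ci: tuple[float, float] | None = None


def cohen_kappa(table: ConfusionTable) -> float:
    """Chance-corrected two-rater agreement on the 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed accuracy and
    p_e the chance agreement implied by the two margins; returns 1.0 in
    the degenerate p_e = p_o = 1 case.
    """
    n = table.total
    p_o = (table.tp + table.tn) / n
    ref_pos = table.tp + table.fn
    ref_neg = table.fp + table.tn
    test_pos = table.tp + table.fp
    test_neg = table.fn + table.tn
    p_e = (ref_pos * test_pos + ref_neg * test_neg) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def confusion_metrics(table: ConfusionTable) -> dict[str, float | None]:
    """Diagnostic metrics in percent; undefined metrics come back None.

    Keys: ``sensitivity``, ``specificity``, ``ppv``, ``npv``,
    ``accuracy``.  A metric whose denominator is zero is flagged as None
    rather than raising.
    """

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return {
        "sensitivity": pct(table.tp, table.tp + table.fn),
        "specificity": pct(table.tn, table.tn + table.fp),
        "ppv": pct(table.tp, table.tp + table.fp),
        "npv": pct(table.tn, table.tn + table.fn),
        "accuracy": pct(table.tp + table.tn, table.total),
    }


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for an items x categories count matrix.

    Every row must sum to the same number of raters (>= 2); at least two
    items are required.
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("ratings must be an (n_items >= 2, n_categories >= 2) matrix")
    if (r < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = r.sum(axis=1)
    n_raters = row_sums[0]
    if n_raters < 2 or not np.all(row_sums == n_raters):
        raise ValueError("all items must be rated by the same >= 2 raters")
    n_items = r.shape[0]
    p_i = ((r * (r - 1)).sum(axis=1)) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_j = r.sum(axis=0) / (n_items * n_raters)
    p_e = float((p_j**2).sum())
    if p_e == 1.0:
        return 1.0 if p_bar == 1.0 else 0.0
    return float((p_bar - p_e) / (1.0 - p_e))


def _auc_rank(scores: np.ndarray, truth: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks; ties count one half."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    r_pos = ranks[truth.astype(bool)].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_youden(
    ratios: Sequence[float],
    reference: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
    ci: bool = True,
) -> RocResult:
    """ROC analysis of the width-to-mean ratio against narrowed truth.

    Smaller ratios indicate narrowing, so the ROC score is the negated
    ratio.  AUC uses the rank (Mann-Whitney) method with ties counted
    one half.  The operating threshold maximizes Youden's
    J = sensitivity + specificity - 1 over the observed ratio values,
    with gaps labeled narrowed iff ratio <= threshold; J-ties resolve
    toward the higher-specificity (smaller) threshold.  The optional
    95% CI for the AUC is a seeded stratified percentile bootstrap.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(reference, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ratios and reference must be matching 1D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference must contain both narrowed and normal gaps")

    auc = _auc_rank(-x, y)

    best = None  # (J, specificity, -threshold) maximized lexicographically
    best_stats = None
    for thr in np.unique(x):
        pred = x <= thr
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        j = sens + spec - 1.0
        key = (j, spec, -thr)
        if best is None or key > best:
            best = key
            best_stats = (float(thr), sens, spec)
    threshold, sensitivity, specificity = best_stats

    auc_ci = None
    if ci and n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = x[y]
        neg = x[~y]
        boot = np.empty(n_boot)
        for i in range(n_boot):
            bp = rng.choice(pos, size=n_pos, replace=True)
            bn = rng.choice(neg, size=n_neg, replace=True)
            boot[i] = _auc_rank(
                -np.concatenate([bp, bn]),
                np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
            )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        auc_ci = (float(lo), float(hi))

    return RocResult(
        auc=auc,
        threshold=threshold,
        sensitivity=sensitivity,
        specificity=specificity,
        auc_ci=auc_ci,
    )


def roc_curve_points(
    ratios: Sequence[float], reference: Sequence[bool]
) -> list[dict[str, float]]:
    """(fpr, tpr, cut) triples over all observed ratio cuts, for plotting."""
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(reference, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("reference must contain both narrowed and normal gaps")
    points = []
    for thr in np.unique(x):
        pred = x <= thr
        points.append(
            {
                "cut": float(thr),
                "tpr": float((pred & y).sum() / n_pos),
                "fpr": float((pred & ~y).sum() / n_neg),
            }
        )
    return points


def pool_confusion(
    model_labels: Sequence[Sequence[str]],
    reference_labels: Sequence[Sequence[str]],
) -> ConfusionTable:
    """Pool per-image gap labels into one narrowed-vs-not 2x2 table.

    ``model_labels[i]`` and ``reference_labels[i]`` are the per-gap label
    lists of image ``i``, aligned by ordinal gap index; a length mismatch
    in any image is an error.
    """
    if len(model_labels) != len(reference_labels):
        raise ValueError("model and reference must cover the same images")
    tp = fn = fp = tn = 0
    for i, (mod, ref) in enumerate(zip(model_labels, reference_labels)):
        if len(mod) != len(ref):
            raise ValueError(
                f"image {i}: model has {len(mod)} gaps but reference has {len(ref)}"
            )
        for m, r in zip(mod, ref):
            m_pos = m == "narrowed"
            r_pos = r == "narrowed"
            if r_pos and m_pos:
                tp += 1
            elif r_pos:
                fn += 1
            elif m_pos:
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def agreement_report(
    model_labels: Sequence[Sequence[str]],
    reference_labels: Sequence[Sequence[str]],
) -> dict:
    """Pooled 2x2 table, Cohen's kappa, and diagnostic metrics."""
    table = pool_confusion(model_labels, reference_labels)
    metrics = confusion_metrics(table)
    return {
        "table": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
        "kappa": cohen_kappa(table),
        "metrics": metrics,
    }
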