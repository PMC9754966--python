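"""Evaluation statistics: segmentation IoU, 2x2 diagnostic accuracy,
ROC/AUC with bootstrap confidence interval, Cohen's kappa with the
conventional interpretation bands, and a 2x2 association test.

Diagnostic rates are computed as exact rationals and rounded only for
display (half away from zero), so printed whole-percent values agree with
hand computation from the confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.stats import chi2_contingency, fisher_exact
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .preprocess import IGNORE_LABEL

__all__ = [
    "ConfusionTable2x2",
    "DiagnosticReport",
    "RocResult",
    "KappaResult",
    "mean_iou",
    "diagnostics",
    "roc_auc",
    "cohens_kappa",
    "association_test",
    "confusion_from_calls",
]


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Counts with "positive" = DLS/neMNV present: tp, fn, fp, tn."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def _round_half_away(x: Fraction, digits: int = 0) -> float:
    scale = 10**digits
    q = x * scale
    sign = 1 if q >= 0 else -1
    return sign * float(int(abs(q) + Fraction(1, 2))) / scale


@dataclass
class DiagnosticReport:
    table: ConfusionTable2x2
    sensitivity: Fraction | None
    specificity: Fraction | None
    ppv: Fraction | None
    npv: Fraction | None
    p_value: float | None = None
    rounding: int = 0

    def percent(self, name: str, digits: int = 0) -> float | None:
        """Rate as a percentage rounded half away from zero."""
        value = getattr(self, name)
        return None if value is None else _round_half_away(value * 100, digits)

    def as_dict(self, digits: int = 0) -> dict:
        out = {"tp": self.table.tp, "fn": self.table.fn, "fp": self.table.fp, "tn": self.table.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            out[name] = None if getattr(self, name) is None else float(getattr(self, name))
            out[f"{name}_pct"] = self.percent(name, digits)
        out["p_value"] = self.p_value
        return out


def diagnostics(table: ConfusionTable2x2, with_p_value: bool = True) -> DiagnosticReport:
    """Sensitivity/specificity/PPV/NPV from a 2x2 table, exactly.

    A rate whose denominator is zero is reported as None (undefined), never
    as 0.  The two-sided Fisher p-value for the DLS-MNV association is
    attached unless disabled.
    """
    if table.total == 0:
        raise ValueError("empty confusion table")

    def rate(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den > 0 else None

    report = DiagnosticReport(
        table=table,
        sensitivity=rate(table.tp, table.tp + table.fn),
        specificity=rate(table.tn, table.tn + table.fp),
        ppv=rate(table.tp, table.tp + table.fp),
        npv=rate(table.tn, table.tn + table.fn),
    )
    if with_p_value:
        report.p_value = association_test(table)
    return report


def confusion_from_calls(calls, truth) -> ConfusionTable2x2:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have the same length")
    return ConfusionTable2x2(
        tp=int((calls & truth).sum()),
        fn=int((~calls & truth).sum()),
        fp=int((calls & ~truth).sum()),
        tn=int((~calls & ~truth).sum()),
    )


@dataclass
class RocResult:
    points: np.ndarray  # (n, 2) of (false-positive rate, true-positive rate)
    auc: float
    ci95: tuple[float, float]
    ci_method: str
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))


def roc_auc(
    scores,
    truth,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC over all score thresholds with trapezoidal AUC.

    The AUC equals P(score_pos > score_neg) + 0.5 * P(equal).  The 95% CI is
    a stratified bootstrap (positives and negatives resampled separately),
    seeded for reproducibility.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = roc_curve(truth, scores, drop_intermediate=False)
    a = float(sk_auc(fpr, tpr))
    rng = np.random.default_rng(seed)
    pos, neg = scores[truth], scores[~truth]
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        # closed-form AUC of the resample via rank statistics
        boots[i] = _pairwise_auc(bp, bn)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        points=np.column_stack([fpr, tpr]),
        auc=a,
        ci95=(float(lo), float(hi)),
        ci_method=f"stratified bootstrap ({n_bootstrap} resamples)",
        thresholds=thr,
    )


def _pairwise_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney form of the AUC (wins + half-ties over all pairs)."""
    from scipy.stats import rankdata

    all_scores = np.concatenate([pos, neg])
    ranks = rankdata(all_scores)
    r_pos = ranks[: pos.size].sum()
    return (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


_KAPPA_BANDS = ((0.4, "poor"), (0.75, "fair to good"))


@dataclass
class KappaResult:
    kappa: float | None
    interpretation: str


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Chance-corrected agreement between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    Interpretation bands: < 0.4 poor, 0.4-0.75 (inclusive) fair to good,
    > 0.75 excellent.  If both raters are constant and identical (p_e = 1)
    kappa is undefined and reported as such.
    """
    a = np.asarray(ratings_a, dtype=bool)
    b = np.asarray(ratings_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("ratings must be equal-length 1-D arrays of length >= 2")
    n = a.size
    p_o = float((a == b).mean())
    p_yes = float(a.mean()) * float(b.mean())
    p_no = float((~a).mean()) * float((~b).mean())
    p_e = p_yes + p_no
    if p_e >= 1.0 - 1e-15:
        return KappaResult(kappa=None, interpretation="undefined")
    k = (p_o - p_e) / (1.0 - p_e)
    if k < _KAPPA_BANDS[0][0]:
        interp = "poor"
    elif k <= _KAPPA_BANDS[1][0]:
        interp = "fair to good"
    else:
        interp = "excellent"
    return KappaResult(kappa=k, interpretation=interp)


def association_test(table: ConfusionTable2x2, method: str = "fisher") -> float:
    """Two-sided association p-value for a 2x2 table.

    Fisher's exact test by default (appropriate for small cells); Pearson
    chi-square with continuity correction behind ``method='chi2'``.
    """
    if table.total == 0:
        raise ValueError("empty table")
    arr = [[table.tp, table.fn], [table.fp, table.tn]]
    if method == "fisher":
        return float(fisher_exact(arr, alternative="two-sided").pvalue)
    if method == "chi2":
        return float(chi2_contingency(arr, correction=True).pvalue)
    raise ValueError(f"unknown method {method!r}")


def mean_iou(
    pred,
    truth,
    n_classes: int = 3,
    lesion_classes: tuple[int, ...] = (1, 2),
) -> dict:
    """Per-class IoU pooled across images plus the mean over lesion classes.

    `pred` and `truth` are arrays or equal-length sequences of arrays; pixels
    whose truth is the ignore label are excluded.  Classes absent from both
    prediction and truth are skipped in the mean (IoU undefined: None).
    """
    if isinstance(pred, np.ndarray):
        pred, truth = [pred], [truth]
    if len(pred) != len(truth):
        raise ValueError("pred and truth must have the same number of items")
    inter = np.zeros(n_classes, dtype=np.int64)
    union = np.zeros(n_classes, dtype=np.int64)
    for p, t in zip(pred, truth):
        p, t = np.asarray(p), np.asarray(t)
        if p.shape != t.shape:
            raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
        valid = t != IGNORE_LABEL
        for c in range(n_classes):
            pc = (p == c) & valid
            tc = (t == c) & valid
            inter[c] += int((pc & tc).sum())
            union[c] += int((pc | tc).sum())
    per_class = {c: (inter[c] / union[c] if union[c] > 0 else None) for c in range(n_classes)}
    lesion = [per_class[c] for c in lesion_classes if per_class[c] is not None]
    return {
        "per_class": per_class,
        "mean_lesion_iou": float(np.mean(lesion)) if lesion else None,
    }
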