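"""Method-comparison statistics: FCM calls versus standard suspension tests.

Two methods that both report an MBC on a two-fold ladder are compared by

* **categorical agreement** -- the fraction of paired samples classified
  identically ("above_or_MBC" vs "not_MBC"),
* **essential agreement** -- the fraction of evaluable pairs whose MBCs
  fall within +/-k doubling dilutions of each other (|log2 ratio| <= k),
  conventionally k = 1; pairs with a censored MBC on either side are
  excluded from the denominator and counted separately,
* **ROC analysis** of the normalized count as a predictor of the standard
  test's bactericidal call.  The score is *inverted*: low counts indicate a
  kill, so a sample is predicted bactericidal when its normalized count is
  below the threshold.  The operating threshold maximizes Youden's J
  (sensitivity + specificity - 1), breaking ties toward higher
  specificity.

Welch's unequal-variance t-test and the Kruskal-Wallis rank test are the
auxiliary group-comparison tests used alongside the agreement figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dose_response import ABOVE_OR_MBC, NOT_MBC

__all__ = [
    "PairedResult",
    "AgreementReport",
    "categorical_agreement",
    "essential_agreement",
    "roc_analysis",
    "pooled_percentage",
    "welch_t",
    "kruskal_wallis",
    "mbc_median",
]


def _round1(value: float) -> float:
    """Round half-up to one decimal (report parity with printed tables)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"),
                                               rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PairedResult:
    """One (strain, disinfectant) sample scored by both methods."""

    strain: str
    disinfectant: str
    fcm_label: str
    std_label: str
    fcm_mbc: float | None = None
    std_mbc: float | None = None
    fcm_censored: bool = False
    std_censored: bool = False

    def __post_init__(self) -> None:
        for label in (self.fcm_label, self.std_label):
            if label not in (ABOVE_OR_MBC, NOT_MBC):
                raise ValueError(f"label must be {ABOVE_OR_MBC!r} or {NOT_MBC!r}")


@dataclass
class AgreementReport:
    n_total: int
    n_concordant: int
    percent_agreement: float
    essential_k: int
    n_within_k: int
    n_evaluable: int
    percent_within_k: float
    n_censored: int
    confusion: tuple[tuple[int, int], tuple[int, int]] | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    roc_points: list[tuple[float, float, float]] = field(default_factory=list)
    auc: float | None = None
    chosen_threshold: float | None = None


class CategoricalAgreement(NamedTuple):
    n_concordant: int
    n_total: int
    percent: float


def categorical_agreement(pairs: Sequence[PairedResult]) -> CategoricalAgreement:
    """Fraction of pairs with identical bactericidal classification."""
    if not pairs:
        raise ValueError("no paired results")
    n_concordant = sum(p.fcm_label == p.std_label for p in pairs)
    n_total = len(pairs)
    return CategoricalAgreement(n_concordant, n_total,
                                _round1(100.0 * n_concordant / n_total))


class EssentialAgreement(NamedTuple):
    n_within_k: int
    n_evaluable: int
    percent: float
    n_censored: int


def essential_agreement(pairs: Sequence[PairedResult],
                        k: int = 1) -> EssentialAgreement:
    """Pairs whose MBCs agree within +/-k doubling dilutions.

    Censored pairs (either MBC missing or flagged censored) are excluded
    from the denominator and counted separately.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    n_within = n_eval = n_censored = 0
    for p in pairs:
        if (p.fcm_mbc is None or p.std_mbc is None
                or p.fcm_censored or p.std_censored):
            n_censored += 1
            continue
        if p.fcm_mbc <= 0 or p.std_mbc <= 0:
            raise ValueError("MBC concentrations must be > 0")
        n_eval += 1
        if abs(np.log2(p.fcm_mbc / p.std_mbc)) <= k + 1e-9:
            n_within += 1
    percent = _round1(100.0 * n_within / n_eval) if n_eval else 0.0
    return EssentialAgreement(n_within, n_eval, percent, n_censored)


def pooled_percentage(counts: Sequence[tuple[int, int]]) -> float:
    """Pool per-group (numerator, denominator) counts into one percentage."""
    num = sum(n for n, _ in counts)
    den = sum(d for _, d in counts)
    if den <= 0 or any(d <= 0 for _, d in counts):
        raise ValueError("denominators must be > 0")
    return _round1(100.0 * num / den)


def _truth_to_binary(truth: Sequence) -> np.ndarray:
    out = []
    for t in truth:
        if isinstance(t, str):
            out.append(1 if t == ABOVE_OR_MBC else 0)
        else:
            out.append(int(bool(t)))
    return np.asarray(out)


class RocResult(NamedTuple):
    roc_points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float
    chosen_threshold: float
    sensitivity: float
    specificity: float
    confusion: tuple[tuple[int, int], tuple[int, int]]  # [[TP,FN],[FP,TN]]


def roc_analysis(scores: Sequence[float], truth: Sequence) -> RocResult:
    """ROC of normalized counts against the reference bactericidal call.

    The positive class is "above_or_MBC" (a kill); because low counts mean
    a kill, a sample is predicted positive when ``score <= threshold``.
    The curve is swept over all distinct scores (ties grouped), the AUC is
    the trapezoid area, and the operating threshold maximizes Youden's J
    with ties broken toward higher specificity.
    """
    y = _truth_to_binary(truth)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    if y.min() == y.max():
        raise ValueError("truth must contain both classes")
    # negate so that larger transformed score = more positive, the
    # orientation scikit-learn's sweep expects
    fpr, tpr, neg_thr = _sk_roc_curve(y, -s)
    thresholds = -neg_thr
    roc_points = [(float(f), float(t), float(th))
                  for f, t, th in zip(fpr, tpr, thresholds)]
    auc_value = float(_trapezoid_auc(fpr, tpr))
    youden = tpr - fpr
    # ties on J resolved toward higher specificity (lower fpr)
    best = int(np.lexsort((fpr, -youden))[0])
    chosen = float(thresholds[best])
    predicted = s <= chosen
    tp = int(np.sum(predicted & (y == 1)))
    fn = int(np.sum(~predicted & (y == 1)))
    fp = int(np.sum(predicted & (y == 0)))
    tn = int(np.sum(~predicted & (y == 0)))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return RocResult(roc_points, auc_value, chosen, float(sensitivity),
                     float(specificity), ((tp, fn), (fp, tn)))


def welch_t(x: Sequence[float], y: Sequence[float],
            sides: str = "two") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df.

    ``sides='one'`` tests mean(x) > mean(y).
    """
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("both samples have zero variance")
    alternative = "greater" if sides == "one" else "two-sided"
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p, df = groups - 1."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    df = float(len(groups) - 1)
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def mbc_median(values: Sequence[float]) -> float:
    """Median of a column of MBC determinations (how MBCs are reported)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no MBC values")
    return float(np.median(arr))
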