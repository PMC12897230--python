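"""Class-imbalance-aware diagnostic statistics and paired McNemar testing.

Screening cohorts for age-related macular degeneration are heavily skewed
toward the negative class, so overall accuracy alone is misleading.  This
module computes the statistics that remain informative under imbalance —
per-class sensitivity/specificity/precision/F1 from one-vs-rest confusion
counts, balanced accuracy, macro and support-weighted averages, the
multiclass Matthews correlation coefficient and Cohen's kappa — plus the
paired McNemar test that compares two conditions (e.g. a classifier run on
noisy versus denoised inputs) on the same cases.

The multiclass MCC uses the marginal-only form (Gorodkin's R_K): it needs
only the confusion-matrix diagonal and the row/column totals, which is all a
table of one-vs-rest aggregates preserves.  It is algebraically identical to
the full-matrix definition (verified against scikit-learn in the tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OneVsRestCounts",
    "ClassRates",
    "MacroSummary",
    "MulticlassMarginals",
    "AgreementStats",
    "McNemarInput",
    "McNemarResult",
    "per_class_rates",
    "macro_summary",
    "multiclass_agreement",
    "mcnemar",
    "round_half_up",
]


def round_half_up(x: float, digits: int = 4) -> float:
    """Round with ties away from zero, matching how report tables are printed."""
    if math.isnan(x):
        return x
    q = 10.0**digits
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class OneVsRestCounts:
    """Per-class TP/FN/FP/TN tables from a multiclass evaluation.

    Each class is scored one-vs-rest, so every class's four counts sum to the
    same total N and the TP entries are the multiclass confusion diagonal.
    """

    classes: tuple[str, ...]
    tp: tuple[int, ...]
    fn: tuple[int, ...]
    fp: tuple[int, ...]
    tn: tuple[int, ...]

    def __post_init__(self) -> None:
        k = len(self.classes)
        if not all(len(x) == k for x in (self.tp, self.fn, self.fp, self.tn)):
            raise ValueError("all count tuples must have one entry per class")
        if any(v < 0 for x in (self.tp, self.fn, self.fp, self.tn) for v in x):
            raise ValueError("counts must be non-negative")
        totals = {self.tp[i] + self.fn[i] + self.fp[i] + self.tn[i] for i in range(k)}
        if len(totals) != 1:
            raise ValueError("tp+fn+fp+tn must be identical across classes")

    @property
    def n(self) -> int:
        return self.tp[0] + self.fn[0] + self.fp[0] + self.tn[0]

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(t + f for t, f in zip(self.tp, self.fn))

    def marginals(self) -> "MulticlassMarginals":
        return MulticlassMarginals(
            classes=self.classes,
            diagonal=self.tp,
            true_totals=tuple(t + f for t, f in zip(self.tp, self.fn)),
            pred_totals=tuple(t + f for t, f in zip(self.tp, self.fp)),
            n=self.n,
        )


@dataclass(frozen=True)
class MulticlassMarginals:
    """Diagonal and marginal totals of a multiclass confusion matrix."""

    classes: tuple[str, ...]
    diagonal: tuple[int, ...]
    true_totals: tuple[int, ...]
    pred_totals: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if sum(self.true_totals) != self.n or sum(self.pred_totals) != self.n:
            raise ValueError("true and predicted totals must each sum to N")
        for d, t, p in zip(self.diagonal, self.true_totals, self.pred_totals):
            if not (0 <= d <= min(t, p)):
                raise ValueError("diagonal entries must satisfy 0 <= d <= min(t, p)")


@dataclass
class ClassRates:
    label: str
    sensitivity: float  # NaN where the denominator is empty
    specificity: float
    precision: float
    f1: float


@dataclass
class MacroSummary:
    overall_accuracy: float
    balanced_accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float


@dataclass
class AgreementStats:
    mcc: float
    kappa: float
    degenerate: bool = False  # constant predictor or constant truth


@dataclass(frozen=True)
class McNemarInput:
    """Paired 2x2 correctness table: a both-correct, b improved, c degraded, d both-wrong."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class McNemarResult:
    b: int
    c: int
    chi2_cc: float      # continuity-corrected (|b-c|-1)^2 / (b+c)
    p_cc: float
    chi2_unc: float     # (b-c)^2 / (b+c)
    p_unc: float
    p_exact: float      # two-sided exact binomial
    degenerate: bool = False  # b + c == 0: chi-square forms undefined


def per_class_rates(counts: OneVsRestCounts) -> list[ClassRates]:
    """Sensitivity, specificity, precision and F1 for each class.

    A zero denominator makes the corresponding metric undefined; it is
    reported as NaN rather than silently coerced to 0.
    """
    out = []
    for i, label in enumerate(counts.classes):
        tp, fn, fp, tn = counts.tp[i], counts.fn[i], counts.fp[i], counts.tn[i]
        sens = tp / (tp + fn) if tp + fn else math.nan
        spec = tn / (tn + fp) if tn + fp else math.nan
        prec = tp / (tp + fp) if tp + fp else math.nan
        if math.isnan(sens) or math.isnan(prec) or (prec + sens) == 0:
            f1 = math.nan if (math.isnan(sens) or math.isnan(prec)) else 0.0
        else:
            f1 = 2 * prec * sens / (prec + sens)
        out.append(ClassRates(label, sens, spec, prec, f1))
    return out


def macro_summary(counts: OneVsRestCounts) -> MacroSummary:
    """Imbalance-aware aggregate metrics over all classes.

    Balanced accuracy is the unweighted mean of per-class sensitivities;
    macro metrics are unweighted means, weighted F1 weights per-class F1 by
    class support.  Any undefined per-class metric propagates as NaN.
    """
    rates = per_class_rates(counts)
    sens = np.array([r.sensitivity for r in rates])
    prec = np.array([r.precision for r in rates])
    f1 = np.array([r.f1 for r in rates])
    support = np.array(counts.support, dtype=np.float64)
    return MacroSummary(
        overall_accuracy=sum(counts.tp) / counts.n,
        balanced_accuracy=float(sens.mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(sens.mean()),
        macro_f1=float(f1.mean()),
        weighted_f1=float((support * f1).sum() / support.sum()),
    )


def multiclass_agreement(m: MulticlassMarginals) -> AgreementStats:
    """Multiclass MCC (marginal-only form) and Cohen's kappa.

    MCC = (N * sum(d) - sum(p_k * t_k)) / sqrt((N^2 - sum(p_k^2)) * (N^2 - sum(t_k^2)));
    kappa = (p_o - p_e) / (1 - p_e) with p_o = sum(d)/N and p_e = sum(p_k * t_k)/N^2.
    A constant predictor or constant truth zeroes a denominator; by
    convention both statistics are then 0 with the degeneracy flagged.
    """
    if m.n <= 0:
        raise ValueError("N must be positive")
    d = np.array(m.diagonal, dtype=np.float64)
    t = np.array(m.true_totals, dtype=np.float64)
    p = np.array(m.pred_totals, dtype=np.float64)
    n = float(m.n)
    cov = d.sum() * n - float(p @ t)
    var_p = n * n - float(p @ p)
    var_t = n * n - float(t @ t)
    pe = float(p @ t) / (n * n)
    degenerate = var_p == 0.0 or var_t == 0.0 or pe == 1.0
    if degenerate:
        return AgreementStats(mcc=0.0, kappa=0.0, degenerate=True)
    mcc = cov / math.sqrt(var_p * var_t)
    po = d.sum() / n
    kappa = (po - pe) / (1.0 - pe)
    return AgreementStats(mcc=float(mcc), kappa=float(kappa))


def mcnemar(table: McNemarInput) -> McNemarResult:
    """Paired McNemar test on the discordant counts b (improved), c (degraded).

    Reports the continuity-corrected and uncorrected chi-square statistics
    (1 degree of freedom) and the exact two-sided binomial p-value of b
    successes in b + c fair-coin trials, computed as twice the smaller tail
    probability capped at 1.  With b + c = 0 the chi-square forms are
    undefined: only p_exact = 1 is returned, flagged degenerate.
    """
    b, c = table.b, table.c
    nd = b + c
    if nd == 0:
        return McNemarResult(b, c, math.nan, math.nan, math.nan, math.nan, 1.0, degenerate=True)
    chi2_cc = (abs(b - c) - 1) ** 2 / nd
    chi2_unc = (b - c) ** 2 / nd
    p_cc = float(stats.chi2.sf(chi2_cc, df=1))
    p_unc = float(stats.chi2.sf(chi2_unc, df=1))
    lower = float(stats.binom.cdf(b, nd, 0.5))
    upper = float(stats.binom.sf(b - 1, nd, 0.5))
    p_exact = min(1.0, 2.0 * min(lower, upper))
    return McNemarResult(b, c, float(chi2_cc), p_cc, float(chi2_unc), p_unc, p_exact)
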