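"""Confusion-matrix based diagnostic performance indicators and their 95% CIs.

All point estimates are computed at full precision; rounding happens only at
the reporting boundary (see :mod:`dxeval.reporting`).  Whenever a denominator
is zero the affected estimate is the missing sentinel ``None`` — never an
exception or an infinity — so that downstream tables and plots degrade
gracefully on extreme data.

Interval conventions
--------------------
* Sensitivity, specificity and accuracy carry Wilson score intervals, which
  behave far better than Wald intervals for small samples and proportions
  near 0 or 1.
* Predictive values are prevalence-conditioned through Bayes' theorem; their
  bounds are propagated conservatively by evaluating the Bayes expression at
  every combination of the Se and Sp interval limits.
* Likelihood-ratio intervals follow Simel's log-scale construction.
* The Youden index interval uses the sum of the two binomial variances.

The normal quantile is the literal constant ``z = 1.96`` (95% level, fixed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "AnalysisConfig",
    "build_confusion_matrix",
    "wilson_interval",
    "sensitivity",
    "specificity",
    "accuracy",
    "predictive_values",
    "likelihood_ratios",
    "youden",
    "evaluate_all",
]

#: fixed 95% normal quantile used throughout
Z_95 = 1.96


@dataclass(frozen=True)
class ConfusionMatrix:
    """The four counts of a 2x2 classification table.

    ``tp``/``fn`` partition the diseased margin, ``tn``/``fp`` the
    non-diseased margin.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_nondiseased(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_counts(self) -> dict[str, int]:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}


@dataclass
class Estimate:
    """A point estimate with 95% bounds; any field may be missing (``None``)."""

    label: str
    value: Optional[float]
    lower: Optional[float] = None
    upper: Optional[float] = None

    @property
    def is_missing(self) -> bool:
        return self.value is None

    def astuple(self) -> tuple[Optional[float], Optional[float], Optional[float]]:
        return (self.value, self.lower, self.upper)

    @classmethod
    def missing(cls, label: str) -> "Estimate":
        return cls(label=label, value=None, lower=None, upper=None)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-wide settings: population prevalence, normal quantile, display digits.

    ``prevalence`` is the pre-test disease probability in the target
    population; it drives PPV/NPV and must lie strictly inside (0, 1) since
    the Bayes expressions degenerate at the endpoints.  ``z`` and
    ``report_decimals`` are fixed by convention (95% level, 3 decimals).
    """

    prevalence: float
    z: float = Z_95
    report_decimals: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(
                f"prevalence must lie strictly between 0 and 1, got {self.prevalence!r}"
            )
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.report_decimals < 0:
            raise ValueError("report_decimals must be >= 0")


def build_confusion_matrix(
    test_binary: Sequence[int], ref: Sequence[int]
) -> ConfusionMatrix:
    """Cross-tabulate a 0/1 test vector against the 0/1 reference."""
    t = np.asarray(test_binary)
    r = np.asarray(ref)
    if t.shape != r.shape or t.ndim != 1:
        raise ValueError(
            f"test and reference vectors must be 1-D and of equal length "
            f"(got shapes {t.shape} and {r.shape})"
        )
    if t.size < 1:
        raise ValueError("empty input vectors")
    for name, v in (("test", t), ("reference", r)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} vector must contain only 0 and 1 values")
    t = t.astype(int)
    r = r.astype(int)
    return ConfusionMatrix(
        tp=int(np.sum((t == 1) & (r == 1))),
        fp=int(np.sum((t == 1) & (r == 0))),
        fn=int(np.sum((t == 0) & (r == 1))),
        tn=int(np.sum((t == 0) & (r == 0))),
    )


def wilson_interval(
    successes: int, n: int, z: float = Z_95
) -> tuple[Optional[float], Optional[float]]:
    """Wilson score interval for a binomial proportion.

    Returns ``(None, None)`` when ``n == 0`` (the zero-denominator rule).
    The lower bound is exactly 0 at zero successes and the upper bound
    exactly 1 at ``successes == n`` (the score interval collapses
    algebraically at the boundary; we enforce it against round-off).
    """
    if n == 0:
        return (None, None)
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, n]; got {successes} with n={n}")
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = (z * math.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))) / denom
    lower = 0.0 if successes == 0 else max(0.0, centre - half)
    upper = 1.0 if successes == n else min(1.0, centre + half)
    return (lower, upper)


def _proportion_estimate(
    label: str, successes: int, n: int, z: float
) -> Estimate:
    if n == 0:
        return Estimate.missing(label)
    lower, upper = wilson_interval(successes, n, z)
    return Estimate(label=label, value=successes / n, lower=lower, upper=upper)


def sensitivity(cm: ConfusionMatrix, cfg: AnalysisConfig) -> Estimate:
    """Se = TP / (TP + FN), Wilson interval on the diseased margin."""
    return _proportion_estimate("Sensitivity", cm.tp, cm.n_diseased, cfg.z)


def specificity(cm: ConfusionMatrix, cfg: AnalysisConfig) -> Estimate:
    """Sp = TN / (TN + FP), Wilson interval on the non-diseased margin."""
    return _proportion_estimate("Specificity", cm.tn, cm.n_nondiseased, cfg.z)


def accuracy(cm: ConfusionMatrix, cfg: AnalysisConfig) -> Estimate:
    """Overall correct-classification proportion (TP + TN) / N."""
    return _proportion_estimate("Accuracy", cm.tp + cm.tn, cm.total, cfg.z)


def _bayes_ppv(se: float, sp: float, pr: float) -> Optional[float]:
    denom = se * pr + (1.0 - sp) * (1.0 - pr)
    if denom == 0.0:
        return None
    return se * pr / denom


def _bayes_npv(se: float, sp: float, pr: float) -> Optional[float]:
    denom = sp * (1.0 - pr) + (1.0 - se) * pr
    if denom == 0.0:
        return None
    return sp * (1.0 - pr) / denom


def predictive_values(
    se: Estimate, sp: Estimate, cfg: AnalysisConfig
) -> tuple[Estimate, Estimate]:
    """PPV and NPV from Bayes' theorem at the configured population prevalence.

    The supplied (not the sample) prevalence is the pre-test probability.
    Bounds are the min and max of the Bayes expression over the four
    combinations of the Se and Sp interval limits — a conservative,
    distribution-free propagation suited to small samples.  If either input
    estimate is missing, both outputs are fully missing.
    """
    pr = cfg.prevalence
    if se.is_missing or sp.is_missing:
        return (Estimate.missing("PPV"), Estimate.missing("NPV"))

    ppv_val = _bayes_ppv(se.value, sp.value, pr)
    npv_val = _bayes_npv(se.value, sp.value, pr)

    def _bounds(fun) -> tuple[Optional[float], Optional[float]]:
        if se.lower is None or sp.lower is None:
            return (None, None)
        combos = [
            fun(a, b, pr)
            for a, b in itertools.product((se.lower, se.upper), (sp.lower, sp.upper))
        ]
        combos = [c for c in combos if c is not None]
        if not combos:
            return (None, None)
        return (min(combos), max(combos))

    ppv_lo, ppv_hi = _bounds(_bayes_ppv) if ppv_val is not None else (None, None)
    npv_lo, npv_hi = _bounds(_bayes_npv) if npv_val is not None else (None, None)
    return (
        Estimate("PPV", ppv_val, ppv_lo, ppv_hi),
        Estimate("NPV", npv_val, npv_lo, npv_hi),
    )


def likelihood_ratios(
    cm: ConfusionMatrix, cfg: AnalysisConfig
) -> tuple[Estimate, Estimate]:
    """LR+ = Se/(1-Sp) and LR- = (1-Se)/Sp with Simel log-scale intervals.

    The log-scale standard errors involve reciprocals of individual cells,
    so a zero cell entering a reciprocal leaves that interval missing; a
    zero in a point-estimate denominator (an empty margin, Sp = 1 for LR+,
    Sp = 0 for LR-) leaves the whole estimate missing.  No continuity
    correction is applied.
    """
    z = cfg.z
    n_d, n_nd = cm.n_diseased, cm.n_nondiseased

    lr_pos = Estimate.missing("LR+")
    if n_d > 0 and n_nd > 0 and cm.fp > 0:  # fp == 0 <=> 1 - Sp == 0
        se = cm.tp / n_d
        one_minus_sp = cm.fp / n_nd
        value = se / one_minus_sp
        lower = upper = None
        if cm.tp > 0:
            log_se = math.sqrt(1 / cm.tp - 1 / n_d + 1 / cm.fp - 1 / n_nd)
            lower = math.exp(math.log(value) - z * log_se)
            upper = math.exp(math.log(value) + z * log_se)
        lr_pos = Estimate("LR+", value, lower, upper)

    lr_neg = Estimate.missing("LR-")
    if n_d > 0 and n_nd > 0 and cm.tn > 0:  # tn == 0 <=> Sp == 0
        one_minus_se = cm.fn / n_d
        sp = cm.tn / n_nd
        value = one_minus_se / sp
        lower = upper = None
        if cm.fn > 0:
            log_se = math.sqrt(1 / cm.fn - 1 / n_d + 1 / cm.tn - 1 / n_nd)
            lower = math.exp(math.log(value) - z * log_se)
            upper = math.exp(math.log(value) + z * log_se)
        lr_neg = Estimate("LR-", value, lower, upper)

    return (lr_pos, lr_neg)


def youden(cm: ConfusionMatrix, cfg: AnalysisConfig) -> Estimate:
    """Youden index J = Se + Sp - 1 with a binomial-variance normal interval.

    Se and Sp are estimated on disjoint margins and treated as independent,
    so var(J) = Se(1-Se)/n_d + Sp(1-Sp)/n_nd.  Bounds are reported
    unclipped; values slightly outside [0, 1] are a faithful reflection of
    the normal approximation, not an error.
    """
    if cm.n_diseased == 0 or cm.n_nondiseased == 0:
        return Estimate.missing("Youden index")
    se = cm.tp / cm.n_diseased
    sp = cm.tn / cm.n_nondiseased
    j = se + sp - 1.0
    sd = math.sqrt(
        se * (1.0 - se) / cm.n_diseased + sp * (1.0 - sp) / cm.n_nondiseased
    )
    return Estimate("Youden index", j, j - cfg.z * sd, j + cfg.z * sd)


def evaluate_all(cm: ConfusionMatrix, cfg: AnalysisConfig):
    """Compute the full indicator table for a confusion matrix.

    Returns a :class:`dxeval.reporting.MetricsReport` holding Se, Sp,
    accuracy, PPV, NPV, LR+, LR-, and the Youden index.  The AUC entry is
    appended by the ROC layer when a quantitative test is analysed.
    """
    from dxeval.reporting import MetricsReport  # deferred: reporting imports this module

    se = sensitivity(cm, cfg)
    sp = specificity(cm, cfg)
    acc = accuracy(cm, cfg)
    ppv, npv = predictive_values(se, sp, cfg)
    lr_pos, lr_neg = likelihood_ratios(cm, cfg)
    j = youden(cm, cfg)
    return MetricsReport.from_estimates(
        [se, sp, acc, ppv, npv, lr_pos, lr_neg, j], config=cfg
    )
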