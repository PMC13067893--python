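"""ROC curve construction, AUC with DeLong interval, cutoff selection, bootstrap band.

The curve is evaluated on the canonical candidate-threshold set: midpoints
between consecutive distinct observed values, flanked by -inf/+inf
sentinels.  With midpoint thresholds the strict (`>`) and non-strict (`>=`)
positivity rules are indistinguishable on the observed data; we classify a
score as positive when it lies strictly beyond the threshold in the
positive direction.

The trapezoidal area under this curve equals the Mann-Whitney statistic
with ties counted 1/2, i.e. the probability that a random case score
exceeds a random control score.  The AUC confidence interval uses DeLong's
nonparametric placement-value variance with midrank tie handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from dxeval.metrics import Z_95

__all__ = [
    "HIGHER_IS_POSITIVE",
    "LOWER_IS_POSITIVE",
    "ROCPoint",
    "ROCCurve",
    "AUCResult",
    "CutoffResult",
    "SensitivityBand",
    "detect_direction",
    "candidate_thresholds",
    "roc_curve",
    "auc",
    "delong_ci",
    "optimal_cutoff",
    "dichotomize",
    "bootstrap_band",
]

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"
_DIRECTIONS = (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE)


@dataclass(frozen=True)
class ROCPoint:
    """Empirical (Se, Sp) at one classification threshold."""

    threshold: float  # may be +-inf at the curve endpoints
    se: float
    sp: float


@dataclass
class ROCCurve:
    """Ordered ROC points over the full candidate-threshold range."""

    points: list[ROCPoint]
    direction: str

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.threshold for p in self.points])

    @property
    def se(self) -> np.ndarray:
        return np.array([p.se for p in self.points])

    @property
    def sp(self) -> np.ndarray:
        return np.array([p.sp for p in self.points])


@dataclass
class AUCResult:
    """AUC with a DeLong 95% interval; bounds are None on degenerate inputs."""

    auc: float
    lower: Optional[float]
    upper: Optional[float]
    method: str = "delong"
    variance: Optional[float] = None


@dataclass
class CutoffResult:
    """The threshold minimising the Euclidean distance to the ROC top-left corner."""

    threshold: float
    se: float
    sp: float
    distance: float


@dataclass
class SensitivityBand:
    """Pointwise bootstrap percentile band: Se quantiles on a specificity grid."""

    sp_grid: np.ndarray
    se_lower: np.ndarray
    se_upper: np.ndarray
    n_boot: int
    seed: Optional[int] = None


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError(
            f"scores and labels must be 1-D and of equal length "
            f"(got shapes {s.shape} and {y.shape})"
        )
    if np.isnan(s).any():
        raise ValueError("scores contain missing values; clean the dataset first")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must contain only 0 and 1 values")
    y = y.astype(int)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both label classes (0 and 1) must be present")
    return s, y


def detect_direction(scores: Sequence[float], labels: Sequence[int]) -> str:
    """Auto-detect positivity direction by comparing group medians.

    Higher scores indicate disease when the case median is at least the
    control median (ties resolve to ``higher_is_positive``).
    """
    s, y = _check_scores_labels(scores, labels)
    if np.median(s[y == 1]) >= np.median(s[y == 0]):
        return HIGHER_IS_POSITIVE
    return LOWER_IS_POSITIVE


def candidate_thresholds(scores: Sequence[float]) -> np.ndarray:
    """Midpoints between consecutive distinct score values, flanked by +-inf."""
    s = np.asarray(scores, dtype=float)
    if s.size < 1:
        raise ValueError("scores must be non-empty")
    vals = np.unique(s)
    mids = (vals[:-1] + vals[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_curve(
    scores: Sequence[float], labels: Sequence[int], direction: str
) -> ROCCurve:
    """Empirical ROC curve over the candidate thresholds.

    Under ``higher_is_positive`` a score is test-positive iff it is strictly
    greater than the threshold (mirrored under ``lower_is_positive``), so
    the -inf/+inf sentinels yield the (Se=1, Sp=0) and (Se=0, Sp=1)
    endpoints respectively.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    s, y = _check_scores_labels(scores, labels)
    thresholds = candidate_thresholds(s)
    cases = np.sort(s[y == 1])
    controls = np.sort(s[y == 0])
    n_d, n_nd = cases.size, controls.size

    if direction == HIGHER_IS_POSITIVE:
        # positive iff score > t
        pos_cases = n_d - np.searchsorted(cases, thresholds, side="right")
        pos_controls = n_nd - np.searchsorted(controls, thresholds, side="right")
    else:
        # positive iff score < t
        pos_cases = np.searchsorted(cases, thresholds, side="left")
        pos_controls = np.searchsorted(controls, thresholds, side="left")

    se = pos_cases / n_d
    sp = (n_nd - pos_controls) / n_nd
    points = [
        ROCPoint(threshold=float(t), se=float(a), sp=float(b))
        for t, a, b in zip(thresholds, se, sp)
    ]
    return ROCCurve(points=points, direction=direction)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the curve over (1 - Sp, Se).

    Equals the Mann-Whitney statistic with ties counted 1/2 on the raw
    scores, because the candidate-threshold curve visits every empirical
    operating point.
    """
    fpr = 1.0 - curve.sp
    se = curve.se
    order = np.lexsort((se, fpr))
    return float(np.trapezoid(se[order], fpr[order]))


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    return scores if direction == HIGHER_IS_POSITIVE else -scores


def delong_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    z: float = Z_95,
    direction: str = HIGHER_IS_POSITIVE,
) -> AUCResult:
    """AUC with DeLong's nonparametric variance from midrank placement values.

    The placement value of a case is the fraction of controls it beats
    (ties 1/2), and vice versa; the AUC variance is the sum of the two
    placement sample variances scaled by their group sizes.  With fewer
    than two cases or two controls the variance is undefined and the bounds
    are missing while the AUC itself is still returned.  Bounds are clipped
    to [0, 1].
    """
    s, y = _check_scores_labels(scores, labels)
    x = _oriented(s, direction)
    cases = x[y == 1]
    controls = x[y == 0]
    m, n = cases.size, controls.size

    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)

    # placement values: fraction of the other group each observation beats
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    auc_hat = float(np.mean(v10))

    if m < 2 or n < 2:
        return AUCResult(auc=auc_hat, lower=None, upper=None)

    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    half = z * math.sqrt(var)
    return AUCResult(
        auc=auc_hat,
        lower=max(0.0, auc_hat - half),
        upper=min(1.0, auc_hat + half),
        variance=var,
    )


def optimal_cutoff(curve: ROCCurve) -> Optional[CutoffResult]:
    """Finite threshold minimising d(t) = sqrt((1-Se)^2 + (1-Sp)^2).

    Ties are broken by highest sensitivity, then by smallest threshold —
    deterministic, and favouring case detection.  Returns ``None`` when the
    curve has no finite threshold (constant scores).
    """
    best: Optional[CutoffResult] = None
    for p in curve.points:
        if not math.isfinite(p.threshold):
            continue
        d = math.hypot(1.0 - p.se, 1.0 - p.sp)
        cand = CutoffResult(threshold=p.threshold, se=p.se, sp=p.sp, distance=d)
        if (
            best is None
            or cand.distance < best.distance
            or (cand.distance == best.distance and cand.se > best.se)
            or (
                cand.distance == best.distance
                and cand.se == best.se
                and cand.threshold < best.threshold
            )
        ):
            best = cand
    return best


def dichotomize(
    scores: Sequence[float], cutoff: float, direction: str = HIGHER_IS_POSITIVE
) -> np.ndarray:
    """Classify each score as test-positive (1) or test-negative (0).

    Positive means strictly greater than the cutoff under
    ``higher_is_positive``, strictly smaller under ``lower_is_positive``.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    s = np.asarray(scores, dtype=float)
    if direction == HIGHER_IS_POSITIVE:
        return (s > cutoff).astype(int)
    return (s < cutoff).astype(int)


def _se_at_sp(curve: ROCCurve, sp_grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of the ROC polyline's Se at given specificities.

    For duplicated specificity values (vertical curve segments) the upper
    envelope (maximum Se) is used, so the interpolated band is conservative
    towards the curve.
    """
    sp = curve.sp
    se = curve.se
    order = np.lexsort((se, sp))
    sp_sorted = sp[order]
    se_sorted = se[order]
    # keep the max Se per distinct specificity; lexsort put it last
    keep = np.concatenate([sp_sorted[1:] != sp_sorted[:-1], [True]])
    return np.interp(sp_grid, sp_sorted[keep], se_sorted[keep])


def bootstrap_band(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 5000,
    sp_grid: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    direction: Optional[str] = None,
) -> SensitivityBand:
    """Pointwise 95% bootstrap band for sensitivity along the ROC curve.

    Cases and controls are resampled separately with replacement
    (stratified bootstrap), the ROC curve is rebuilt per replicate, and the
    sensitivity at each grid specificity is interpolated; the band is the
    2.5th/97.5th percentile envelope.  A replicate with constant scores
    degenerates to the diagonal curve and is retained, never an error.
    With a seed the band is bit-reproducible; without one fresh randomness
    is used.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    s, y = _check_scores_labels(scores, labels)
    if direction is None:
        direction = detect_direction(s, y)
    if sp_grid is None:
        sp_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)
    grid = np.asarray(sp_grid, dtype=float)

    cases = s[y == 1]
    controls = s[y == 0]
    rng = np.random.default_rng(seed)
    se_samples = np.empty((n_boot, grid.size))
    lab = np.concatenate([np.ones(cases.size, dtype=int), np.zeros(controls.size, dtype=int)])
    for b in range(n_boot):
        rs = np.concatenate(
            [
                rng.choice(cases, size=cases.size, replace=True),
                rng.choice(controls, size=controls.size, replace=True),
            ]
        )
        se_samples[b] = _se_at_sp(roc_curve(rs, lab, direction), grid)

    lower = np.percentile(se_samples, 2.5, axis=0)
    upper = np.percentile(se_samples, 97.5, axis=0)
    return SensitivityBand(
        sp_grid=grid,
        se_lower=lower,
        se_upper=upper,
        n_boot=n_boot,
        seed=seed,
    )
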