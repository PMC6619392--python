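"""Predictive-performance measures.

Discrimination
    Empirical concordance (c-statistic / ROC area) and its binormal
    approximation AUC = Phi((m1 - m0) / sqrt(v1 + v0)), together with the
    closed-form change in AUC induced by a measurement model.

Overall accuracy
    Brier score BS = mean (y - p)^2 and its exact decomposition into a
    calibration term, mean (y - p)(1 - 2p), and a refinement term,
    mean p(1 - p).  For y in {0, 1} the identity
    (y - p)^2 = (y - p)(1 - 2p) + p(1 - p) holds pointwise, so the split is
    exact for every sample.  Under perfect calibration the calibration term
    has expectation zero and the expected Brier score is the refinement
    term; the expected change in Brier score from substituting measurements
    is then the difference of the two refinement terms.

Calibration
    Logistic recalibration logit(y) = a + b * lp gives the calibration
    slope b (1 ideal, <1 predictions too extreme, >1 too moderate);
    calibration-in-the-large is the intercept refitted with lp as a fixed
    offset (a | b=1), negative when risks are systematically overestimated.
    Calibration curves are quantile-binned by predicted risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import norm, rankdata

from .measurement import MeasurementSpec
from .modeling import fit_logistic

__all__ = [
    "GroupStats",
    "BrierParts",
    "CalibrationResult",
    "concordance",
    "binormal_auc",
    "delta_auc",
    "brier",
    "brier_decomposition",
    "expected_delta_brier",
    "recalibrate",
    "calibration_in_the_large",
    "calibration_curve",
    "evaluate_predictions",
    "evaluate_predictions_table",
]


@dataclass(frozen=True)
class GroupStats:
    """Per-class sample moments of one measurement (cases vs noncases)."""

    mean1: float
    mean0: float
    var1: float
    var0: float
    n1: int
    n0: int

    def __post_init__(self) -> None:
        if self.var1 < 0 or self.var0 < 0:
            raise ValueError("variances must be non-negative")
        if self.n1 < 1 or self.n0 < 1:
            raise ValueError("both classes must be non-empty")

    @classmethod
    def from_sample(cls, y: np.ndarray, x: np.ndarray) -> "GroupStats":
        y = np.asarray(y)
        x = np.asarray(x, dtype=float)
        x1, x0 = x[y == 1], x[y == 0]
        if x1.size < 2 or x0.size < 2:
            raise ValueError("need at least two observations per class")
        return cls(
            mean1=float(x1.mean()),
            mean0=float(x0.mean()),
            var1=float(x1.var(ddof=1)),
            var0=float(x0.var(ddof=1)),
            n1=x1.size,
            n0=x0.size,
        )

    def swapped(self) -> "GroupStats":
        return GroupStats(self.mean0, self.mean1, self.var0, self.var1, self.n0, self.n1)


@dataclass(frozen=True)
class BrierParts:
    """Brier score split into calibration and refinement components."""

    total: float
    calibration_term: float
    refinement_term: float


@dataclass
class CalibrationResult:
    """Recalibration summary: slope b, intercept a, CITL, binned curve."""

    slope: float
    intercept: float
    citl: float | None = None
    curve: list[tuple[float, float, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# discrimination


def concordance(y: np.ndarray, scores: np.ndarray) -> float:
    """Empirical c-statistic: P(score_case > score_noncase), ties count 1/2.

    Equals the area under the ROC curve.  Computed from mid-ranks in
    O(n log n).
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("concordance requires both outcome classes")
    ranks = rankdata(scores)  # mid-ranks give ties half credit
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def binormal_auc(stats: GroupStats) -> float:
    """Binormal approximation Phi((mean1 - mean0) / sqrt(var1 + var0))."""
    total_var = stats.var1 + stats.var0
    if total_var <= 0:
        raise ValueError("total within-class variance must be positive")
    return float(norm.cdf((stats.mean1 - stats.mean0) / np.sqrt(total_var)))


def transformed_group_stats(stats_x: GroupStats, spec: MeasurementSpec) -> GroupStats:
    """Group moments of W implied by the measurement model applied to X."""
    return GroupStats(
        mean1=spec.psi1 + spec.theta1 * stats_x.mean1,
        mean0=spec.psi0 + spec.theta0 * stats_x.mean0,
        var1=stats_x.var1 * spec.theta1**2 + spec.err_var1,
        var0=stats_x.var0 * spec.theta0**2 + spec.err_var0,
        n1=stats_x.n1,
        n0=stats_x.n0,
    )


def delta_auc(stats_x: GroupStats, spec: MeasurementSpec) -> float:
    """Closed-form change in binormal AUC when X is replaced by W.

    Negative under random error (noise dilutes the case/noncase contrast);
    can be positive under differential error, e.g. a case-specific upward
    shift psi1 > psi0 that widens the contrast.
    """
    return binormal_auc(transformed_group_stats(stats_x, spec)) - binormal_auc(stats_x)


# ---------------------------------------------------------------------------
# overall accuracy


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return p


def brier(y: np.ndarray, p: np.ndarray) -> float:
    """Brier score: mean squared difference between outcomes and predictions."""
    y = np.asarray(y, dtype=float)
    p = _check_probs(p)
    return float(np.mean((y - p) ** 2))


def brier_decomposition(y: np.ndarray, p: np.ndarray) -> BrierParts:
    """Exact split of the Brier score into calibration + refinement terms."""
    y = np.asarray(y, dtype=float)
    p = _check_probs(p)
    cal = float(np.mean((y - p) * (1.0 - 2.0 * p)))
    ref = float(np.mean(p * (1.0 - p)))
    return BrierParts(total=cal + ref, calibration_term=cal, refinement_term=ref)


def expected_delta_brier(p_w: np.ndarray, p_x: np.ndarray) -> float:
    """Expected Brier-score change under perfect calibration.

    Difference of refinement terms, mean p_w(1-p_w) - mean p_x(1-p_x);
    positive when the pragmatic measurement yields less accurate (less
    extreme) predictions.
    """
    p_w = _check_probs(p_w)
    p_x = _check_probs(p_x)
    if p_w.shape != p_x.shape:
        raise ValueError("p_w and p_x must have equal length")
    return float(np.mean(p_w * (1.0 - p_w)) - np.mean(p_x * (1.0 - p_x)))


# ---------------------------------------------------------------------------
# calibration


def recalibrate(y_val: np.ndarray, lp: np.ndarray) -> CalibrationResult:
    """Fit the recalibration model logit(y) = a + b * lp by ML."""
    lp = np.asarray(lp, dtype=float)
    if lp.std() == 0.0:
        raise ValueError("linear predictor is constant; slope is undefined")
    fit = fit_logistic(np.asarray(y_val, dtype=float), lp)
    return CalibrationResult(slope=float(fit.coef_hat[0]), intercept=fit.intercept_hat)


def calibration_in_the_large(
    y_val: np.ndarray, lp: np.ndarray, tol: float = 1e-12, max_iter: int = 100
) -> float:
    """Intercept of an intercept-only ML logistic fit with lp as fixed offset.

    The recalibration intercept given unit slope, a | b = 1.  Zero in the
    fitting sample; negative when predicted risks exceed observed rates.
    """
    y = np.asarray(y_val, dtype=float)
    lp = np.asarray(lp, dtype=float)
    n1 = y.sum()
    if n1 == 0 or n1 == y.shape[0]:
        raise ValueError("both outcome classes must be present")
    a = 0.0
    for _ in range(max_iter):
        p = expit(a + lp)
        info = np.sum(p * (1.0 - p))
        step = np.sum(y - p) / info
        a += step
        if abs(step) < tol:
            break
    return float(a)


def calibration_curve(
    y: np.ndarray, p: np.ndarray, n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Quantile-binned calibration curve.

    Returns one ``(mean predicted, observed fraction, count)`` tuple per
    bin of predicted risk.  Bins with identical quantile edges (few
    distinct predictions) are collapsed with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=float)
    p = _check_probs(p)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"collapsed {n_bins} requested bins to {max(len(edges) - 1, 1)} "
            "due to ties in predicted risk",
            stacklevel=2,
        )
    if len(edges) < 2:  # all predictions identical
        return [(float(p.mean()), float(y.mean()), int(y.size))]
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
    curve = []
    for b in range(len(edges) - 1):
        mask = idx == b
        cnt = int(mask.sum())
        if cnt == 0:
            continue
        curve.append((float(p[mask].mean()), float(y[mask].mean()), cnt))
    return curve


# ---------------------------------------------------------------------------
# standalone evaluation of user-supplied predictions


def evaluate_predictions(
    y: np.ndarray,
    p: np.ndarray | None = None,
    lp: np.ndarray | None = None,
) -> dict[str, float]:
    """All performance measures for one (outcome, prediction) table.

    Provide predicted probabilities ``p`` or a linear predictor ``lp``
    (probabilities are then ``expit(lp)``).  Returns a flat record with the
    c-statistic, recalibration slope and intercept, CITL, and the Brier
    score with its components.
    """
    if (p is None) == (lp is None):
        raise ValueError("provide exactly one of p (probabilities) or lp (logits)")
    if lp is None:
        p = _check_probs(p)
        eps = np.finfo(float).tiny
        lp = np.log(np.clip(p, eps, 1.0)) - np.log(np.clip(1.0 - p, eps, 1.0))
    else:
        lp = np.asarray(lp, dtype=float)
        p = expit(lp)
    y = np.asarray(y, dtype=float)
    recal = recalibrate(y, lp)
    parts = brier_decomposition(y, p)
    return {
        "n": int(y.size),
        "c": concordance(y, lp),
        "slope": recal.slope,
        "recal_intercept": recal.intercept,
        "citl": calibration_in_the_large(y, lp),
        "brier": parts.total,
        "brier_calibration": parts.calibration_term,
        "brier_refinement": parts.refinement_term,
    }


def evaluate_predictions_table(
    path,
    outcome_col: str = "y",
    prediction_col: str | None = "p",
    lp_col: str | None = None,
    delimiter: str | None = None,
) -> dict[str, float]:
    """Evaluate a delimited-text table of outcomes and predictions.

    The file must have a header row; the delimiter is sniffed from the
    extension (``.csv`` -> comma, otherwise whitespace/tab) unless given.
    """
    import pandas as pd

    sep = delimiter or ("," if str(path).endswith(".csv") else r"\s+")
    frame = pd.read_csv(path, sep=sep)
    for col in filter(None, (outcome_col, prediction_col, lp_col)):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    y = frame[outcome_col].to_numpy(dtype=float)
    if lp_col is not None:
        return evaluate_predictions(y, lp=frame[lp_col].to_numpy(dtype=float))
    return evaluate_predictions(y, p=frame[prediction_col].to_numpy(dtype=float))
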