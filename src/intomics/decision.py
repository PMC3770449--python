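"""Aggregation of platform statistics and the empirical decision rule.

The linear aggregated statistic weights each platform's side-adjusted
statistic by the inverse of its permutation-null standard deviation,

    t_A = sum_q t_q / sigma_hat_q,

and a biomarker is selected when t_A strictly exceeds C_alpha, the
empirical 100(1-alpha)% percentile of the aggregated statistic over the
pooled null. For Q = 2 the rule is a line in the (t_1, t_2) plane with
coefficients (1/sigma_hat_1, 1/sigma_hat_2) and intercept C_alpha.

The quadratic alternative t_Q = v' Sigma_hat^{-1} v (v the signed
statistic vector) is sign-agnostic and intended for two-sided
alternatives only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .data import StatMatrix, ValidationError
from .permutation import NullDistribution

ArrayLike = Union[np.ndarray, StatMatrix]


@dataclass
class DecisionResult:
    """Per-biomarker aggregated statistics and the selection they imply."""

    biomarker_ids: np.ndarray
    platform_ids: np.ndarray
    t_agg: np.ndarray
    C_alpha: float
    alpha: float
    method: str  # "linear" | "quadratic"
    selected_mask: np.ndarray
    sigma_hat: np.ndarray
    #: for Q=2 linear: (1/sigma_hat_1, 1/sigma_hat_2, C_alpha)
    decision_line: Optional[Tuple[float, float, float]] = None

    @property
    def selected(self) -> np.ndarray:
        return self.biomarker_ids[self.selected_mask]

    @property
    def n_selected(self) -> int:
        return int(self.selected_mask.sum())


def _adjusted(stats: ArrayLike) -> np.ndarray:
    return stats.stats if isinstance(stats, StatMatrix) else np.asarray(stats, float)


def _raw(stats: ArrayLike) -> np.ndarray:
    return stats.raw if isinstance(stats, StatMatrix) else np.asarray(stats, float)


def aggregate_linear(stats: ArrayLike, null: NullDistribution) -> np.ndarray:
    """Inverse-sd weighted sum of side-adjusted statistics per biomarker."""
    S = _adjusted(stats)
    if S.shape[1] != null.sigma_hat.shape[0]:
        raise ValidationError(
            f"stat matrix has {S.shape[1]} platforms but null has "
            f"{null.sigma_hat.shape[0]}"
        )
    return S @ (1.0 / null.sigma_hat)


def aggregate_quadratic(
    stats: ArrayLike,
    null: NullDistribution,
    max_condition: float = 1e12,
) -> np.ndarray:
    """Mahalanobis-form statistic v' Sigma_hat^{-1} v on signed statistics."""
    V = _raw(stats)
    cov = null.cov_hat
    if V.shape[1] != cov.shape[0]:
        raise ValidationError("stat matrix / covariance dimension mismatch")
    if np.linalg.cond(cov) > max_condition:
        raise ValidationError(
            "estimated statistic covariance is (near-)singular; consider "
            "dropping a redundant platform or adding a ridge to cov_hat"
        )
    return np.einsum("ij,ij->i", V, np.linalg.solve(cov, V.T).T)


def null_aggregate(null: NullDistribution, method: str = "linear") -> np.ndarray:
    """The aggregated statistic evaluated on every pooled null row."""
    if method == "linear":
        return null.pooled @ (1.0 / null.sigma_hat)
    if method == "quadratic":
        return aggregate_quadratic(null.pooled_raw, null)
    raise ValidationError(f"unknown method {method!r}")


def threshold(null_agg: np.ndarray, alpha: float) -> float:
    """Empirical 100(1-alpha)% percentile of the aggregated null.

    Returns the k-th order statistic with k = ceil((1-alpha) * M),
    clamped to [1, M]; alpha = 1 therefore yields the minimum. The value
    is attained (conservative) rather than interpolated.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    a = np.asarray(null_agg, dtype=float).ravel()
    M = a.size
    if M == 0:
        raise ValidationError("empty null aggregate")
    k = math.ceil((1 - alpha) * M - 1e-9)
    k = min(max(k, 1), M)
    return float(np.partition(a, k - 1)[k - 1])


def select(
    stats: StatMatrix,
    null: NullDistribution,
    alpha: float = 0.05,
    method: str = "linear",
) -> DecisionResult:
    """Aggregate, threshold at the pooled-null percentile, and select.

    Selection uses the strict inequality t_agg > C_alpha; a biomarker
    exactly on the decision boundary is not selected.
    """
    if method == "linear":
        t_agg = aggregate_linear(stats, null)
    elif method == "quadratic":
        t_agg = aggregate_quadratic(stats, null)
    else:
        raise ValidationError(f"unknown method {method!r}")
    c = threshold(null_aggregate(null, method), alpha)
    mask = t_agg > c
    line = None
    if method == "linear" and stats.n_platforms == 2:
        line = (
            float(1.0 / null.sigma_hat[0]),
            float(1.0 / null.sigma_hat[1]),
            float(c),
        )
    return DecisionResult(
        biomarker_ids=stats.biomarker_ids,
        platform_ids=stats.platform_ids,
        t_agg=t_agg,
        C_alpha=c,
        alpha=alpha,
        method=method,
        selected_mask=mask,
        sigma_hat=null.sigma_hat.copy(),
        decision_line=line,
    )
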