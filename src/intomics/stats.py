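"""Per-platform two-group summary statistics.

All raw statistics are oriented disease-minus-control, so a positive raw
value indicates up-regulation in the disease group. The side adjustment
then maps onto the scale where larger positive values support the
alternative hypothesis:

* ``right`` (up-regulated in disease): keep the raw statistic,
* ``left`` (down-regulated in disease): negate it,
* ``two``: absolute value.

Available statistics:

* ``student_t`` — Welch (unpooled-variance) two-sample t,
  ``t = (mean_d - mean_c) / sqrt(s_d^2/n_d + s_c^2/n_c)``;
* ``mean_diff`` — the unstandardized difference of group means;
* ``wilcoxon`` — the rank-sum of the disease group standardized by its
  exact permutation mean and tie-corrected variance (normal
  approximation, no continuity correction).

Marginal distributional accuracy is unimportant here: downstream
calibration is by permutation, so only the ordering and scale of the
statistics matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .data import PlatformData, StatMatrix, ValidationError, check_shared_biomarkers

logger = logging.getLogger(__name__)

STATISTICS = ("student_t", "mean_diff", "wilcoxon")
SIDES = ("right", "left", "two")

#: Finite stand-in for an infinite t when both group variances vanish but
#: the means differ; keeps pooled-null percentiles finite.
DEFAULT_CAP = 1e6


@dataclass(frozen=True)
class TestSpec:
    """Choice of statistic and alternative side for one platform."""

    __test__ = False  # not a pytest collection target

    statistic: str = "student_t"
    side: str = "two"

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValidationError(
                f"unknown statistic {self.statistic!r}; expected one of {STATISTICS}"
            )
        if self.side not in SIDES:
            raise ValidationError(
                f"unknown side {self.side!r}; expected one of {SIDES}"
            )


def side_adjust(raw: np.ndarray, side: str) -> np.ndarray:
    """Orient a raw (disease-minus-control) statistic toward its alternative."""
    if side == "right":
        return +np.asarray(raw)
    if side == "left":
        return -np.asarray(raw)
    if side == "two":
        return np.abs(raw)
    raise ValidationError(f"unknown side {side!r}")


# ---------------------------------------------------------------------------
# Vectorized kernels. X is (n, S); D is a (B, S) 0/1 disease-indicator
# matrix, one row per (permuted) group assignment. All return (n, B).
# ---------------------------------------------------------------------------

def _group_moments(X: np.ndarray, D: np.ndarray, n_d: int, n_c: int):
    sum_d = X @ D.T
    tot = X.sum(axis=1, keepdims=True)
    mean_d = sum_d / n_d
    mean_c = (tot - sum_d) / n_c
    return mean_d, mean_c


def _welch_t(X: np.ndarray, D: np.ndarray, n_d: int, n_c: int, cap: float) -> np.ndarray:
    # center rows to keep the sum-of-squares update numerically stable
    scale = np.maximum(1.0, np.abs(X).max(axis=1, keepdims=True))
    Xc = X - X.mean(axis=1, keepdims=True)
    sum_d = Xc @ D.T
    sumsq_d = (Xc * Xc) @ D.T
    tot = Xc.sum(axis=1, keepdims=True)
    totsq = (Xc * Xc).sum(axis=1, keepdims=True)
    mean_d = sum_d / n_d
    mean_c = (tot - sum_d) / n_c
    var_d = np.maximum(sumsq_d - n_d * mean_d**2, 0.0) / (n_d - 1)
    var_c = np.maximum((totsq - sumsq_d) - n_c * mean_c**2, 0.0) / (n_c - 1)
    denom = np.sqrt(var_d / n_d + var_c / n_c)
    diff = mean_d - mean_c
    zero_diff = np.abs(diff) <= 1e-8 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0
    if degenerate.any():
        capped = degenerate & ~zero_diff
        if capped.any():
            logger.warning(
                "%d biomarker/permutation cells had zero pooled variance with "
                "unequal means; statistic capped at %.3g",
                int(capped.sum()),
                cap,
            )
        t = np.where(degenerate, np.where(zero_diff, 0.0, np.sign(diff) * cap), t)
    return t


def _mean_diff(X: np.ndarray, D: np.ndarray, n_d: int, n_c: int) -> np.ndarray:
    mean_d, mean_c = _group_moments(X, D, n_d, n_c)
    return mean_d - mean_c


def _wilcoxon_z(R: np.ndarray, D: np.ndarray, n_d: int, n_c: int) -> np.ndarray:
    """Standardized disease rank-sum from precomputed within-row ranks R.

    Uses the exact mean and (tie-corrected) variance of the rank-sum under
    random relabeling: Var W = n_d * n_c / (S - 1) * pop-var(ranks).
    """
    S = R.shape[1]
    W = R @ D.T
    mu = n_d * (S + 1) / 2.0
    var_w = n_d * n_c / (S - 1) * R.var(axis=1, keepdims=True)
    sd = np.sqrt(var_w)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W - mu) / sd
    return np.where(sd == 0, 0.0, z)


def raw_stat_block(
    X: np.ndarray,
    D: np.ndarray,
    n_d: int,
    n_c: int,
    statistic: str,
    cap: float = DEFAULT_CAP,
    ranks: np.ndarray | None = None,
) -> np.ndarray:
    """Raw disease-minus-control statistics for all rows of X under each
    assignment in D. Returns an (n, B) array."""
    if statistic == "student_t":
        return _welch_t(X, D, n_d, n_c, cap)
    if statistic == "mean_diff":
        return _mean_diff(X, D, n_d, n_c)
    if statistic == "wilcoxon":
        if ranks is None:
            ranks = rankdata(X, axis=1)
        return _wilcoxon_z(ranks, D, n_d, n_c)
    raise ValidationError(f"unknown statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Public, scalar / matrix interfaces
# ---------------------------------------------------------------------------

def compute_statistic(
    x_control: Sequence[float],
    x_disease: Sequence[float],
    spec: TestSpec,
    cap: float = DEFAULT_CAP,
) -> float:
    """Side-adjusted statistic for one biomarker on one platform.

    Parameters
    ----------
    x_control, x_disease : array-like
        Measurements of the control and disease groups. Each needs at
        least two values (one suffices for ``mean_diff``).
    spec : TestSpec
    cap : float
        Finite value substituted for an infinite t when both group
        variances are zero but the means differ.
    """
    xc = np.asarray(x_control, dtype=float).ravel()
    xd = np.asarray(x_disease, dtype=float).ravel()
    min_len = 1 if spec.statistic == "mean_diff" else 2
    if len(xc) < min_len or len(xd) < min_len:
        raise ValidationError(
            f"{spec.statistic} needs >= {min_len} samples per group, got "
            f"{len(xc)} control / {len(xd)} disease"
        )
    X = np.concatenate([xd, xc])[None, :]
    D = np.zeros((1, X.shape[1]))
    D[0, : len(xd)] = 1.0
    raw = raw_stat_block(X, D, len(xd), len(xc), spec.statistic, cap=cap)
    return float(side_adjust(raw, spec.side)[0, 0])


def compute_stat_matrix(
    platforms: Sequence[PlatformData],
    specs: Sequence[TestSpec],
    cap: float = DEFAULT_CAP,
) -> StatMatrix:
    """Observed n x Q statistic matrix across platforms.

    All platforms must carry identical biomarker ids in identical order;
    entry (i, q) equals ``compute_statistic`` for biomarker i on platform
    q (computed vectorized).
    """
    biomarker_ids = check_shared_biomarkers(platforms)
    if len(specs) != len(platforms):
        raise ValidationError(
            f"got {len(specs)} test specs for {len(platforms)} platforms"
        )
    raw_cols = []
    adj_cols = []
    for p, spec in zip(platforms, specs):
        D = p.disease_mask.astype(float)[None, :]
        raw = raw_stat_block(
            p.values, D, p.n_disease, p.n_control, spec.statistic, cap=cap
        )[:, 0]
        raw_cols.append(raw)
        adj_cols.append(side_adjust(raw, spec.side))
    return StatMatrix(
        stats=np.column_stack(adj_cols),
        raw=np.column_stack(raw_cols),
        platform_ids=np.array([p.platform_id for p in platforms], dtype=object),
        biomarker_ids=biomarker_ids,
    )
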