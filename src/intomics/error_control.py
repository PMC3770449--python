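"""Multiplicity adjustment and error-rate summaries.

Two per-biomarker level choices are supported: the Bonferroni level
alpha*/n for familywise control, and the expected-false-positive level
alpha = f / (n * pi_hat) that targets at most f false discoveries, where
pi_hat is the (estimated) proportion of non-differential biomarkers
(conservative fallback pi_hat = 1).

Reported quantities: FP_hat = n * pi_hat * alpha (estimated false
positives), TP_hat (number selected), FDR_hat = FP_hat / TP_hat, and —
when truth labels are available, e.g. in simulations — the realized FP,
FDR = FP / TP_hat and PSR (correctly selected / truly differential).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import ValidationError
from .decision import DecisionResult

logger = logging.getLogger(__name__)


def bonferroni_alpha(alpha_star: float, n: int) -> float:
    """Per-biomarker level alpha*/n for familywise control at alpha*."""
    if not 0 < alpha_star <= 1:
        raise ValidationError(f"alpha_star must be in (0, 1], got {alpha_star}")
    if n < 1:
        raise ValidationError(f"need n >= 1, got {n}")
    return alpha_star / n


def fp_controlled_alpha(f: float, n: int, pi_hat: float = 1.0) -> float:
    """Level alpha = f / (n * pi_hat) targeting <= f expected false positives.

    pi_hat defaults to 1, which is conservative. The result is clamped
    into (0, 1]; clamping to 1 (when f > n * pi_hat) logs a warning.
    """
    if f <= 0:
        raise ValidationError(f"need f > 0, got {f}")
    if n < 1:
        raise ValidationError(f"need n >= 1, got {n}")
    if not 0 < pi_hat <= 1:
        raise ValidationError(f"pi_hat must be in (0, 1], got {pi_hat}")
    alpha = f / (n * pi_hat)
    if alpha > 1:
        logger.warning(
            "target of f=%g false positives exceeds n*pi_hat=%g; alpha clamped to 1",
            f,
            n * pi_hat,
        )
        alpha = 1.0
    return alpha


def estimate_pi_hat(t_agg: np.ndarray, null_agg: np.ndarray) -> float:
    """Plug-in estimate of the non-differential proportion pi.

    Doubles the fraction of observed aggregated statistics lying below
    the null median (differential biomarkers concentrate above it),
    clamped into (0, 1]. This is a heuristic convenience — by default
    all levels use the conservative pi_hat = 1, and simulation studies
    pass the known pi explicitly.
    """
    t_agg = np.asarray(t_agg, dtype=float)
    if t_agg.size == 0:
        raise ValidationError("empty statistic vector")
    med = float(np.median(null_agg))
    pi = 2.0 * float(np.mean(t_agg < med))
    return min(max(pi, 1.0 / t_agg.size), 1.0)


@dataclass
class ErrorReport:
    """Estimated and (when truth is known) realized selection errors."""

    n: int
    alpha: float
    pi_hat: float
    TP_hat: int  # number selected
    FP_hat: float  # n * pi_hat * alpha
    FDR_hat: float  # FP_hat / TP_hat, capped at 1; 0 when nothing selected
    # realized quantities, None without truth labels
    FP: Optional[int] = None
    FDR: Optional[float] = None
    PSR: Optional[float] = None
    n_de: Optional[int] = None
    alpha_star: Optional[float] = None
    f: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def error_report(
    result: DecisionResult,
    truth: Optional[np.ndarray] = None,
    pi_hat: float = 1.0,
    alpha_star: Optional[float] = None,
    f: Optional[float] = None,
) -> ErrorReport:
    """Summarize selection errors for one decision.

    Parameters
    ----------
    result : DecisionResult
    truth : array-like of bool, optional
        Indicator of truly differential biomarkers; enables the realized
        FP / FDR / PSR fields. FDR is defined as 0 when nothing is
        selected; PSR is NaN when no biomarker is truly differential.
    pi_hat : float
        Estimated proportion of non-differential biomarkers used in
        FP_hat = n * pi_hat * alpha.
    """
    n = len(result.t_agg)
    tp_hat = result.n_selected
    fp_hat = n * pi_hat * result.alpha
    fdr_hat = min(fp_hat / tp_hat, 1.0) if tp_hat > 0 else 0.0
    report = ErrorReport(
        n=n,
        alpha=result.alpha,
        pi_hat=pi_hat,
        TP_hat=tp_hat,
        FP_hat=fp_hat,
        FDR_hat=fdr_hat,
        alpha_star=alpha_star,
        f=f,
    )
    if truth is not None:
        t = np.asarray(truth).astype(bool).ravel()
        if t.shape != (n,):
            raise ValidationError(
                f"truth has length {t.size}, expected {n}"
            )
        fp = int((result.selected_mask & ~t).sum())
        correct = int((result.selected_mask & t).sum())
        g = int(t.sum())
        report.FP = fp
        report.FDR = fp / tp_hat if tp_hat > 0 else 0.0
        report.PSR = correct / g if g > 0 else math.nan
        report.n_de = g
    return report
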