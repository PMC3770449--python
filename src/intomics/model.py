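"""Model / Results front end for the multi-platform integration test.

``MultiPlatformIntegration`` is constructed from the per-platform data
(or pandas DataFrames) and a test specification per platform; ``fit``
builds the simultaneous-permutation null, aggregates the statistics and
returns an :class:`IntegrationResults` carrying the per-biomarker
aggregated statistics, the empirical threshold, the selected set, scale
and covariance estimates, and error summaries.

Example
-------
>>> model = MultiPlatformIntegration.from_dataframes(
...     {"mrna": expr_df, "protein": prot_df}, groups=design_series)
>>> res = model.fit(alpha=0.05, B=100, seed=7)
>>> print(res.summary())
>>> res.to_frame().head()
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data import PlatformData, StatMatrix, ValidationError, check_shared_biomarkers
from .decision import DecisionResult, select
from .error_control import ErrorReport, bonferroni_alpha, error_report, fp_controlled_alpha
from .permutation import NullDistribution, build_null
from .stats import DEFAULT_CAP, TestSpec, compute_stat_matrix


class MultiPlatformIntegration:
    """Weighted-aggregation integration test across Q data platforms.

    Parameters
    ----------
    platforms : sequence of PlatformData
        Pre-aligned platforms: identical biomarker ids in identical
        order (an id mismatch is an error, not a silent join).
    specs : TestSpec or sequence of TestSpec, optional
        Statistic/side per platform; a single spec is broadcast.
        Defaults to a two-sided Welch t on every platform.
    cap : float
        Finite stand-in for infinite t statistics (degenerate variance).
    scale_basis : {"raw", "adjusted"}
        Whether null scales are estimated from signed or side-adjusted
        permuted statistics.
    """

    def __init__(
        self,
        platforms: Sequence[PlatformData],
        specs: Union[TestSpec, Sequence[TestSpec], None] = None,
        cap: float = DEFAULT_CAP,
        scale_basis: str = "raw",
    ) -> None:
        self.platforms = list(platforms)
        if specs is None:
            specs = TestSpec("student_t", "two")
        if isinstance(specs, TestSpec):
            specs = [specs] * len(self.platforms)
        self.specs = list(specs)
        if len(self.specs) != len(self.platforms):
            raise ValidationError(
                f"got {len(self.specs)} specs for {len(self.platforms)} platforms"
            )
        self.cap = cap
        self.scale_basis = scale_basis
        self.biomarker_ids = check_shared_biomarkers(self.platforms)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframes(
        cls,
        frames: Mapping[str, pd.DataFrame],
        groups: Union[Mapping[str, str], pd.Series],
        specs: Union[TestSpec, Sequence[TestSpec], None] = None,
        dtypes: Optional[Mapping[str, str]] = None,
        link_samples: bool = True,
        **kwargs,
    ) -> "MultiPlatformIntegration":
        """Build from biomarker x sample DataFrames.

        ``groups`` maps sample (column) names to "disease"/"control".
        When ``link_samples`` is true, column names double as subject
        ids, so identically named samples on different platforms are
        permuted simultaneously.
        """
        groups = dict(groups)
        dtypes = dict(dtypes or {})
        platforms = []
        for pid, df in frames.items():
            missing = [c for c in df.columns if c not in groups]
            if missing:
                raise ValidationError(
                    f"platform {pid!r}: samples without group assignment: "
                    f"{missing[:5]}"
                )
            platforms.append(
                PlatformData(
                    platform_id=pid,
                    values=df.to_numpy(dtype=float),
                    group=np.array([groups[c] for c in df.columns], dtype=object),
                    biomarker_ids=df.index.to_numpy(dtype=object),
                    subject_id=(
                        df.columns.to_numpy(dtype=object) if link_samples else None
                    ),
                    dtype=dtypes.get(pid, "continuous"),
                )
            )
        return cls(platforms, specs=specs, **kwargs)

    @property
    def n_biomarkers(self) -> int:
        return self.platforms[0].n_biomarkers

    @property
    def n_platforms(self) -> int:
        return len(self.platforms)

    # ------------------------------------------------------------------
    def fit(
        self,
        alpha: Optional[float] = 0.05,
        B: int = 100,
        method: str = "linear",
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        f: Optional[float] = None,
        pi_hat: float = 1.0,
        alpha_star: Optional[float] = None,
    ) -> "IntegrationResults":
        """Run the integration test.

        Exactly one multiplicity mode is active: a direct per-biomarker
        ``alpha``, an expected-false-positive target ``f`` (with
        ``pi_hat``), or a familywise ``alpha_star`` (Bonferroni).

        Parameters
        ----------
        B : int
            Number of permutation rounds for the empirical null.
        method : {"linear", "quadratic"}
            Weighted linear aggregation, or the Mahalanobis quadratic
            form (two-sided alternatives only).
        seed : int, optional
            Seed for the permutation generator; fits with the same seed
            are reproducible.
        """
        modes = sum(x is not None for x in (f, alpha_star))
        if modes > 1:
            raise ValidationError("choose one of alpha, f, or alpha_star")
        n = self.n_biomarkers
        if f is not None:
            eff_alpha = fp_controlled_alpha(f, n, pi_hat)
        elif alpha_star is not None:
            eff_alpha = bonferroni_alpha(alpha_star, n)
        else:
            if alpha is None:
                raise ValidationError("no significance level supplied")
            eff_alpha = alpha
        observed = compute_stat_matrix(self.platforms, self.specs, cap=self.cap)
        null = build_null(
            self.platforms,
            self.specs,
            B=B,
            rng=rng,
            seed=seed,
            cap=self.cap,
            scale_basis=self.scale_basis,
        )
        decision = select(observed, null, alpha=eff_alpha, method=method)
        return IntegrationResults(
            model=self,
            observed=observed,
            null=null,
            decision=decision,
            pi_hat=pi_hat,
            f=f,
            alpha_star=alpha_star,
            seed=seed,
        )


class IntegrationResults:
    """Fitted results: aggregated statistics, threshold and selection."""

    def __init__(
        self,
        model: MultiPlatformIntegration,
        observed: StatMatrix,
        null: NullDistribution,
        decision: DecisionResult,
        pi_hat: float = 1.0,
        f: Optional[float] = None,
        alpha_star: Optional[float] = None,
        seed: Optional[int] = None,
    ) -> None:
        self.model = model
        self.observed = observed
        self.null = null
        self.decision = decision
        self.pi_hat = pi_hat
        self.f = f
        self.alpha_star = alpha_star
        self.seed = seed

    # -- pass-throughs --------------------------------------------------
    @property
    def t_agg(self) -> np.ndarray:
        return self.decision.t_agg

    @property
    def C_alpha(self) -> float:
        return self.decision.C_alpha

    @property
    def alpha(self) -> float:
        return self.decision.alpha

    @property
    def selected(self) -> np.ndarray:
        return self.decision.selected

    @property
    def selected_mask(self) -> np.ndarray:
        return self.decision.selected_mask

    @property
    def sigma_hat(self) -> np.ndarray:
        return self.null.sigma_hat

    @property
    def cov_hat(self) -> np.ndarray:
        return self.null.cov_hat

    @property
    def corr_hat(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.null.cov_hat))
        return self.null.cov_hat / np.outer(s, s)

    @property
    def decision_line(self):
        return self.decision.decision_line

    # ------------------------------------------------------------------
    def error_report(
        self, truth: Optional[np.ndarray] = None, pi_hat: Optional[float] = None
    ) -> ErrorReport:
        return error_report(
            self.decision,
            truth=truth,
            pi_hat=self.pi_hat if pi_hat is None else pi_hat,
            alpha_star=self.alpha_star,
            f=self.f,
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-biomarker table: platform statistics, t_agg, selected flag."""
        data = {"biomarker_id": self.observed.biomarker_ids}
        for q, pid in enumerate(self.observed.platform_ids):
            data[f"t_{pid}"] = self.observed.stats[:, q]
        data["t_agg"] = self.t_agg
        data["selected"] = self.selected_mask.astype(int)
        return pd.DataFrame(data)

    def summary(self, truth: Optional[np.ndarray] = None) -> str:
        """Plain-text summary table of the fit."""
        rep = self.error_report(truth=truth)
        lines = [
            "Multi-Platform Integration Results",
            "=" * 50,
            f"{'No. biomarkers:':<28}{rep.n}",
            f"{'No. platforms:':<28}{self.model.n_platforms}",
            f"{'Permutations (B):':<28}{self.null.B}",
            f"{'Method:':<28}{self.decision.method}",
            f"{'Alpha (per biomarker):':<28}{rep.alpha:.6g}",
            f"{'Threshold C_alpha:':<28}{self.C_alpha:.6g}",
            f"{'No. selected (TP_hat):':<28}{rep.TP_hat}",
            f"{'Est. false pos. (FP_hat):':<28}{rep.FP_hat:.4g}",
            f"{'Est. FDR (FDR_hat):':<28}{rep.FDR_hat:.4g}",
            "-" * 50,
        ]
        for q, pid in enumerate(self.null.platform_ids):
            spec = self.model.specs[q]
            lines.append(
                f"  {pid:<16} {spec.statistic:<10} {spec.side:<6} "
                f"sigma_hat={self.sigma_hat[q]:.4f}"
            )
        if self.model.n_platforms > 1:
            off = self.corr_hat[np.triu_indices(self.model.n_platforms, 1)]
            lines.append(f"{'Null statistic corr.:':<28}" +
                         ", ".join(f"{c:.4f}" for c in off))
        if rep.PSR is not None:
            lines.append("-" * 50)
            lines.append(f"{'Realized FP / FDR / PSR:':<28}"
                         f"{rep.FP} / {rep.FDR:.4f} / {rep.PSR:.4f}")
        lines.append("=" * 50)
        return "\n".join(lines)

    def save(self, outdir: Union[str, Path]) -> None:
        """Write decisions.tsv and summary.json (with decision line) to outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "decisions.tsv", sep="\t", index=False)
        rep = self.error_report()
        payload = {
            "n_biomarkers": rep.n,
            "n_platforms": self.model.n_platforms,
            "B": self.null.B,
            "seed": self.seed,
            "method": self.decision.method,
            "alpha": rep.alpha,
            "C_alpha": self.C_alpha,
            "sigma_hat": [float(s) for s in self.sigma_hat],
            "cov_hat": [[float(v) for v in row] for row in self.cov_hat],
            "n_selected": rep.TP_hat,
            "FP_hat": rep.FP_hat,
            "FDR_hat": rep.FDR_hat,
            "decision_line": (
                list(self.decision_line) if self.decision_line else None
            ),
        }
        (outdir / "summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    def plot_decision(self, ax=None, truth: Optional[np.ndarray] = None):
        """Scatter of (t_1, t_2) with the linear decision line (Q=2 only)."""
        if self.model.n_platforms != 2 or self.decision.method != "linear":
            raise ValidationError(
                "decision-line plot is defined for the Q=2 linear method"
            )
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.observed.stats
        if truth is not None:
            t = np.asarray(truth).astype(bool)
            ax.plot(s[~t, 0], s[~t, 1], "o", ms=3, alpha=0.5, label="non-DE")
            ax.plot(s[t, 0], s[t, 1], "^", ms=4, alpha=0.7, label="DE")
            ax.legend()
        else:
            ax.plot(s[:, 0], s[:, 1], "o", ms=3, alpha=0.5)
        w1, w2, c = self.decision_line
        xs = np.array(ax.get_xlim())
        ax.plot(xs, (c - w1 * xs) / w2, "--", color="k")
        ax.set_xlabel(f"t ({self.observed.platform_ids[0]})")
        ax.set_ylabel(f"t ({self.observed.platform_ids[1]})")
        return ax
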