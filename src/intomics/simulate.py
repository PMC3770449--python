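"""Synthetic multi-platform data generator and evaluation harness.

The generator emulates two-group differential-expression experiments on
Q platforms. Continuous platforms draw each biomarker's 2m measurements
from a multivariate normal with unit variances and exchangeable
correlation ``rho_within`` (Sigma = (1-rho) I + rho J), control mean 0
and disease mean e; count platforms draw independent Poisson counts with
control mean lambda and disease mean lambda + e. The differential
biomarkers occupy the first g1 + g2 indices, split into two subgroups
with their own effect sizes per platform. Optionally, matched samples on
different continuous platforms share a Gaussian exchangeable coupling
``rho_across`` (disease and control groups stay independent), in which
case the platforms are linked for simultaneous permutation.

``run_scenario`` repeats simulate -> permutation null -> selection over
many replicate datasets and summarizes positive selection rate (PSR) and
realized false discovery rate (FDR) for the integrated method and for
each single-platform analysis run through the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import PlatformData, ValidationError
from .decision import select
from .error_control import error_report
from .permutation import build_null
from .stats import TestSpec, compute_stat_matrix


@dataclass(frozen=True)
class PlatformScenario:
    """Generative settings for one platform.

    ``effects`` are the mean shifts (disease minus control) for the two
    differential subgroups; a scalar applies to both. ``side`` defaults
    to the orientation implied by the effect signs (all positive ->
    right, all negative -> left, mixed -> two).
    """

    dtype: str = "continuous"
    effects: Tuple[float, float] = (0.0, 0.0)
    side: Optional[str] = None
    statistic: str = "student_t"
    count_base: float = 5.0

    def effect_vector(self, n: int, g1: int, g2: int) -> np.ndarray:
        e = np.zeros(n)
        e[:g1] = self.effects[0]
        e[g1 : g1 + g2] = self.effects[1]
        return e

    def resolved_side(self) -> str:
        if self.side is not None:
            return self.side
        e = np.asarray(self.effects, dtype=float)
        if (e >= 0).all() and (e > 0).any():
            return "right"
        if (e <= 0).all() and (e < 0).any():
            return "left"
        return "two"

    def test_spec(self) -> TestSpec:
        return TestSpec(self.statistic, self.resolved_side())


@dataclass
class SimulationScenario:
    """Full generative description of one simulation setting."""

    name: str
    platforms: List[PlatformScenario]
    n: int = 1000
    g1: int = 100
    g2: int = 100
    m: int = 5  # samples per group per platform
    rho_within: float = 0.0
    rho_across: float = 0.0
    reps: int = 100
    B: int = 100
    alpha: float = 0.05
    method: str = "linear"  # aggregation for the multi-platform analysis
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.g1 + self.g2 > self.n:
            raise ValidationError("g1 + g2 must not exceed n")
        for r in (self.rho_within, self.rho_across):
            if not 0 <= r < 1:
                raise ValidationError(f"correlations must lie in [0, 1), got {r}")
        if self.rho_within + self.rho_across >= 1:
            raise ValidationError("rho_within + rho_across must be < 1")
        # normalize scalar effects
        self.platforms = [
            replace(p, effects=tuple(np.broadcast_to(p.effects, (2,)).tolist()))
            for p in self.platforms
        ]

    @property
    def n_de(self) -> int:
        return self.g1 + self.g2

    def test_specs(self) -> List[TestSpec]:
        return [p.test_spec() for p in self.platforms]

    def truth(self) -> np.ndarray:
        t = np.zeros(self.n, dtype=bool)
        t[: self.n_de] = True
        return t


def simulate_dataset(
    scenario: SimulationScenario, rng: np.random.Generator
) -> Tuple[List[PlatformData], np.ndarray]:
    """Draw one replicate dataset: list of PlatformData plus truth vector.

    Sample columns 0..m-1 are control, m..2m-1 disease on every
    platform. When ``rho_across`` > 0, continuous platforms share
    subject ids so they are permuted simultaneously downstream.
    """
    n, m = scenario.n, scenario.m
    s_tot = 2 * m
    rw, ra = scenario.rho_within, scenario.rho_across
    group = np.array(["control"] * m + ["disease"] * m, dtype=object)
    shared_subjects = (
        np.array([f"subj{j}" for j in range(s_tot)], dtype=object)
        if ra > 0
        else None
    )
    # latent factor shared by matched samples across continuous platforms
    W = rng.standard_normal((n, s_tot)) if ra > 0 else None
    platforms: List[PlatformData] = []
    for q, ps in enumerate(scenario.platforms):
        e = ps.effect_vector(n, scenario.g1, scenario.g2)
        if ps.dtype == "continuous":
            Z = np.sqrt(max(1.0 - rw - ra, 0.0)) * rng.standard_normal((n, s_tot))
            if rw > 0:
                Z += np.sqrt(rw) * rng.standard_normal((n, 1))
            if ra > 0:
                Z += np.sqrt(ra) * W
            Z[:, m:] += e[:, None]
            values = Z
        elif ps.dtype == "count":
            lam = np.empty((n, s_tot))
            lam[:, :m] = ps.count_base
            lam[:, m:] = ps.count_base + e[:, None]
            if (lam < 0).any():
                raise ValidationError(
                    f"platform {q + 1}: Poisson mean lambda + e is negative"
                )
            values = rng.poisson(lam).astype(float)
        else:
            raise ValidationError(f"unknown platform dtype {ps.dtype!r}")
        platforms.append(
            PlatformData(
                platform_id=f"p{q + 1}",
                values=values,
                group=group,
                subject_id=shared_subjects,
                dtype=ps.dtype,
            )
        )
    return platforms, scenario.truth()


@dataclass
class EvaluationSummary:
    """Replicate-averaged PSR/FDR per analysis method.

    ``methods`` maps "multi" and each platform id to a dict with keys
    psr_mean, psr_var, fdr_mean, fdr_var, fp_mean, tp_hat_mean.
    """

    scenario: str
    reps: int
    alpha: float
    method: str
    methods: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.methods)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "metric"
        frame.to_csv(path, sep="\t")


def _metrics(decision, truth, pi_hat: float = 1.0) -> Dict[str, float]:
    rep = error_report(decision, truth=truth, pi_hat=pi_hat)
    return {
        "psr": rep.PSR,
        "fdr": rep.FDR,
        "fp": rep.FP,
        "tp_hat": rep.TP_hat,
    }


def run_scenario(
    scenario: SimulationScenario,
    rng: Optional[np.random.Generator] = None,
    reps: Optional[int] = None,
    B: Optional[int] = None,
    alpha: Optional[float] = None,
) -> EvaluationSummary:
    """Run the full pipeline over replicate datasets and summarize.

    Each replicate simulates a dataset, builds one pooled permutation
    null for all platforms jointly, then performs the multi-platform
    selection plus each single-platform selection (the same machinery
    restricted to one statistic column, sharing the permutations).
    """
    reps = scenario.reps if reps is None else reps
    B = scenario.B if B is None else B
    alpha = scenario.alpha if alpha is None else alpha
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    specs = scenario.test_specs()
    keys = ["multi"] + [f"p{q + 1}" for q in range(len(scenario.platforms))]
    acc: Dict[str, Dict[str, List[float]]] = {
        k: {"psr": [], "fdr": [], "fp": [], "tp_hat": []} for k in keys
    }
    for _ in range(reps):
        platforms, truth = simulate_dataset(scenario, rng)
        observed = compute_stat_matrix(platforms, specs)
        null = build_null(platforms, specs, B=B, rng=rng)
        multi = select(observed, null, alpha=alpha, method=scenario.method)
        for k, v in _metrics(multi, truth).items():
            acc["multi"][k].append(v)
        for q in range(len(platforms)):
            single = select(
                observed.column(q), null.column(q), alpha=alpha, method="linear"
            )
            for k, v in _metrics(single, truth).items():
                acc[f"p{q + 1}"][k].append(v)
    summary = EvaluationSummary(
        scenario=scenario.name, reps=reps, alpha=alpha, method=scenario.method
    )
    for key, vals in acc.items():
        psr = np.asarray(vals["psr"], dtype=float)
        fdr = np.asarray(vals["fdr"], dtype=float)
        summary.methods[key] = {
            "psr_mean": float(np.mean(psr)),
            "psr_var": float(np.var(psr, ddof=1)) if reps > 1 else 0.0,
            "fdr_mean": float(np.mean(fdr)),
            "fdr_var": float(np.var(fdr, ddof=1)) if reps > 1 else 0.0,
            "fp_mean": float(np.mean(vals["fp"])),
            "tp_hat_mean": float(np.mean(vals["tp_hat"])),
        }
    return summary


# ---------------------------------------------------------------------------
# Named scenario catalog (the benchmark settings)
# ---------------------------------------------------------------------------

def _two_platform(name: str, e1, e2, rho: float, **kw) -> SimulationScenario:
    return SimulationScenario(
        name=name,
        platforms=[
            PlatformScenario(effects=tuple(e1)),
            PlatformScenario(effects=tuple(e2)),
        ],
        rho_within=rho,
        **kw,
    )


_FIVE_PLATFORM_EFFECTS = [
    (1.5, 1.5),
    (1.5, 1.0),
    (-0.5, -2.0),
    (-1.0, 1.5),
    (2.0, -1.0),
]


def scenario_catalog() -> Dict[str, SimulationScenario]:
    """Ready-to-run benchmark scenarios (n=1000, g1=g2=100, 5+5 samples,
    B=100, alpha=0.05 unless noted).

    Sides are inferred from the signs of the per-subgroup effects:
    all-positive platforms test right-sided, all-negative left-sided,
    mixed-sign two-sided.
    """
    cat: Dict[str, SimulationScenario] = {}
    s1 = dict(rho=0.0)
    s2 = dict(rho=0.5)
    cat["table1_s1_right"] = _two_platform(
        "table1_s1_right", (0.5, 2.0), (1.5, 1.0), **s1
    )
    cat["table1_s1_left"] = _two_platform(
        "table1_s1_left", (-0.5, -2.0), (-1.5, -1.0), **s1
    )
    cat["table1_s1_two"] = _two_platform(
        "table1_s1_two", (-1.0, 1.5), (2.0, -1.0), **s1
    )
    cat["table1_s2_right"] = _two_platform(
        "table1_s2_right", (0.5, 2.0), (1.5, 1.0), **s2
    )
    cat["table1_s2_left"] = _two_platform(
        "table1_s2_left", (-0.5, -2.0), (-1.5, -1.0), **s2
    )
    cat["table1_s2_two"] = _two_platform(
        "table1_s2_two", (-1.0, 1.5), (2.0, -1.0), **s2
    )
    for key, rho in (("table2_s1", 0.0), ("table2_s2", 0.5)):
        cat[key] = SimulationScenario(
            name=key,
            platforms=[
                PlatformScenario(effects=e) for e in _FIVE_PLATFORM_EFFECTS
            ],
            rho_within=rho,
        )
    cat["table3_mixed"] = SimulationScenario(
        name="table3_mixed",
        platforms=[
            PlatformScenario(effects=(0.5, 2.0)),
            PlatformScenario(
                dtype="count", effects=(3.0, 3.0), count_base=5.0, side="right"
            ),
        ],
        rho_within=0.0,
    )
    # expected-false-positive control study: scenario 2 left-sided at
    # alpha = f/(n*pi) = 4/(1000*0.8) = 0.005
    cat["table4_fp"] = _two_platform(
        "table4_fp", (-0.5, -2.0), (-1.5, -1.0), rho=0.5, alpha=0.005
    )
    cat["table6_small"] = _two_platform(
        "table6_small", (0.5, 2.0), (1.5, 1.0), rho=0.0, m=2
    )
    cat["table6_xplat"] = _two_platform(
        "table6_xplat", (0.5, 2.0), (1.5, 1.0), rho=0.0, rho_across=0.5
    )
    unstd = _two_platform("table6_unstd", (0.5, 2.0), (1.5, 1.0), rho=0.0)
    unstd.platforms = [
        replace(p, statistic="mean_diff") for p in unstd.platforms
    ]
    cat["table6_unstd"] = unstd
    cat["table7_quadratic"] = _two_platform(
        "table7_quadratic", (-1.0, 1.5), (2.0, -1.0), rho=0.5, method="quadratic"
    )
    return cat
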