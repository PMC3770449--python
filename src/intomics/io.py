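"""Reading platform matrices and designs; writing run outputs.

Matrices are TSV with a header row of sample ids and a first column of
biomarker ids. The design file is TSV with columns ``sample_id``,
``group`` (disease/control) and optionally ``subject_id`` for
cross-platform sample linkage. Missing values are an error: impute
upstream before integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import GROUP_LABELS, PlatformData, ValidationError
from .error_control import ErrorReport
from .model import IntegrationResults, MultiPlatformIntegration
from .stats import TestSpec

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_design(design_path: PathLike) -> pd.DataFrame:
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(design.columns)
    if missing:
        raise ValidationError(
            f"design file {design_path} lacks column(s) {sorted(missing)}"
        )
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id {dup!r} in design")
    bad = set(design["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(
            f"unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}"
        )
    return design.set_index("sample_id")


def read_platform(
    matrix_path: PathLike,
    design_path: PathLike,
    dtype: str = "continuous",
    platform_id: Optional[str] = None,
) -> PlatformData:
    """Load one platform matrix plus its design into a PlatformData."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.columns.duplicated().any():
        raise ValidationError(f"duplicate sample ids in {matrix_path}")
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate biomarker ids in {matrix_path}")
    if df.isna().any().any():
        raise ValidationError(
            f"{matrix_path} contains missing values; impute upstream "
            "(e.g. with MICE) before integration"
        )
    design = read_design(design_path)
    unknown = [c for c in df.columns if c not in design.index]
    if unknown:
        raise ValidationError(
            f"samples {unknown[:5]} in {matrix_path} absent from design"
        )
    sub = design.loc[list(df.columns)]
    subject_id = (
        sub["subject_id"].to_numpy(dtype=object)
        if "subject_id" in sub.columns
        else None
    )
    return PlatformData(
        platform_id=platform_id or Path(matrix_path).stem,
        values=df.to_numpy(dtype=float),
        group=sub["group"].to_numpy(dtype=object),
        biomarker_ids=df.index.to_numpy(dtype=object),
        subject_id=subject_id,
        dtype=dtype,
    )


def write_platform(
    platform: PlatformData, matrix_path: PathLike, design_path: PathLike
) -> None:
    """Write a platform back out as matrix + design TSVs (round-trippable)."""
    samples = (
        [str(s) for s in platform.subject_id]
        if platform.subject_id is not None
        else [f"s{j + 1}" for j in range(platform.n_samples)]
    )
    pd.DataFrame(
        platform.values, index=platform.biomarker_ids, columns=samples
    ).to_csv(matrix_path, sep="\t", float_format="%.17g")
    design = pd.DataFrame(
        {"sample_id": samples, "group": platform.group}
    )
    if platform.subject_id is not None:
        design["subject_id"] = platform.subject_id
    design.to_csv(design_path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Configuration of one `integrate` run. Exactly one of alpha, f, or
    alpha_star selects the multiplicity mode."""

    platforms: List[Tuple[str, str]]  # (matrix path, dtype)
    design: str
    statistic: str = "student_t"
    side: str = "two"
    alpha: Optional[float] = 0.05
    f: Optional[float] = None
    pi_hat: float = 1.0
    alpha_star: Optional[float] = None
    B: int = 100
    seed: Optional[int] = None
    method: str = "linear"
    outdir: str = "results"

    def __post_init__(self) -> None:
        if sum(x is not None for x in (self.f, self.alpha_star)) > 1:
            raise ValidationError("choose one of alpha, f, or alpha_star")
        for p, _ in self.platforms:
            if not Path(p).exists():
                raise ValidationError(f"platform file not found: {p}")
        if not Path(self.design).exists():
            raise ValidationError(f"design file not found: {self.design}")

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["platforms"] = [tuple(p) for p in raw["platforms"]]
        return cls(**raw)


def run_integrate(config: RunConfig) -> Tuple[IntegrationResults, ErrorReport]:
    """Load platforms, fit the integration model, write outputs.

    Writes ``decisions.tsv`` and ``summary.json`` under ``config.outdir``
    and returns the results and error report. Deterministic given seed.
    """
    platforms = [
        read_platform(path, config.design, dtype=dt) for path, dt in config.platforms
    ]
    spec = TestSpec(config.statistic, config.side)
    model = MultiPlatformIntegration(platforms, specs=spec)
    res = model.fit(
        alpha=config.alpha,
        f=config.f,
        pi_hat=config.pi_hat,
        alpha_star=config.alpha_star,
        B=config.B,
        method=config.method,
        seed=config.seed,
    )
    rep = res.error_report()
    logger.info(
        "n=%d Q=%d B=%d alpha=%.6g sigma_hat=%s C_alpha=%.6g selected=%d",
        rep.n,
        model.n_platforms,
        config.B,
        rep.alpha,
        np.array2string(res.sigma_hat, precision=4),
        res.C_alpha,
        rep.TP_hat,
    )
    res.save(config.outdir)
    return res, rep
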