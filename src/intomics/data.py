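"""Containers for per-platform measurements and per-biomarker statistics.

A :class:`PlatformData` holds one platform's biomarker-by-sample matrix
together with the disease/control assignment of each sample column and an
optional subject linkage key. Subjects sharing a ``subject_id`` across
platforms are treated as the same biological sample and receive a common
relabeling during permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

DISEASE = "disease"
CONTROL = "control"
GROUP_LABELS = (DISEASE, CONTROL)

DTYPES = ("continuous", "count")


class ValidationError(ValueError):
    """Raised when input data violate the container invariants."""


def _default_biomarker_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"bm{i:0{width}d}" for i in range(1, n + 1)])


@dataclass
class PlatformData:
    """One platform's biomarker x sample measurement matrix.

    Parameters
    ----------
    platform_id : str
        Label for the platform (e.g. ``"mrna"`` or ``"protein"``).
    values : ndarray, shape (n_biomarkers, n_samples)
        Measurements; continuous reals or non-negative integer counts.
    group : sequence of str
        Per-sample-column label, each ``"disease"`` or ``"control"``.
        At least two samples per group are required.
    biomarker_ids : sequence of str, optional
        Row labels; generated if omitted.
    subject_id : sequence, optional
        Per-sample linkage key. Samples carrying the same key on
        different platforms are permuted simultaneously.
    dtype : {"continuous", "count"}
        Count platforms are validated to hold non-negative integers.
    """

    platform_id: str
    values: np.ndarray
    group: np.ndarray
    biomarker_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: Optional[np.ndarray] = None
    dtype: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"{self.platform_id}: values must be 2-D "
                f"(biomarkers x samples), got ndim={self.values.ndim}"
            )
        if self.values.shape[0] < 1:
            raise ValidationError(f"{self.platform_id}: need at least one biomarker")
        if not np.isfinite(self.values).all():
            raise ValidationError(
                f"{self.platform_id}: missing or non-finite values present; "
                "impute upstream before integration"
            )
        self.group = np.asarray(self.group, dtype=object)
        if self.group.shape != (self.values.shape[1],):
            raise ValidationError(
                f"{self.platform_id}: group has length {self.group.shape}, "
                f"expected {self.values.shape[1]} (one label per sample column)"
            )
        bad = set(self.group) - set(GROUP_LABELS)
        if bad:
            raise ValidationError(
                f"{self.platform_id}: unknown group label(s) {sorted(bad)}; "
                f"expected one of {GROUP_LABELS}"
            )
        if self.n_disease < 2 or self.n_control < 2:
            raise ValidationError(
                f"{self.platform_id}: need >= 2 samples per group, got "
                f"{self.n_disease} disease / {self.n_control} control"
            )
        if self.biomarker_ids is None:
            self.biomarker_ids = _default_biomarker_ids(self.n_biomarkers)
        self.biomarker_ids = np.asarray(self.biomarker_ids, dtype=object)
        if self.biomarker_ids.shape != (self.n_biomarkers,):
            raise ValidationError(
                f"{self.platform_id}: biomarker_ids length mismatch"
            )
        if self.subject_id is not None:
            self.subject_id = np.asarray(self.subject_id, dtype=object)
            if self.subject_id.shape != (self.n_samples,):
                raise ValidationError(
                    f"{self.platform_id}: subject_id length mismatch"
                )
            if len(set(self.subject_id)) != self.n_samples:
                raise ValidationError(
                    f"{self.platform_id}: subject_id values must be unique "
                    "within a platform"
                )
        if self.dtype not in DTYPES:
            raise ValidationError(
                f"{self.platform_id}: dtype must be one of {DTYPES}"
            )
        if self.dtype == "count":
            if (self.values < 0).any() or (self.values % 1 != 0).any():
                raise ValidationError(
                    f"{self.platform_id}: count platform requires "
                    "non-negative integer values"
                )

    # -- convenience views ------------------------------------------------
    @property
    def n_biomarkers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def disease_mask(self) -> np.ndarray:
        return self.group == DISEASE

    @property
    def n_disease(self) -> int:
        return int(np.sum(self.group == DISEASE))

    @property
    def n_control(self) -> int:
        return int(np.sum(self.group == CONTROL))

    def with_group(self, group: Sequence[str]) -> "PlatformData":
        """Return a copy sharing ``values`` but with new group labels."""
        return replace(self, group=np.asarray(group, dtype=object))


@dataclass
class StatMatrix:
    """Observed per-biomarker statistics across Q platforms.

    ``stats`` holds the side-adjusted statistics (larger positive values
    support the alternative); ``raw`` keeps the signed disease-minus-control
    statistics, which the quadratic aggregation consumes.
    """

    stats: np.ndarray  # (n, Q) side-adjusted
    raw: np.ndarray  # (n, Q) signed
    platform_ids: np.ndarray
    biomarker_ids: np.ndarray

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.stats.shape != self.raw.shape or self.stats.ndim != 2:
            raise ValidationError("StatMatrix: stats/raw shape mismatch")
        if not np.isfinite(self.stats).all():
            raise ValidationError("StatMatrix: non-finite statistic")
        self.platform_ids = np.asarray(self.platform_ids, dtype=object)
        self.biomarker_ids = np.asarray(self.biomarker_ids, dtype=object)
        n, q = self.stats.shape
        if self.platform_ids.shape != (q,) or self.biomarker_ids.shape != (n,):
            raise ValidationError("StatMatrix: label length mismatch")

    @property
    def n_biomarkers(self) -> int:
        return self.stats.shape[0]

    @property
    def n_platforms(self) -> int:
        return self.stats.shape[1]

    def column(self, q: int) -> "StatMatrix":
        """Single-platform view (used for individual-platform analyses)."""
        return StatMatrix(
            stats=self.stats[:, [q]],
            raw=self.raw[:, [q]],
            platform_ids=self.platform_ids[[q]],
            biomarker_ids=self.biomarker_ids,
        )


def check_shared_biomarkers(platforms: Sequence[PlatformData]) -> np.ndarray:
    """Verify all platforms carry identical biomarker ids in identical order.

    Returns the shared id vector; raises naming the first offending id
    otherwise. Pre-align platforms upstream — silent intersection is not
    performed.
    """
    if not platforms:
        raise ValidationError("no platforms supplied")
    ref = platforms[0].biomarker_ids
    for p in platforms[1:]:
        if p.n_biomarkers != len(ref):
            raise ValidationError(
                f"platform {p.platform_id!r} has {p.n_biomarkers} biomarkers, "
                f"expected {len(ref)}; pre-align platforms to a shared panel"
            )
        neq = ref != p.biomarker_ids
        if neq.any():
            i = int(np.argmax(neq))
            raise ValidationError(
                f"biomarker id mismatch at row {i}: "
                f"{ref[i]!r} (platform {platforms[0].platform_id!r}) vs "
                f"{p.biomarker_ids[i]!r} (platform {p.platform_id!r})"
            )
    return ref
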