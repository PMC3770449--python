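"""Simultaneous-permutation empirical null distribution.

Group labels are permuted as whole sample columns — one relabeling per
round applied to every biomarker at once — which preserves within-sample
dependence across biomarkers. Platforms linked through shared
``subject_id`` values receive one common relabeling per round, preserving
cross-platform dependence; unlinked platforms are permuted independently.
Each round recomputes the full n x Q statistic matrix, and the B·n
resulting Q-vectors are pooled across biomarkers (valid under
exchangeability of the within-platform covariance) to form the empirical
null. Per-platform scales sigma_hat and the cross-platform covariance
Sigma_hat are estimated from this pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .data import DISEASE, PlatformData, ValidationError, check_shared_biomarkers
from .stats import DEFAULT_CAP, TestSpec, raw_stat_block, side_adjust


@dataclass
class NullDistribution:
    """Pooled permutation null of the Q-vector of platform statistics.

    Attributes
    ----------
    pooled : ndarray, shape (B*n, Q)
        Side-adjusted permuted statistics; row b*n + i is biomarker i
        under permutation round b.
    pooled_raw : ndarray, shape (B*n, Q)
        The signed (pre-side-adjustment) values of the same rows.
    sigma_hat : ndarray, shape (Q,)
        Per-platform scale: sample sd of the scale-basis values.
    cov_hat : ndarray, shape (Q, Q)
        Sample covariance of the scale-basis Q-vectors.
    B : int
        Number of permutation rounds.
    seed : int or None
        Seed used to build the generator, when one was supplied.
    scale_basis : {"raw", "adjusted"}
        Whether sigma_hat / cov_hat are computed from the signed
        statistics (default) or the side-adjusted ones.
    """

    pooled: np.ndarray
    pooled_raw: np.ndarray
    sigma_hat: np.ndarray
    cov_hat: np.ndarray
    B: int
    seed: Optional[int]
    scale_basis: str
    platform_ids: np.ndarray

    @property
    def n_platforms(self) -> int:
        return self.pooled.shape[1]

    def column(self, q: int) -> "NullDistribution":
        """Single-platform view, for individual-platform analyses."""
        return NullDistribution(
            pooled=self.pooled[:, [q]],
            pooled_raw=self.pooled_raw[:, [q]],
            sigma_hat=self.sigma_hat[[q]],
            cov_hat=self.cov_hat[[q]][:, [q]],
            B=self.B,
            seed=self.seed,
            scale_basis=self.scale_basis,
            platform_ids=self.platform_ids[[q]],
        )


# ---------------------------------------------------------------------------
# Linkage and label permutation
# ---------------------------------------------------------------------------

def linkage_components(platforms: Sequence[PlatformData]) -> List[List[int]]:
    """Partition platform indices into simultaneous-permutation components.

    Platforms sharing any subject_id are linked and must carry the same
    subject set with consistent group labels; platforms without
    subject_id (or with disjoint subject sets) form their own components.
    """
    n = len(platforms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    subject_sets = [
        set(p.subject_id) if p.subject_id is not None else None for p in platforms
    ]
    for i in range(n):
        if subject_sets[i] is None:
            continue
        for j in range(i + 1, n):
            if subject_sets[j] is None:
                continue
            if subject_sets[i] & subject_sets[j]:
                parent[find(i)] = find(j)
    groups: dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    comps = sorted(groups.values(), key=lambda idx: idx[0])
    # validate each linked component
    for comp in comps:
        if len(comp) == 1:
            continue
        ref = platforms[comp[0]]
        ref_set = subject_sets[comp[0]]
        label_of = dict(zip(ref.subject_id, ref.group))
        for j in comp[1:]:
            p = platforms[j]
            if subject_sets[j] != ref_set:
                raise ValidationError(
                    f"platforms {ref.platform_id!r} and {p.platform_id!r} share "
                    "some but not all subject ids; linked platforms must "
                    "measure the same subject set"
                )
            for sid, lab in zip(p.subject_id, p.group):
                if label_of[sid] != lab:
                    raise ValidationError(
                        f"subject {sid!r} is labeled {label_of[sid]!r} on "
                        f"platform {ref.platform_id!r} but {lab!r} on "
                        f"platform {p.platform_id!r}"
                    )
    return comps


def _draw_permuted_groups(
    platforms: Sequence[PlatformData],
    comps: Sequence[Sequence[int]],
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """One permutation round: a new group vector per platform.

    Uniform over balanced assignments (group sizes preserved exactly);
    one draw per linkage component, broadcast through subject ids.
    """
    out: List[Optional[np.ndarray]] = [None] * len(platforms)
    for comp in comps:
        lead = platforms[comp[0]]
        perm = rng.permutation(lead.n_samples)
        permuted = lead.group[perm]
        out[comp[0]] = permuted
        if len(comp) > 1:
            label_of = dict(zip(lead.subject_id, permuted))
            for j in comp[1:]:
                p = platforms[j]
                out[j] = np.array(
                    [label_of[sid] for sid in p.subject_id], dtype=object
                )
    return out  # type: ignore[return-value]


def permute_labels(
    platforms: Sequence[PlatformData], rng: np.random.Generator
) -> List[PlatformData]:
    """Simultaneously permute disease/control labels across platforms.

    Linked platforms (shared subject_id) get one common relabeling;
    unlinked platforms are permuted independently. Group sizes are
    preserved exactly and entire sample columns move as units.
    """
    comps = linkage_components(platforms)
    groups = _draw_permuted_groups(platforms, comps, rng)
    return [p.with_group(g) for p, g in zip(platforms, groups)]


# ---------------------------------------------------------------------------
# Null construction
# ---------------------------------------------------------------------------

def build_null(
    platforms: Sequence[PlatformData],
    specs: Sequence[TestSpec],
    B: int = 100,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    cap: float = DEFAULT_CAP,
    scale_basis: str = "raw",
) -> NullDistribution:
    """Build the pooled empirical null by B simultaneous permutations.

    For each round the full n x Q statistic matrix is recomputed on the
    permuted labels; all B·n Q-vectors are pooled. Rounds are independent
    uniform draws over balanced assignments (the identity is not
    excluded).

    Raises a degenerate-scale error if any platform's pooled statistics
    are constant (e.g. all-constant input data).
    """
    check_shared_biomarkers(platforms)
    if len(specs) != len(platforms):
        raise ValidationError(
            f"got {len(specs)} test specs for {len(platforms)} platforms"
        )
    if B < 1:
        raise ValidationError(f"need B >= 1 permutations, got {B}")
    if scale_basis not in ("raw", "adjusted"):
        raise ValidationError(f"unknown scale_basis {scale_basis!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    comps = linkage_components(platforms)
    n = platforms[0].n_biomarkers
    Q = len(platforms)

    # collect the B disease-indicator rows per platform, consuming the rng
    # in exactly the order permute_labels would
    indicators = [np.empty((B, p.n_samples)) for p in platforms]
    for b in range(B):
        groups = _draw_permuted_groups(platforms, comps, rng)
        for q, g in enumerate(groups):
            indicators[q][b] = g == DISEASE

    pooled_raw = np.empty((B * n, Q))
    pooled = np.empty((B * n, Q))
    for q, (p, spec) in enumerate(zip(platforms, specs)):
        ranks = rankdata(p.values, axis=1) if spec.statistic == "wilcoxon" else None
        raw = raw_stat_block(
            p.values,
            indicators[q],
            p.n_disease,
            p.n_control,
            spec.statistic,
            cap=cap,
            ranks=ranks,
        )  # (n, B)
        if not np.isfinite(raw).all():
            i, b = np.argwhere(~np.isfinite(raw))[0]
            raise ValidationError(
                f"non-finite permuted statistic for biomarker "
                f"{platforms[0].biomarker_ids[i]!r} on platform "
                f"{p.platform_id!r} (round {b})"
            )
        pooled_raw[:, q] = raw.T.ravel()  # row b*n + i
        pooled[:, q] = side_adjust(pooled_raw[:, q], spec.side)

    basis = pooled_raw if scale_basis == "raw" else pooled
    sigma_hat = basis.std(axis=0, ddof=1)
    if not (np.isfinite(sigma_hat).all() and (sigma_hat > 0).all()):
        q = int(np.argmin(sigma_hat))
        raise ValidationError(
            f"degenerate null scale on platform {platforms[q].platform_id!r}: "
            "permuted statistics are constant (is the platform all-constant?)"
        )
    cov_hat = np.atleast_2d(np.cov(basis, rowvar=False, ddof=1))
    return NullDistribution(
        pooled=pooled,
        pooled_raw=pooled_raw,
        sigma_hat=sigma_hat,
        cov_hat=cov_hat,
        B=B,
        seed=seed,
        scale_basis=scale_basis,
        platform_ids=np.array([p.platform_id for p in platforms], dtype=object),
    )
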