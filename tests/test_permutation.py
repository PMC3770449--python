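"""Simultaneous permutation and pooled-null construction."""

import itertools

import numpy as np
import pytest

from intomics.data import ValidationError
from intomics.permutation import build_null, linkage_components, permute_labels
from intomics.stats import TestSpec, compute_stat_matrix
from tests.conftest import make_platform


class TestPermuteLabels:
    def test_uniform_over_balanced_assignments(self, rng):
        """2+2 samples: each of the C(4,2)=6 assignments is equally likely."""
        p = make_platform(np.zeros((1, 4)) + np.arange(4))
        counts = {}
        n_draws = 6000
        for _ in range(n_draws):
            (perm,) = permute_labels([p], rng)
            key = tuple(np.flatnonzero(perm.disease_mask))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for k, c in counts.items():
            assert abs(c / n_draws - 1 / 6) < 0.03, k

    def test_group_sizes_preserved(self, rng):
        p = make_platform(rng.standard_normal((2, 7)),
                          group=["control"] * 3 + ["disease"] * 4)
        for _ in range(20):
            (perm,) = permute_labels([p], rng)
            assert perm.n_disease == 4 and perm.n_control == 3

    def test_linked_platforms_share_assignment(self, rng):
        subj = [f"s{i}" for i in range(6)]
        p1 = make_platform(rng.standard_normal((3, 6)), subject_id=subj)
        # platform 2 lists the same subjects in a different column order
        order = [3, 0, 5, 1, 4, 2]
        p2 = make_platform(
            rng.standard_normal((3, 6)),
            group=[p1.group[i] for i in order],
            subject_id=[subj[i] for i in order],
            platform_id="p2",
        )
        for _ in range(30):
            q1, q2 = permute_labels([p1, p2], rng)
            lab1 = dict(zip(q1.subject_id, q1.group))
            lab2 = dict(zip(q2.subject_id, q2.group))
            assert lab1 == lab2

    def test_unlinked_platforms_independent(self, rng):
        p1 = make_platform(np.zeros((1, 4)), platform_id="a")
        p2 = make_platform(np.zeros((1, 4)), platform_id="b")
        v1, v2 = [], []
        for _ in range(10000):
            q1, q2 = permute_labels([p1, p2], rng)
            v1.append(q1.disease_mask[0])
            v2.append(q2.disease_mask[0])
        corr = np.corrcoef(np.asarray(v1, float), np.asarray(v2, float))[0, 1]
        assert abs(corr) < 0.05

    def test_contradictory_linked_labels_error(self, rng):
        subj = ["s0", "s1", "s2", "s3"]
        p1 = make_platform(np.zeros((1, 4)),
                           group=["control", "control", "disease", "disease"],
                           subject_id=subj)
        p2 = make_platform(np.zeros((1, 4)),
                           group=["disease", "control", "disease", "control"],
                           subject_id=subj, platform_id="p2")
        with pytest.raises(ValidationError, match="labeled"):
            permute_labels([p1, p2], rng)

    def test_partial_subject_overlap_error(self, rng):
        p1 = make_platform(np.zeros((1, 4)), subject_id=["a", "b", "c", "d"])
        p2 = make_platform(np.zeros((1, 4)), subject_id=["c", "d", "e", "f"],
                           platform_id="p2")
        with pytest.raises(ValidationError, match="some but not all"):
            linkage_components([p1, p2])


class TestBuildNull:
    def test_matches_exhaustive_enumeration(self, rng):
        """2+2 mean_diff: pooled null frequencies match the 6-assignment
        enumeration (independent oracle by brute force)."""
        vals = np.array([[1.0, 2.0, 4.0, 8.0]])
        p = make_platform(vals)
        spec = TestSpec("mean_diff", "right")
        # oracle: enumerate balanced disease assignments
        expected = []
        for d_idx in itertools.combinations(range(4), 2):
            dm = np.zeros(4, bool)
            dm[list(d_idx)] = True
            expected.append(vals[0, dm].mean() - vals[0, ~dm].mean())
        exp_vals, exp_freq = np.unique(np.round(expected, 9), return_counts=True)
        exp_freq = exp_freq / exp_freq.sum()

        null = build_null([p], [spec], B=6000, rng=rng)
        obs = np.round(null.pooled_raw[:, 0], 9)
        assert set(np.unique(obs)) <= set(exp_vals)
        for v, f in zip(exp_vals, exp_freq):
            assert abs((obs == v).mean() - f) < 0.03

    def test_sigma_hat_near_theoretical_t_sd(self, rng):
        """Null Welch t with 5+5 samples has sd near sqrt(8/6)."""
        p = make_platform(rng.standard_normal((1000, 10)))
        null = build_null([p], [TestSpec("student_t", "right")], B=20, rng=rng)
        assert null.sigma_hat[0] == pytest.approx(np.sqrt(8 / 6), rel=0.10)

    def test_scale_equivariance(self, rng):
        p = make_platform(rng.standard_normal((30, 10)))
        scaled = make_platform(p.values * 7.0)
        for statistic, factor in (("student_t", 1.0), ("mean_diff", 7.0)):
            spec = [TestSpec(statistic, "right")]
            n1 = build_null([p], spec, B=30, seed=11)
            n2 = build_null([scaled], spec, B=30, seed=11)
            assert n2.sigma_hat[0] == pytest.approx(
                factor * n1.sigma_hat[0], rel=1e-9
            )

    def test_cov_symmetric_psd(self, two_noise_platforms, rng):
        null = build_null(two_noise_platforms, [TestSpec()] * 2, B=20, rng=rng)
        np.testing.assert_allclose(null.cov_hat, null.cov_hat.T, atol=1e-12)
        eig = np.linalg.eigvalsh(null.cov_hat)
        assert (eig > -1e-10).all()

    def test_linked_identical_platforms_perfectly_correlated(self, rng):
        subj = [f"s{i}" for i in range(10)]
        vals = rng.standard_normal((15, 10))
        p1 = make_platform(vals, subject_id=subj, platform_id="a")
        p2 = make_platform(vals.copy(), subject_id=subj, platform_id="b")
        null = build_null([p1, p2], [TestSpec("student_t", "right")] * 2,
                          B=20, rng=rng)
        np.testing.assert_allclose(null.pooled[:, 0], null.pooled[:, 1],
                                   atol=1e-10)
        corr = null.cov_hat[0, 1] / (null.sigma_hat[0] * null.sigma_hat[1])
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_constant_data_degenerate_scale_error(self):
        p = make_platform(np.full((5, 8), 3.0))
        with pytest.raises(ValidationError, match="degenerate"):
            build_null([p], [TestSpec("student_t", "right")], B=10, seed=0)

    def test_pooled_row_count_and_order(self, two_noise_platforms):
        null = build_null(two_noise_platforms, [TestSpec()] * 2, B=7, seed=1)
        assert null.pooled.shape == (7 * 20, 2)
        assert null.B == 7

    def test_vectorized_path_matches_permute_labels_loop(self, two_noise_platforms):
        """build_null consumes the rng exactly as a loop of permute_labels +
        compute_stat_matrix would, so pooled values agree bit-for-bit."""
        specs = [TestSpec("student_t", "two"), TestSpec("wilcoxon", "right")]
        B = 9
        null = build_null(two_noise_platforms, specs, B=B, seed=77)
        rng = np.random.default_rng(77)
        n = two_noise_platforms[0].n_biomarkers
        for b in range(B):
            permuted = permute_labels(two_noise_platforms, rng)
            sm = compute_stat_matrix(permuted, specs)
            np.testing.assert_allclose(
                null.pooled_raw[b * n : (b + 1) * n], sm.raw, atol=1e-12
            )

    def test_adjusted_scale_basis_switch(self, two_noise_platforms):
        specs = [TestSpec("student_t", "two")] * 2
        raw = build_null(two_noise_platforms, specs, B=15, seed=3,
                         scale_basis="raw")
        adj = build_null(two_noise_platforms, specs, B=15, seed=3,
                         scale_basis="adjusted")
        # |t| has smaller sd than t under a symmetric null
        assert (adj.sigma_hat < raw.sigma_hat).all()
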