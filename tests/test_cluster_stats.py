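"""Clustering, Hungarian matching, ANOVA and FDR machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import neuromodes as nm
from neuromodes.cluster_stats import _safe_centroid_corr, cluster_quality
from neuromodes.errors import DataError, DomainError


def _fake_modes(vectors, stabilities, frequencies, state):
    from neuromodes.eigenmodes import Eigenmode

    out = []
    for v, s, f in zip(vectors, stabilities, frequencies):
        v = np.asarray(v, dtype=complex)
        v = v / np.linalg.norm(v)
        out.append(
            Eigenmode(
                eigenvalue=complex(np.exp(s * 2.0), 0.0),
                eigenvector=v,
                frequency_hz=f,
                stability_per_s=s,
                magnitude=float(np.exp(s * 2.0)),
                angle=f * 4 * np.pi,
                stability_class="stable",
                state_label=state,
            )
        )
    return out


class TestModeFeatures:
    def test_rows_are_magnitudes_unit_norm(self, small_system):
        modes = nm.decompose(small_system.A_true, 2.0, state_label="awake")
        F, states = nm.mode_features(modes)
        assert F.shape == (6, 6)
        assert np.all(F >= 0)
        np.testing.assert_allclose(np.linalg.norm(F, axis=1), 1.0, atol=1e-12)

    def test_conjugate_pairs_identical_rows(self, small_system):
        modes = nm.decompose(small_system.A_true, 2.0)
        F, _ = nm.mode_features(modes)
        lam = np.array([m.eigenvalue for m in modes])
        for i, j in itertools.combinations(range(len(modes)), 2):
            if abs(lam[i] - lam[j].conjugate()) < 1e-10:
                np.testing.assert_allclose(F[i], F[j], atol=1e-10)

    def test_four_states_of_hundred_modes_give_400_rows(self, rng):
        from neuromodes.experiments import random_stable_spec

        all_modes = []
        for st_label in ("awake", "light", "deep", "recovery"):
            sys_ = nm.make_stable_system(
                100, random_stable_spec(100, rng), seed=int(rng.integers(2**31))
            )
            all_modes.extend(nm.decompose(sys_.A_true, 2.0, state_label=st_label))
        F, states = nm.mode_features(all_modes)
        assert F.shape == (400, 100)
        assert len(states) == 400


class TestRunKmeans:
    def test_separated_blobs_exact_recovery(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.eye(3) * 10
        X = np.vstack([centers[i] + 0.05 * rng.standard_normal((20, 3)) for i in range(3)])
        truth = np.repeat(np.arange(3), 20)
        run = nm.run_kmeans(X, 3, seed=0)
        assert adjusted_rand_score(truth, run.labels) == 1.0

    def test_duplicate_rows_share_labels(self, rng):
        X = rng.standard_normal((10, 4))
        XX = np.vstack([X, X])
        run = nm.run_kmeans(XX, 3, seed=1)
        np.testing.assert_array_equal(run.labels[:10], run.labels[10:])

    def test_same_seed_identical(self, rng):
        X = rng.standard_normal((30, 5))
        a = nm.run_kmeans(X, 4, seed=7)
        b = nm.run_kmeans(X, 4, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_k_exceeding_rows_rejected(self, rng):
        with pytest.raises(DomainError):
            nm.run_kmeans(rng.standard_normal((3, 2)), 5, seed=0)


class TestMatchCentroids:
    def test_identity(self, rng):
        C = rng.standard_normal((4, 10))
        np.testing.assert_array_equal(nm.match_centroids(C, C), np.arange(4))

    def test_permutation_recovered(self, rng):
        C = rng.standard_normal((5, 8))
        perm = rng.permutation(5)
        got = nm.match_centroids(C[perm], C)
        np.testing.assert_array_equal(C[perm][got], C)

    def test_beats_every_alternative_assignment(self, rng):
        """Exhaustive oracle: total matched correlation is maximal."""
        for trial in range(10):
            cur = rng.standard_normal((4, 10))
            ref = rng.standard_normal((4, 10))
            perm = nm.match_centroids(cur, ref)
            C = _safe_centroid_corr(cur, ref)
            ours = C[np.arange(4), perm].sum()
            best = max(
                sum(C[i, p[i]] for i in range(4))
                for p in itertools.permutations(range(4))
            )
            assert ours == pytest.approx(best, abs=1e-12)

    def test_constant_row_warns_and_matches(self, rng):
        cur = rng.standard_normal((3, 6))
        cur[1] = 2.5
        ref = rng.standard_normal((3, 6))
        with pytest.warns(RuntimeWarning):
            perm = nm.match_centroids(cur, ref)
        assert sorted(perm) == [0, 1, 2]


class TestStateAnova:
    def test_identical_constants_degenerate_convention(self):
        F, p, f = nm.state_anova([np.ones(4), np.ones(4)])
        assert np.isnan(F) and p == 1.0 and f == 0.0

    def test_identical_distributions_null(self):
        F, p, f = nm.state_anova([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_group_equals_t_squared(self, rng):
        """Closed-form oracle: two-group one-way ANOVA F = t**2."""
        a = rng.standard_normal(8)
        b = rng.standard_normal(10) + 0.5
        F, p, _ = nm.state_anova([a, b])
        t, pt = stats.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)

    def test_strong_shift_tiny_p_large_effect(self, rng):
        a = 1e-6 * rng.standard_normal(4)
        b = 1.0 + 1e-6 * rng.standard_normal(4)
        F, p, f = nm.state_anova([a, b])
        assert p < 1e-10
        assert f > 100

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            nm.state_anova([np.array([1.0]), np.array([1.0, 2.0])])


class TestFdrCorrect:
    def test_hand_computed_stepup(self):
        reject, q = nm.fdr_correct([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    def test_all_ones_nothing_significant(self):
        reject, _ = nm.fdr_correct(np.ones(10))
        assert not reject.any()

    def test_single_p_reduces_to_raw_threshold(self):
        reject, q = nm.fdr_correct([0.04], alpha=0.05)
        assert reject[0]
        assert q[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            nm.fdr_correct([0.5, 1.2])

    @given(st.integers(0, 500))
    def test_matches_bruteforce_benjamini_hochberg(self, draw):
        """Independent step-up oracle on random p-vectors."""
        rng = np.random.default_rng(draw)
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, m)
        reject, _ = nm.fdr_correct(p, alpha=0.05)
        order = np.argsort(p)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passing = np.nonzero(p[order] <= thresh)[0]
        manual = np.zeros(m, dtype=bool)
        if passing.size:
            manual[order[: passing[-1] + 1]] = True
        np.testing.assert_array_equal(reject, manual)


class TestRepeatedClusterAnova:
    def _toy_modes(self, shift, seed=0):
        """5 tight eigenvector clusters; one carries a stability shift in
        the deep state."""
        rng = np.random.default_rng(seed)
        states = ("awake", "light", "deep", "recovery")
        base_vecs = np.eye(5)
        modes = {}
        for st_label in states:
            ms = []
            for c in range(5):
                for rep in range(4):
                    v = base_vecs[c] + 0.01 * rng.standard_normal(5)
                    s = -0.1 + 0.01 * c + 0.002 * rep + 0.001 * rng.standard_normal()
                    if shift and c == 2 and st_label == "deep":
                        s -= 0.15
                    ms.extend(_fake_modes([v], [s], [0.05 + 0.01 * c], st_label))
            modes[st_label] = ms
        return modes

    def test_planted_shift_detected_null_frequency(self):
        rep = nm.repeated_cluster_anova(self._toy_modes(True), [5], 30, seed=1)
        s = rep.summary
        stab = s[(s.measure == "stability")].set_index("cluster")["significance_rate"]
        freq = s[(s.measure == "frequency")].set_index("cluster")["significance_rate"]
        assert stab.max() > 90
        assert freq[stab.idxmax()] <= 5

    def test_no_effect_no_detection(self):
        rep = nm.repeated_cluster_anova(self._toy_modes(False, seed=5), [5], 30, seed=2)
        assert (rep.summary["significance_rate"] <= 5).all()

    def test_perfect_clusters_perfect_reliability(self):
        rep = nm.repeated_cluster_anova(self._toy_modes(False, seed=6), [5], 20, seed=3)
        assert (rep.summary["ref_corr_mean"] > 0.99).all()
        assert (rep.summary["pc1_variance_pct"] <= 100).all()

    def test_label_permutation_destroys_significance(self):
        modes = self._toy_modes(True)
        # randomly permute state labels across the pooled modes
        pooled = [m for st in modes for m in modes[st]]
        states = ["awake", "light", "deep", "recovery"]
        shuffled = {st: [] for st in states}
        new_labels = np.random.default_rng(0).permutation(
            np.repeat(states, len(pooled) // 4)
        )
        for i, m in enumerate(pooled):
            st_new = str(new_labels[i])
            shuffled[st_new].append(
                type(m)(
                    eigenvalue=m.eigenvalue, eigenvector=m.eigenvector,
                    frequency_hz=m.frequency_hz, stability_per_s=m.stability_per_s,
                    magnitude=m.magnitude, angle=m.angle,
                    stability_class=m.stability_class, state_label=st_new,
                )
            )
        rep = nm.repeated_cluster_anova(shuffled, [5], 30, seed=4)
        assert (rep.summary["significance_rate"] <= 10).all()


def test_cluster_quality_diagnostics(rng):
    X = np.vstack([np.zeros((10, 3)), np.ones((10, 3))]) + 0.01 * rng.standard_normal((20, 3))
    labels = np.repeat([0, 1], 10)
    q = cluster_quality(X, labels)
    assert q["silhouette"] > 0.9
    assert q["calinski_harabasz"] > 100
    assert q["davies_bouldin"] < 0.5
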