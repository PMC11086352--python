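"""Unit tests for synergy pooling, k-means model selection, and the
mutual-assignment rule."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from emgsynergy import (
    ClusterSolution, SynergyPool, centroid_sign_profile, kmeans_best_of,
    mutual_assignment_pct, reclassify_by_style, select_cluster_number,
)

STYLES = ["FL", "FS", "SL", "SS"]


def _pool(vectors, trial_ids, styles=None, synergy_index=None):
    n = len(vectors)
    prov = pd.DataFrame(
        {
            "subject": ["s01"] * n,
            "side": ["L"] * n,
            "task": ["t"] * n,
            "style": styles or [STYLES[i % 4] for i in range(n)],
            "trial_id": trial_ids,
            "synergy_index": synergy_index or list(range(n)),
        }
    )
    return SynergyPool(np.asarray(vectors, float), prov)


def _blob_pool(rng, n_blobs=2, per_blob=20, sep=10.0, dim=6):
    centers = sep * rng.standard_normal((n_blobs, dim))
    vectors, labels, trials = [], [], []
    for b in range(n_blobs):
        for i in range(per_blob):
            vectors.append(centers[b] + rng.standard_normal(dim))
            labels.append(b)
            trials.append(f"tr{b}_{i}")
    return _pool(vectors, trials), np.array(labels)


class TestKMeansBestOf:
    def test_separated_blobs_recovered(self, rng):
        pool, truth = _blob_pool(rng)
        sol = kmeans_best_of(pool, 2, n_rep=5, seed=3)
        assert adjusted_rand_score(truth, sol.assignment) == 1.0
        assert set(sol.assignment) == {1, 2}

    def test_near_degenerate_geometry_returns(self, rng):
        vectors = np.ones((10, 4)) + 1e-9 * rng.standard_normal((10, 4))
        pool = _pool(list(vectors), [f"t{i}" for i in range(10)])
        sol = kmeans_best_of(pool, 2, n_rep=3, seed=1)
        assert abs(sol.mean_silhouette) < 0.5

    def test_determinism(self, rng):
        pool, _ = _blob_pool(rng, n_blobs=3)
        a = kmeans_best_of(pool, 3, n_rep=5, seed=9)
        b = kmeans_best_of(pool, 3, n_rep=5, seed=9)
        assert np.array_equal(a.assignment, b.assignment)

    def test_invalid_k_raises(self, rng):
        pool, _ = _blob_pool(rng, per_blob=3)
        with pytest.raises(ValueError):
            kmeans_best_of(pool, 1, seed=1)
        with pytest.raises(ValueError):
            kmeans_best_of(pool, pool.n_rows, seed=1)

    def test_conservation(self, rng):
        pool, _ = _blob_pool(rng, n_blobs=3, per_blob=10)
        sol = kmeans_best_of(pool, 3, n_rep=5, seed=2)
        sizes = np.bincount(sol.assignment)[1:]
        assert sizes.sum() == pool.n_rows
        assert np.all(sizes > 0)


class TestMutualAssignment:
    def _solution(self, labels, k):
        labels = np.asarray(labels)
        return ClusterSolution(k=k, assignment=labels,
                               centroids=np.zeros((k, 2)),
                               mean_silhouette=0.0)

    def test_enumerated_oracle_cases(self, rng):
        vectors = list(rng.standard_normal((6, 3)))
        trials = ["a", "a", "b", "b", "c", "c"]
        pool = _pool(vectors, trials)
        # all distinct within trials -> 0%
        assert mutual_assignment_pct(
            self._solution([1, 2, 1, 2, 1, 2], 2), pool) == 0.0
        # exactly one trial mutually assigned -> 33.333%
        pct = mutual_assignment_pct(self._solution([1, 1, 1, 2, 1, 2], 2), pool)
        assert pct == pytest.approx(100.0 / 3.0)
        # all trials mutually assigned -> 100%
        assert mutual_assignment_pct(
            self._solution([1, 1, 2, 2, 1, 1], 2), pool) == 100.0

    def test_matches_brute_force_on_random_assignments(self, rng):
        vectors = list(rng.standard_normal((24, 3)))
        trials = [f"t{i // 3}" for i in range(24)]  # 8 trials of 3 synergies
        pool = _pool(vectors, trials)
        for _ in range(20):
            labels = rng.integers(1, 6, size=24)
            brute = 0
            for t in range(8):
                lab = labels[3 * t: 3 * t + 3]
                brute += len(set(lab)) < 3
            expected = 100.0 * brute / 8
            got = mutual_assignment_pct(self._solution(labels, 5), pool)
            assert got == pytest.approx(expected)


class TestSelectClusterNumber:
    def _planted(self, rng, n_templates=4, n_trials=40, per_trial=3):
        templates = rng.standard_normal((n_templates, 8)) * 3
        vectors, trials = [], []
        for t in range(n_trials):
            chosen = rng.choice(n_templates, size=per_trial, replace=False)
            for tem in chosen:
                vectors.append(templates[tem] + 0.1 * rng.standard_normal(8))
                trials.append(f"trial{t}")
        return _pool(vectors, trials)

    def test_planted_templates_select_true_k(self, rng):
        pool = self._planted(rng)
        k, trace = select_cluster_number(pool, k_range=range(2, 8),
                                         n_outer=5, n_rep=5, seed=4)
        assert k == 4
        assert sum(trace["histogram"].values()) == 5

    def test_trace_reproducible(self, rng):
        pool = self._planted(rng, n_trials=20)
        a = select_cluster_number(pool, k_range=range(2, 7), n_outer=1,
                                  n_rep=3, seed=5)
        b = select_cluster_number(pool, k_range=range(2, 7), n_outer=1,
                                  n_rep=3, seed=5)
        assert a[0] == b[0]
        assert a[1]["selections"] == b[1]["selections"]
        assert a[1]["ma_by_k"] == b[1]["ma_by_k"]

    def test_impossible_threshold_raises(self, rng):
        pool = self._planted(rng, n_trials=15)
        with pytest.raises(RuntimeError, match="MA%"):
            select_cluster_number(pool, k_range=range(2, 4), ma_threshold=-1.0,
                                  n_outer=2, n_rep=2, seed=1)

    def test_ma_decreases_with_k_on_average(self, rng):
        curves = []
        for s in range(6):
            rng_s = np.random.default_rng(100 + s)
            pool = self._planted(rng_s, n_templates=5, n_trials=30)
            row = []
            for k in range(2, 8):
                sol = kmeans_best_of(pool, k, n_rep=5, seed=s)
                row.append(sol.ma_pct)
            curves.append(row)
        mean_curve = np.mean(curves, axis=0)
        assert np.all(np.diff(mean_curve) <= 2.0)  # single-step slack
        assert mean_curve[-1] < mean_curve[0]


class TestSignProfile:
    def _members_pool(self, weights, trials=None):
        n = len(weights)
        return _pool(list(weights), trials or [f"t{i}" for i in range(n)])

    def test_consistent_positive_channel_flagged(self, rng):
        w = 0.1 * rng.standard_normal((20, 3))
        w[:, 1] = 0.5
        pool = self._members_pool(w)
        sol = ClusterSolution(k=1, assignment=np.ones(20, int),
                              centroids=w.mean(0, keepdims=True),
                              mean_silhouette=0.0)
        prof = centroid_sign_profile(sol, pool)
        row = prof[(prof.cluster == 1) & (prof.channel == 1)].iloc[0]
        assert row.significant and row.sign == 1.0 and row.p_value < 0.05

    def test_symmetric_channel_masked_out(self):
        w = np.zeros((20, 2))
        w[::2, 0], w[1::2, 0] = 0.3, -0.3
        w[:, 1] = 0.2
        pool = self._members_pool(w)
        sol = ClusterSolution(k=1, assignment=np.ones(20, int),
                              centroids=w.mean(0, keepdims=True),
                              mean_silhouette=0.0)
        prof = centroid_sign_profile(sol, pool)
        assert not prof[prof.channel == 0].iloc[0].significant
        assert prof[prof.channel == 1].iloc[0].significant

    def test_vacuous_alpha_flags_consistent_channels(self, rng):
        w = 0.2 + 0.01 * rng.random((12, 3))
        pool = self._members_pool(w)
        sol = ClusterSolution(k=1, assignment=np.ones(12, int),
                              centroids=w.mean(0, keepdims=True),
                              mean_silhouette=0.0)
        prof = centroid_sign_profile(sol, pool, alpha=1.0)
        assert prof.significant.all()

    def test_singleton_cluster_masked(self, rng):
        w = rng.standard_normal((3, 2))
        pool = self._members_pool(w)
        sol = ClusterSolution(k=2, assignment=np.array([1, 1, 2]),
                              centroids=np.zeros((2, 2)),
                              mean_silhouette=0.0)
        prof = centroid_sign_profile(sol, pool)
        single = prof[prof.cluster == 2]
        assert not single.significant.any()
        assert single.p_value.isna().all()


class TestReclassifyByStyle:
    def test_counts_partition_pool(self, rng):
        pool, _ = _blob_pool(rng, n_blobs=1, per_blob=16, dim=3)
        sol = kmeans_best_of(pool, 2, n_rep=2, seed=1)
        counts, membership = reclassify_by_style(sol, pool)
        assert counts.values.sum() == pool.n_rows
        assert set(counts.columns) == set(STYLES)
        total = sum(len(v) for v in membership.values())
        assert total == pool.n_rows

    def test_absent_style_present_with_zero(self, rng):
        vectors = list(rng.standard_normal((8, 3)))
        pool = _pool(vectors, [f"t{i}" for i in range(8)],
                     styles=["FL"] * 8)
        sol = ClusterSolution(k=2, assignment=np.array([1, 2] * 4),
                              centroids=np.zeros((2, 3)),
                              mean_silhouette=0.0)
        counts, membership = reclassify_by_style(sol, pool)
        assert list(counts.columns) == ["FL"]
        assert counts.values.sum() == 8

    def test_counts_invariant_to_row_order(self, rng):
        vectors = rng.standard_normal((12, 3))
        styles = [STYLES[i % 4] for i in range(12)]
        pool = _pool(list(vectors), [f"t{i}" for i in range(12)], styles=styles)
        labels = np.array([1, 2] * 6)
        sol = ClusterSolution(k=2, assignment=labels,
                              centroids=np.zeros((2, 3)), mean_silhouette=0.0)
        counts1, _ = reclassify_by_style(sol, pool)
        perm = np.random.default_rng(0).permutation(12)
        pool2 = _pool(list(vectors[perm]), [f"t{i}" for i in perm],
                      styles=[styles[i] for i in perm])
        sol2 = ClusterSolution(k=2, assignment=labels[perm],
                               centroids=np.zeros((2, 3)), mean_silhouette=0.0)
        counts2, _ = reclassify_by_style(sol2, pool2)
        assert counts1.equals(counts2)


class TestPoolValidation:
    def test_mixed_sides_rejected(self, rng):
        prov = pd.DataFrame(
            {
                "subject": ["a", "b"], "side": ["L", "R"],
                "task": ["t", "t"], "style": ["FL", "FL"],
                "trial_id": ["x", "y"], "synergy_index": [0, 0],
            }
        )
        with pytest.raises(ValueError, match="side"):
            SynergyPool(rng.standard_normal((2, 3)), prov)

    def test_missing_provenance_column_rejected(self, rng):
        prov = pd.DataFrame({"subject": ["a"], "side": ["L"]})
        with pytest.raises(ValueError, match="missing"):
            SynergyPool(rng.standard_normal((1, 3)), prov)
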