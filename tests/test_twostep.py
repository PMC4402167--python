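"""Two-step clustering: distances, CF tree, agglomeration, k selection, quality."""

import numpy as np
import pytest

from phenocut.twostep_cluster import (CFEntry, agglomerate,
                                      assign_by_centroids, build_cf_tree,
                                      fit_twostep, log_likelihood_distance,
                                      predictor_importance, silhouette)


def _entry(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    e = CFEntry(len(pts), pts.sum(axis=0), (pts ** 2).sum(axis=0))
    return e


class TestDistance:
    def test_identical_point_masses_have_zero_distance(self):
        a = _entry([[1.0, 2.0]])
        b = _entry([[1.0, 2.0]])
        assert log_likelihood_distance(a, b, [1.0, 1.0]) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        pooled = np.array([1.0, 2.0, 0.5])
        for _ in range(20):
            a = _entry(rng.normal(size=(rng.integers(1, 6), 3)))
            b = _entry(rng.normal(size=(rng.integers(1, 6), 3)))
            dab = log_likelihood_distance(a, b, pooled)
            dba = log_likelihood_distance(b, a, pooled)
            assert dab == pytest.approx(dba, rel=1e-12)
            assert dab >= 0.0

    def test_monotone_in_separation(self):
        """Singleton-singleton cost grows with their gap on one predictor."""
        pooled = np.array([1.0])
        gaps = np.linspace(0.0, 10.0, 25)
        costs = [log_likelihood_distance(_entry([[0.0]]), _entry([[g]]),
                                         pooled) for g in gaps]
        assert all(b > a - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_mismatched_predictors_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood_distance(_entry([[0.0]]), _entry([[0.0, 1.0]]),
                                    [1.0])

    def test_merge_conserves_sufficient_statistics(self, rng):
        pts = rng.normal(size=(7, 2))
        a = _entry(pts[:3])
        b = _entry(pts[3:])
        a.absorb(b)
        assert a.n == 7
        np.testing.assert_allclose(a.s, pts.sum(axis=0))
        np.testing.assert_allclose(a.ss, (pts ** 2).sum(axis=0))


class TestCFTree:
    def test_single_record(self):
        entries, assign = build_cf_tree(np.array([[1.0, 2.0]]), [1.0, 1.0])
        assert len(entries) == 1
        assert entries[0].n == 1
        np.testing.assert_allclose(entries[0].variances, 0.0)
        assert assign.tolist() == [0]

    def test_identical_records_merge_at_zero_threshold(self):
        X = np.array([[3.0, 1.0], [3.0, 1.0]])
        entries, assign = build_cf_tree(X, [1.0, 1.0])
        assert len(entries) == 1
        assert entries[0].n == 2
        assert assign.tolist() == [0, 0]

    def test_every_record_absorbed_exactly_once(self, rng):
        X = rng.normal(size=(300, 2))
        entries, assign = build_cf_tree(X, X.var(axis=0), seed=0,
                                        max_entries=64)
        assert sum(e.n for e in entries) == 300
        assert len(entries) <= 64 + 1
        counts = np.bincount(assign, minlength=len(entries))
        np.testing.assert_array_equal(
            counts, np.array([e.n for e in entries]))

    def test_leaves_pure_for_separated_components(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 2)),
                       rng.normal(10, 1, (100, 2))])
        labels = np.repeat([0, 1], 100)
        entries, assign = build_cf_tree(X, X.var(axis=0), seed=1,
                                        max_entries=64)
        for k, e in enumerate(entries):
            members = labels[assign == k]
            assert members.min() == members.max(), "leaf mixes components"

    def test_empty_predictor_list_rejected(self):
        with pytest.raises(ValueError):
            build_cf_tree(np.empty((3, 0)), [])


def _brute_force_merge_order(entries, pooled):
    """Exhaustive greedy closest-pair schedule (lexicographic tie-break)."""
    work = {i: e.copy() for i, e in enumerate(entries)}
    order = []
    while len(work) > 1:
        best = None
        for i in sorted(work):
            for j in sorted(work):
                if j <= i:
                    continue
                d = log_likelihood_distance(work[i], work[j], pooled)
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        order.append((i, j, d))
        work[i].absorb(work.pop(j))
    return order


class TestAgglomerate:
    def test_identity_clustering_at_k_equals_entries(self):
        entries = [_entry([[0.0]]), _entry([[5.0]]), _entry([[9.0]])]
        agg = agglomerate(entries, [1.0])
        assert agg.labels_at(3).tolist() == [0, 1, 2]

    def test_merge_order_matches_exhaustive_oracle(self, rng):
        pooled = np.array([1.0, 1.0])
        for trial in range(5):
            entries = [_entry(rng.normal(size=(rng.integers(1, 4), 2)))
                       for _ in range(6)]
            agg = agglomerate(entries, pooled)
            oracle = _brute_force_merge_order(entries, pooled)
            assert agg.merges == [(i, j) for i, j, _ in oracle]
            got = [agg.merge_distances[k] for k in range(6, 1, -1)]
            np.testing.assert_allclose(got, [d for _, _, d in oracle],
                                       rtol=1e-9)

    def test_two_component_means_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (300, 1)),
                       rng.normal(8, 1, (300, 1))])
        m = fit_twostep(X, k=2, seed=0, compute_quality=False)
        means = np.sort(m.means[:, 0])
        assert abs(means[0] - 0.0) < 0.3
        assert abs(means[1] - 8.0) < 0.3
        assert m.sizes.sum() == 600


class TestSelectK:
    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_recovers_component_count(self, n_components):
        hits = 0
        seeds = range(6)
        for s in seeds:
            rng = np.random.default_rng(900 + s)
            centers = np.array([[0, 0], [8, 0], [4, 8]])[:n_components]
            X = np.vstack([rng.normal(c, 1, (300 // n_components, 2))
                           for c in centers])
            if fit_twostep(X, seed=s, compute_quality=False).k == n_components:
                hits += 1
        assert hits > len(seeds) // 2


class TestSilhouette:
    def test_two_distant_singletons_score_one(self):
        s = silhouette(np.array([[0.0], [100.0]]), [0, 1])
        assert s == pytest.approx(1.0, abs=1e-9)

    def test_random_labels_score_near_zero(self, rng):
        X = rng.normal(size=(2000, 2))
        labels = rng.integers(0, 2, 2000)
        assert abs(silhouette(X, labels)) < 0.1

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        labels = rng.integers(0, 3, 50)
        got = silhouette(X, labels)
        # O(n^2) direct evaluation
        s = []
        for i in range(50):
            own = [j for j in range(50) if labels[j] == labels[i] and j != i]
            a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own]) if own else 0.0
            b = min(np.mean([np.linalg.norm(X[i] - X[j])
                             for j in range(50) if labels[j] == c])
                    for c in set(labels) - {labels[i]})
            s.append((b - a) / max(a, b))
        assert got == pytest.approx(np.mean(s), abs=1e-12)

    def test_matches_sklearn_on_regular_clusterings(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        X = rng.normal(size=(120, 2))
        labels = rng.integers(0, 3, 120)
        assert silhouette(X, labels) == pytest.approx(
            sklearn_metrics.silhouette_score(X, labels), abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 1)), np.zeros(5, dtype=int))


class TestImportance:
    def test_flat_predictor_scores_zero(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        labels = np.repeat([0, 1], 20)
        with pytest.warns(UserWarning):
            imp = predictor_importance(X, labels, ["flat", "noise"])
        assert imp["flat"] == 0.0

    def test_sole_separator_scores_one_and_ranking_follows_effect_size(self, rng):
        n = 300
        labels = np.repeat([0, 1], n // 2)
        strong = labels * 10.0 + rng.normal(size=n)
        weak = labels * 1.0 + rng.normal(size=n)
        noise = rng.normal(size=n)
        X = np.column_stack([weak, strong, noise])
        imp = predictor_importance(X, labels, ["weak", "strong", "noise"])
        assert imp["strong"] == 1.0
        assert imp["strong"] > imp["weak"] > imp["noise"]


class TestCentroidAssignment:
    def test_record_at_centroid_goes_to_that_cluster(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 2)),
                       rng.normal(6, 1, (200, 2))])
        m = fit_twostep(X, k=2, seed=0, compute_quality=False)
        labels, skipped = assign_by_centroids(m, m.means)
        assert skipped == 0
        assert labels.tolist() == [0, 1]

    def test_missing_values_skipped_with_warning(self, rng):
        X = rng.normal(size=(50, 2))
        m = fit_twostep(X, k=2, seed=0, compute_quality=False)
        new = np.array([[0.0, 0.0], [np.nan, 1.0]])
        with pytest.warns(UserWarning):
            labels, skipped = assign_by_centroids(m, new)
        assert skipped == 1
        assert labels[1] == -1

    def test_agrees_with_brute_force_nearest(self, rng):
        X = rng.normal(size=(200, 2)) + np.repeat([[0, 0], [5, 5]], 100, axis=0)
        m = fit_twostep(X, k=2, seed=0, compute_quality=False)
        new = rng.normal(2.5, 2.0, size=(50, 2))
        labels, _ = assign_by_centroids(m, new)
        Z = (new - m.standardize_mean) / m.standardize_std
        from phenocut.twostep_cluster import CFEntry, _dist_one_to_many
        for i in range(50):
            d = _dist_one_to_many(CFEntry.from_point(Z[i]), m.cluster_N,
                                  m.cluster_S, m.cluster_SS,
                                  m.pooled_variances)
            assert labels[i] == int(np.argmin(d))


class TestFullPipelineRecovery:
    def test_separated_mixture_recovered_with_high_accuracy(self):
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(50 + s)
            X = np.vstack([rng.normal(0, 1, (500, 2)),
                           rng.normal(6 / np.sqrt(2), 1, (500, 2))])
            truth = np.repeat([0, 1], 500)
            m = fit_twostep(X, seed=s, compute_quality=False)
            if m.k != 2:
                continue
            acc = max((m.labels_ == truth).mean(),
                      (m.labels_ == 1 - truth).mean())
            if acc >= 0.95:
                hits += 1
        assert hits >= 4

    def test_sizes_sum_to_n_and_silhouette_in_range(self, rng):
        X = rng.normal(size=(150, 2))
        m = fit_twostep(X, k=3, seed=0)
        assert m.sizes.sum() == 150
        assert -1.0 <= m.silhouette <= 1.0
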