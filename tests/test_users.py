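"""User clustering on day-type proportions: B construction, the four
techniques, metric oracles, method selection, group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

from wearday.users import (
    ClusterScore,
    METHODS,
    NOISE,
    UserProportionMatrix,
    UserSegmentation,
    build_user_proportions,
    cluster_users,
    correlation_distance,
    score_clustering,
    select_method,
    summarize_groups,
)


def _day_table(user_clusters: dict[str, list[int]], kept=None) -> pd.DataFrame:
    rows = []
    for user, clusters in user_clusters.items():
        for i, c in enumerate(clusters):
            rows.append({"user_id": user, "cluster": c, "kept": 1})
    out = pd.DataFrame(rows)
    if kept is not None:
        out["kept"] = kept
    return out


def _blocks(rng, centers, n_per=30, spread=0.03):
    """Users tightly grouped around simplex points."""
    rows = []
    for c in centers:
        x = np.abs(rng.normal(c, spread, (n_per, 3)))
        rows.append(x / x.sum(axis=1, keepdims=True))
    X = np.vstack(rows)
    ids = np.array([f"u{i}" for i in range(len(X))])
    return UserProportionMatrix(X, ids, ["full_day", "afternoon", "sporadic_evening"])


class TestProportionMatrix:
    def test_count_ratio(self):
        B, dropped = build_user_proportions(_day_table({"u1": [1, 1, 2] + [0] * 0}))
        assert np.allclose(B.values[0], [0, 2 / 3, 1 / 3])
        assert dropped == []

    def test_single_typed_users_give_unit_rows(self):
        B, _ = build_user_proportions(_day_table({"a": [0] * 5, "b": [2] * 4}))
        assert np.allclose(B.values, [[1, 0, 0], [0, 0, 1]])

    def test_trimmed_days_excluded_and_users_dropped(self):
        table = _day_table({"a": [0, 0, 1], "b": [2, 2, 2]},
                           kept=[1, 1, 0, 0, 0, 0])
        B, dropped = build_user_proportions(table)
        assert dropped == ["b"]
        assert np.allclose(B.values, [[1.0, 0.0, 0.0]])

    def test_rows_stochastic_after_any_dropping(self, rng):
        counts = rng.integers(0, 6, (40, 3))
        counts[counts.sum(axis=1) == 0, 0] = 1
        rows = []
        for u, row in enumerate(counts):
            for c, n in enumerate(row):
                rows += [{"user_id": f"u{u:02d}", "cluster": c, "kept": 1}] * n
        B, _ = build_user_proportions(pd.DataFrame(rows))
        assert np.allclose(B.values.sum(axis=1), 1.0, atol=1e-9)


class TestCorrelationDistance:
    def test_perfectly_correlated_rows_distance_zero(self):
        X = np.array([[0.5, 0.25, 0.25], [0.9, 0.05, 0.05]])
        D = correlation_distance(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_constant_row_gets_unit_distance(self):
        X = np.array([[1 / 3, 1 / 3, 1 / 3], [0.8, 0.1, 0.1]])
        D = correlation_distance(X)
        assert D[0, 1] == 1.0 and D[0, 0] == 0.0

    def test_matches_pearson_oracle(self, rng):
        X = rng.dirichlet(np.ones(3), 6)
        D = correlation_distance(X)
        for i in range(6):
            for j in range(6):
                r = np.corrcoef(X[i], X[j])[0, 1]
                assert D[i, j] == pytest.approx(1 - r, abs=1e-9)


class TestClusterUsers:
    @pytest.mark.parametrize("method", METHODS)
    def test_unit_vector_blocks_recovered_by_every_method(self, method, rng):
        B = _blocks(rng, np.eye(3), n_per=40)
        labels = cluster_users(B, method, min_cluster_fraction=0.2, seed=0)
        truth = np.repeat([0, 1, 2], 40)
        found = labels[labels != NOISE]
        # perfect recovery up to label permutation (density method may not
        # emit noise on perfectly separated blocks, but allow none)
        assert (labels != NOISE).all()
        conf = pd.crosstab(truth, labels).to_numpy()
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() == 120

    def test_ward_matches_scipy_linkage_oracle(self, rng):
        X = rng.dirichlet(np.ones(3), 12)
        ours = cluster_users(UserProportionMatrix(
            X, np.arange(12).astype(str), list("abc")), "agglomerative_ward_euclidean",
            n_clusters=3)
        Z = linkage(X, method="ward")
        scipy_labels = fcluster(Z, t=3, criterion="maxclust")
        conf = pd.crosstab(scipy_labels, ours).to_numpy()
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() == 12

    def test_density_method_finds_three_groups_plus_noise(self, rng):
        centers = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
        tight = _blocks(rng, centers, n_per=100, spread=0.05)
        scattered = rng.dirichlet(np.ones(3), 40)
        B = UserProportionMatrix(
            np.vstack([tight.values, scattered]),
            np.arange(340).astype(str),
            tight.type_names,
        )
        labels = cluster_users(B, "density_hierarchical_correlation", seed=0)
        assert len(set(labels) - {NOISE}) == 3
        assert (labels == NOISE).sum() > 0

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            cluster_users(_blocks(rng, np.eye(3)), "spectral")


class TestScores:
    def brute_scores(self, X, labels):
        ks = sorted(set(labels))
        n, k = len(X), len(ks)
        centroids = {c: X[labels == c].mean(axis=0) for c in ks}
        grand = X.mean(axis=0)
        within = sum(((X[labels == c] - centroids[c]) ** 2).sum() for c in ks)
        between = sum((labels == c).sum() * ((centroids[c] - grand) ** 2).sum() for c in ks)
        ch = (between / (k - 1)) / (within / (n - k))
        scatter = {
            c: np.mean(np.linalg.norm(X[labels == c] - centroids[c], axis=1)) for c in ks
        }
        db = np.mean(
            [
                max(
                    (scatter[i] + scatter[j]) / np.linalg.norm(centroids[i] - centroids[j])
                    for j in ks
                    if j != i
                )
                for i in ks
            ]
        )
        return ch, db

    def test_far_tight_clusters_limit(self, rng):
        B = _blocks(rng, np.eye(3)[:2], n_per=20, spread=0.005)
        s = score_clustering(B, np.repeat([0, 1], 20))
        assert s.silhouette > 0.97 and s.davies_bouldin < 0.05

    def test_metrics_match_brute_force_oracles(self, rng):
        X = rng.dirichlet(np.ones(3), 10)
        labels = np.array([0, 1, 0, 1, 0, 1, 1, 0, 0, 1])
        B = UserProportionMatrix(X, np.arange(10).astype(str), list("abc"))
        s = score_clustering(B, labels)
        ch, db = self.brute_scores(X, labels)
        assert s.calinski_harabasz == pytest.approx(ch)
        assert s.davies_bouldin == pytest.approx(db)
        from test_daytypes import brute_silhouette

        assert s.silhouette == pytest.approx(brute_silhouette(X, labels).mean())

    def test_noise_excluded_from_scoring(self, rng):
        B = _blocks(rng, np.eye(3)[:2], n_per=10, spread=0.01)
        labels = np.repeat([0, 1], 10)
        withnoise = np.concatenate([labels, [NOISE] * 5])
        B2 = UserProportionMatrix(
            np.vstack([B.values, rng.dirichlet(np.ones(3), 5)]),
            np.arange(25).astype(str),
            B.type_names,
        )
        s1 = score_clustering(B, labels)
        s2 = score_clustering(B2, withnoise)
        assert s1.silhouette == pytest.approx(s2.silhouette)

    def test_better_split_increases_ch(self, rng):
        B = _blocks(rng, np.eye(3)[:2], n_per=20, spread=0.02)
        good = np.repeat([0, 1], 20)
        bad = good.copy()
        bad[:5] = 1  # misassign a few
        assert (
            score_clustering(B, good).calinski_harabasz
            > score_clustering(B, bad).calinski_harabasz
        )


class TestMethodSelection:
    def test_sweep_winner(self):
        scores = {
            "a": ClusterScore(0.9, 0.2, 100.0),
            "b": ClusterScore(0.5, 0.8, 50.0),
        }
        assert select_method(scores) == "a"

    def test_reported_score_table_awards_density_method(self):
        # the published internal-validation table: the density method wins 3-0
        scores = {
            "kmeans": ClusterScore(0.4539, 0.8267, 18473),
            "agglomerative_ward_euclidean": ClusterScore(0.4264, 0.7169, 13732),
            "agglomerative_average_correlation": ClusterScore(0.6400, 0.6001, 35802),
            "density_hierarchical_correlation": ClusterScore(0.7604, 0.4176, 70327),
        }
        assert select_method(scores) == "density_hierarchical_correlation"

    def test_two_vs_one_majority(self):
        scores = {
            "a": ClusterScore(0.9, 0.9, 10.0),  # wins silhouette
            "b": ClusterScore(0.5, 0.2, 100.0),  # wins DB and CH
        }
        assert select_method(scores) == "b"

    def test_order_invariance(self):
        scores = {
            "a": ClusterScore(0.9, 0.2, 100.0),
            "b": ClusterScore(0.5, 0.8, 50.0),
            "c": ClusterScore(0.7, 0.5, 75.0),
        }
        rev = dict(reversed(list(scores.items())))
        assert select_method(scores) == select_method(rev)


class TestGroupSummaries:
    def test_identical_rows_zero_ci(self):
        X = np.tile([0.6, 0.2, 0.2], (8, 1))
        B = UserProportionMatrix(X, np.arange(8).astype(str),
                                 ["full_day", "afternoon", "sporadic_evening"])
        g = summarize_groups(B, np.zeros(8, dtype=int))
        assert g.loc[0, "ci95_full_day"] == 0.0
        assert g.loc[0, "predominant_type"] == "full_day"

    def test_sizes_partition_non_noise_users(self, rng):
        B = _blocks(rng, np.eye(3), n_per=15)
        labels = np.repeat([0, 1, 2], 15)
        labels[:4] = NOISE
        g = summarize_groups(B, labels)
        assert g["size"].sum() == 45 - 4
        assert g.attrs["n_noise"] == 4


class TestSegmentationModel:
    def test_fit_selects_winner_and_summarizes(self, rng):
        B = _blocks(rng, np.eye(3), n_per=40)
        res = UserSegmentation(B, min_cluster_fraction=0.2, seed=0).fit()
        assert res.winner in METHODS
        assert set(res.scores) == set(METHODS)
        assert len(res.groups) >= 2
        assert "winner" in res.summary()
        table = res.label_table()
        assert set(table["method"]) == set(METHODS)
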