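"""Clustering users on their day-type proportion vectors.

Each user is represented by the proportion of their retained days spent in
each day type (matrix B, rows on the probability simplex).  Four clustering
techniques are compared — k-means, Ward-linkage agglomerative on Euclidean
distance, average-linkage agglomerative on Pearson-correlation distance,
and hierarchical density-based clustering (HDBSCAN) on correlation
distance, which may label sparse users as noise (-1).  Each solution is
scored with three internal validation metrics (silhouette,
Davies-Bouldin, Calinski-Harabasz) and the method winning the majority of
metrics is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN, AgglomerativeClustering, KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

NOISE = -1
METHODS = (
    "kmeans",
    "agglomerative_ward_euclidean",
    "agglomerative_average_correlation",
    "density_hierarchical_correlation",
)
#: density-method minimum cluster size as a fraction of the cohort
#: (the study used 1,000 of 15,905 users)
DEFAULT_MIN_CLUSTER_FRACTION = 1000 / 15905


@dataclass
class UserProportionMatrix:
    """Matrix B: per-user day-type proportions (rows sum to 1)."""

    values: np.ndarray  # (n_users, n_day_types)
    user_ids: np.ndarray
    type_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of B must sum to 1")

    @property
    def n_users(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.type_names)
        out.insert(0, "user_id", self.user_ids)
        return out


@dataclass
class ClusterScore:
    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float


def build_user_proportions(
    day_table: pd.DataFrame, type_names: list[str] | None = None
) -> tuple[UserProportionMatrix, list]:
    """Per-user day-type proportions from the labelled day table.

    ``day_table`` needs columns user_id, cluster and kept; only days kept
    after outlier trimming enter the denominators.  Users with no retained
    day are dropped and reported.
    """
    kept = day_table[day_table["kept"].astype(bool)]
    dropped = sorted(set(day_table["user_id"]) - set(kept["user_id"]))
    counts = (
        kept.groupby(["user_id", "cluster"]).size().unstack(fill_value=0).sort_index()
    )
    k = int(day_table["cluster"].max()) + 1
    counts = counts.reindex(columns=range(k), fill_value=0)
    values = counts.to_numpy(dtype=float)
    values /= values.sum(axis=1, keepdims=True)
    names = type_names if type_names is not None else [f"type_{i}" for i in range(k)]
    return (
        UserProportionMatrix(values, counts.index.to_numpy(), list(names)),
        dropped,
    )


def correlation_distance(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson r between rows.

    Rows are centered before correlating; a constant row (zero variance)
    has undefined correlation and is assigned distance 1 to every other
    row (0 to itself).
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 1e-12
    safe = np.where(ok, norms, 1.0)
    U = Xc / safe[:, None]
    D = 1.0 - U @ U.T
    D[~ok, :] = 1.0
    D[:, ~ok] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def cluster_users(
    B: UserProportionMatrix | np.ndarray,
    method: str,
    n_clusters: int = 3,
    min_cluster_fraction: float = DEFAULT_MIN_CLUSTER_FRACTION,
    seed: int = 0,
) -> np.ndarray:
    """Cluster proportion rows with one of the four techniques.

    k-means and the agglomerative methods return exactly ``n_clusters``
    clusters; the density-hierarchical method infers the count and may
    label users as noise (-1), with its minimum cluster size scaled as
    ``min_cluster_fraction`` of the cohort.
    """
    X = B.values if isinstance(B, UserProportionMatrix) else np.asarray(B, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("B is empty")
    if method == "kmeans":
        return KMeans(
            n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed
        ).fit_predict(X)
    if method == "agglomerative_ward_euclidean":
        return AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(X)
    if method == "agglomerative_average_correlation":
        return AgglomerativeClustering(
            n_clusters=n_clusters, metric="precomputed", linkage="average"
        ).fit_predict(correlation_distance(X))
    if method == "density_hierarchical_correlation":
        mcs = max(2, int(round(min_cluster_fraction * X.shape[0])))
        return HDBSCAN(min_cluster_size=mcs, metric="precomputed", copy=True).fit_predict(
            correlation_distance(X)
        )
    raise ValueError(f"unknown clustering method {method!r}")


def score_clustering(
    B: UserProportionMatrix | np.ndarray, labels: np.ndarray
) -> ClusterScore:
    """Three internal validation metrics, computed on non-noise users only."""
    X = B.values if isinstance(B, UserProportionMatrix) else np.asarray(B, dtype=float)
    labels = np.asarray(labels)
    mask = labels != NOISE
    X, labels = X[mask], labels[mask]
    if len(np.unique(labels)) < 2:
        raise ValueError("scoring needs at least 2 non-noise clusters")
    return ClusterScore(
        silhouette=float(silhouette_score(X, labels)),
        davies_bouldin=float(davies_bouldin_score(X, labels)),
        calinski_harabasz=float(calinski_harabasz_score(X, labels)),
    )


def select_method(scores: dict[str, ClusterScore]) -> str:
    """Pick the method winning the majority of the three metrics.

    Higher silhouette, lower Davies-Bouldin, higher Calinski-Harabasz each
    award one win; a three-way tie is broken by the silhouette score.
    Order-invariant: methods are compared on values, not insertion order.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 scored methods")
    wins = {m: 0 for m in scores}
    wins[max(scores, key=lambda m: scores[m].silhouette)] += 1
    wins[min(scores, key=lambda m: scores[m].davies_bouldin)] += 1
    wins[max(scores, key=lambda m: scores[m].calinski_harabasz)] += 1
    best = max(wins.values())
    leaders = sorted(m for m, w in wins.items() if w == best)
    if len(leaders) == 1:
        return leaders[0]
    return max(leaders, key=lambda m: scores[m].silhouette)


def summarize_groups(
    B: UserProportionMatrix, labels: np.ndarray
) -> pd.DataFrame:
    """Per-group size, mean proportion vector with 95% CI, predominant type."""
    labels = np.asarray(labels)
    rows = []
    for g in sorted(set(labels) - {NOISE}):
        block = B.values[labels == g]
        mean = block.mean(axis=0)
        sem = block.std(axis=0, ddof=1) / np.sqrt(len(block)) if len(block) > 1 else np.zeros_like(mean)
        row = {"group": g, "size": len(block),
               "predominant_type": B.type_names[int(np.argmax(mean))],
               "predominant_proportion": float(mean.max())}
        for j, name in enumerate(B.type_names):
            row[f"mean_{name}"] = mean[j]
            row[f"ci95_{name}"] = 1.96 * sem[j]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_noise"] = int((labels == NOISE).sum())
    return out


class UserSegmentation:
    """User-group model over the proportion matrix B.

    Fits the requested clustering methods, scores each with the three
    internal metrics, and selects the winner by majority of metric wins.
    """

    def __init__(
        self,
        B: UserProportionMatrix,
        methods: tuple[str, ...] = METHODS,
        n_clusters: int = 3,
        min_cluster_fraction: float = DEFAULT_MIN_CLUSTER_FRACTION,
        seed: int = 0,
    ):
        self.B = B
        self.methods = methods
        self.n_clusters = n_clusters
        self.min_cluster_fraction = min_cluster_fraction
        self.seed = seed

    def fit(self) -> "UserSegmentationResults":
        labels = {}
        scores = {}
        for m in self.methods:
            labels[m] = cluster_users(
                self.B,
                m,
                n_clusters=self.n_clusters,
                min_cluster_fraction=self.min_cluster_fraction,
                seed=self.seed,
            )
            try:
                scores[m] = score_clustering(self.B, labels[m])
            except ValueError as err:  # degenerate solution: unscorable, not fatal
                warnings.warn(f"{m} produced an unscorable solution: {err}")
        if not scores:
            raise ValueError("no clustering method produced a scorable solution")
        winner = select_method(scores) if len(scores) > 1 else next(iter(scores))
        return UserSegmentationResults(
            self.B, labels, scores, winner, summarize_groups(self.B, labels[winner])
        )


@dataclass
class UserSegmentationResults:
    B: UserProportionMatrix
    labels: dict[str, np.ndarray]
    scores: dict[str, ClusterScore]
    winner: str
    groups: pd.DataFrame

    @property
    def winning_labels(self) -> np.ndarray:
        return self.labels[self.winner]

    def label_table(self) -> pd.DataFrame:
        frames = []
        for m, lab in self.labels.items():
            frames.append(
                pd.DataFrame(
                    {
                        "user_id": self.B.user_ids,
                        "method": m,
                        "group": lab,
                        "is_noise": (lab == NOISE).astype(int),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [
            f"User clustering on B ({self.B.n_users} users x {len(self.B.type_names)} day types)",
            "-" * 60,
            f"{'method':35s} {'silh':>7s} {'DB':>7s} {'CH':>10s}",
        ]
        for m, s in self.scores.items():
            star = " *" if m == self.winner else ""
            lines.append(
                f"{m:35s} {s.silhouette:7.4f} {s.davies_bouldin:7.4f} "
                f"{s.calinski_harabasz:10.0f}{star}"
            )
        lines.append(f"winner: {self.winner}")
        noise = self.groups.attrs.get("n_noise", 0)
        for r in self.groups.itertuples(index=False):
            lines.append(
                f"  group {r.group}: {r.size} users, predominant "
                f"{r.predominant_type} ({r.predominant_proportion:.2f})"
            )
        lines.append(f"  noise users: {noise}")
        return "\n".join(lines)
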