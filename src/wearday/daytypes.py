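"""Clustering days of hearing-aid use into typical day types.

Days (rows of A, 18 hourly minutes) are clustered with k-means using
k-means++ seeding; k is chosen by the elbow of the WSS/TSS curve; the
solution is evaluated with silhouette coefficients and a 2-component PCA;
per-cluster outliers (days abnormally far from their centroid under the
1.5*IQR fence rule) are trimmed; clusters are named full_day / afternoon /
sporadic_evening from their centroids; and the day-type vs weekday
association is measured with a chi-squared test and Cramer's V.

Features are raw minutes/hour, unscaled: all 18 share the same unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .preprocess import DayUseMatrix
from .simulate import HOURS


def total_sum_of_squares(X: np.ndarray) -> float:
    return float(((X - X.mean(axis=0)) ** 2).sum())


@dataclass
class DayClusterModel:
    """Fitted day-type clustering: centroids, labels, elbow curve, trimming."""

    k: int
    centroids: np.ndarray  # (k, 18) minutes/hour
    labels: np.ndarray  # cluster id per row of A
    wss: float
    wss_tss_curve: dict[int, float] = field(default_factory=dict)
    keep_mask: np.ndarray | None = None
    type_names: list[str] | None = None

    def name_of(self, label: int) -> str:
        return self.type_names[label] if self.type_names else f"type_{label}"


@dataclass
class WeekdayAssociation:
    chi2: float
    p_value: float
    cramers_v: float
    table: pd.DataFrame  # weekend (False/True) x day type counts


def cluster_days(
    A: DayUseMatrix | np.ndarray, k: int, seed: int = 0, n_restarts: int = 10
) -> DayClusterModel:
    """k-means++ with ``n_restarts`` restarts, best solution by WSS."""
    X = A.values if isinstance(A, DayUseMatrix) else np.asarray(A, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k:
        raise ValueError(f"cannot form {k} clusters from {X.shape[0]} rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return DayClusterModel(
        k=k, centroids=km.cluster_centers_.copy(), labels=labels, wss=float(km.inertia_)
    )


def select_k_elbow(
    A: DayUseMatrix | np.ndarray,
    k_range: range | tuple = range(1, 9),
    ratio_threshold: float = 0.5,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, dict[int, float]]:
    """Choose k at the elbow of the WSS/TSS curve.

    A candidate k qualifies when the next marginal decrease in WSS/TSS
    falls below ``ratio_threshold`` times the decrease just achieved —
    adding another cluster stops paying off.  Among qualifying candidates
    the sharpest kink wins: the k maximizing the drop factor
    (decrease at k) / (decrease at k+1).  The full curve is returned so
    the choice can be overridden manually.
    """
    X = A.values if isinstance(A, DayUseMatrix) else np.asarray(A, dtype=float)
    ks = sorted(k_range)
    if ks[0] != 1 or ks != list(range(1, len(ks) + 1)):
        raise ValueError("k_range must be contiguous starting at 1")
    tss = total_sum_of_squares(X)
    curve: dict[int, float] = {}
    for k in ks:
        curve[k] = cluster_days(X, k, seed=seed, n_restarts=n_restarts).wss / tss if tss > 0 else 0.0
    return elbow_from_curve(curve, ratio_threshold), curve


def elbow_from_curve(curve: dict[int, float], ratio_threshold: float = 0.5) -> int:
    """Apply the elbow rule to an already computed WSS/TSS curve."""
    ks = sorted(curve)
    if len(ks) == 1:
        return 1
    drops = {k: curve[k - 1] - curve[k] for k in ks[1:]}
    if drops[ks[1]] < 1e-12:
        warnings.warn("flat WSS/TSS curve; defaulting to k=1")
        return 1
    qualifying = [
        k
        for k in ks[1:-1]
        if drops[k] > 1e-12 and drops[k + 1] < ratio_threshold * drops[k]
    ]
    if not qualifying:
        warnings.warn("no elbow within k_range; returning the largest k")
        return ks[-1]
    return max(qualifying, key=lambda k: drops[k] / max(drops[k + 1], 1e-12))


def silhouette_profile(
    A: DayUseMatrix | np.ndarray,
    labels: np.ndarray,
    subsample: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-observation silhouette coefficients and their mean.

    Pairwise distances are quadratic in n, so for large inputs an optional
    uniform subsample (stratification-free) bounds the cost; coefficients
    are then reported for the sampled rows only.
    """
    X = A.values if isinstance(A, DayUseMatrix) else np.asarray(A, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if subsample is not None and X.shape[0] > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.shape[0], size=subsample, replace=False)
        X, labels = X[idx], labels[idx]
    coeffs = silhouette_samples(X, labels)
    return coeffs, float(coeffs.mean())


def project_pca(A: DayUseMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-component PCA of the centered day matrix.

    Returns (scores, loadings, explained_variance_ratio); each loading
    vector is sign-fixed so its largest-magnitude entry is positive.
    """
    X = A.values if isinstance(A, DayUseMatrix) else np.asarray(A, dtype=float)
    n_comp = min(2, X.shape[0] - 1, X.shape[1]) if X.shape[0] > 1 else 1
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for i in range(loadings.shape[0]):
        if loadings[i, np.argmax(np.abs(loadings[i]))] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    return scores, loadings, pca.explained_variance_ratio_


def trim_cluster_outliers(
    A: DayUseMatrix | np.ndarray, model: DayClusterModel
) -> np.ndarray:
    """Mask of days kept after per-cluster IQR trimming.

    Within each cluster, a day is an outlier if its Euclidean distance to
    the cluster centroid lies outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of that
    cluster's distance distribution (closed interval, so clusters of
    identical points keep everything).
    """
    X = A.values if isinstance(A, DayUseMatrix) else np.asarray(A, dtype=float)
    keep = np.ones(X.shape[0], dtype=bool)
    for c in range(model.k):
        members = np.nonzero(model.labels == c)[0]
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - model.centroids[c], axis=1)
        q1, q3 = np.percentile(d, [25, 75])
        iqr = q3 - q1
        keep[members] = (d >= q1 - 1.5 * iqr - 1e-12) & (d <= q3 + 1.5 * iqr + 1e-12)
    return keep


MORNING_HOURS = slice(1, 5)  # clock hours 7..10 within the 6..23 grid


def name_day_types(centroids: np.ndarray) -> list[str]:
    """Semantic names from centroid shapes (only defined for k=3).

    sporadic_evening has the smallest total use; of the remaining two, the
    one with morning (7:00-10:59) mass is full_day, the other afternoon.
    For k != 3 generic names type_0..type_{k-1} are returned.
    """
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    if k != 3:
        return [f"type_{i}" for i in range(k)]
    totals = centroids.sum(axis=1)
    names = [""] * 3
    order = np.argsort(totals)
    names[order[0]] = "sporadic_evening"
    rest = order[1:]
    morning = centroids[rest, MORNING_HOURS].sum(axis=1)
    full = rest[np.argmax(morning)]
    names[full] = "full_day"
    names[rest[rest != full][0]] = "afternoon"
    return names


def weekday_association(labels: np.ndarray, dates: pd.Series) -> WeekdayAssociation:
    """Chi-squared independence test of day type vs weekend, with Cramer's V."""
    dates = pd.to_datetime(pd.Series(np.asarray(dates)))
    weekend = dates.dt.dayofweek >= 5
    table = pd.crosstab(weekend.to_numpy(), np.asarray(labels))
    chi2, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    n = table.to_numpy().sum()
    m = min(table.shape[0] - 1, table.shape[1] - 1)
    v = float(np.sqrt(chi2 / (n * m))) if m > 0 else 0.0
    return WeekdayAssociation(float(chi2), float(p), v, table)


def match_clusters_to_templates(
    centroids: np.ndarray, templates: dict[str, "object"]
) -> dict[int, str]:
    """Assign each cluster the nearest archetype template (Hungarian matching)."""
    from scipy.optimize import linear_sum_assignment

    names = list(templates)
    T = np.vstack([templates[n].mean_curve for n in names])
    D = np.linalg.norm(centroids[:, None, :] - T[None, :, :], axis=2)
    if centroids.shape[0] == T.shape[0]:
        rows, cols = linear_sum_assignment(D)
        return {int(r): names[c] for r, c in zip(rows, cols)}
    return {int(i): names[int(j)] for i, j in enumerate(D.argmin(axis=1))}


class DayTypeKMeans:
    """Day-type discovery model over the day matrix A.

    Parameters
    ----------
    A : DayUseMatrix
        The preprocessed day-by-hour matrix.
    k : int or "auto"
        Number of day types; "auto" selects k by the elbow rule.
    """

    def __init__(
        self,
        A: DayUseMatrix,
        k: int | str = "auto",
        k_range: range = range(1, 9),
        elbow_ratio_threshold: float = 0.5,
        n_restarts: int = 10,
        seed: int = 0,
        silhouette_subsample: int | None = 5000,
    ):
        self.A = A
        self.k = k
        self.k_range = k_range
        self.elbow_ratio_threshold = elbow_ratio_threshold
        self.n_restarts = n_restarts
        self.seed = seed
        self.silhouette_subsample = silhouette_subsample

    def fit(self) -> "DayTypeResults":
        curve: dict[int, float] = {}
        if self.k == "auto":
            k, curve = select_k_elbow(
                self.A,
                self.k_range,
                self.elbow_ratio_threshold,
                seed=self.seed,
                n_restarts=self.n_restarts,
            )
        else:
            k = int(self.k)
        model = cluster_days(self.A, k, seed=self.seed, n_restarts=self.n_restarts)
        model.wss_tss_curve = curve
        model.keep_mask = trim_cluster_outliers(self.A, model)
        model.type_names = name_day_types(model.centroids)
        sil_mean = np.nan
        if k >= 2:
            _, sil_mean = silhouette_profile(
                self.A, model.labels, subsample=self.silhouette_subsample, seed=self.seed
            )
        assoc = weekday_association(
            model.labels[model.keep_mask],
            self.A.index["date"].to_numpy()[model.keep_mask],
        )
        return DayTypeResults(self.A, model, sil_mean, assoc)


@dataclass
class DayTypeResults:
    """Fitted day types: labels, trimming mask, quality scores."""

    A: DayUseMatrix
    model: DayClusterModel
    silhouette_mean: float
    weekday: WeekdayAssociation

    @property
    def labels(self) -> np.ndarray:
        return self.model.labels

    @property
    def keep_mask(self) -> np.ndarray:
        return self.model.keep_mask

    def day_table(self) -> pd.DataFrame:
        out = self.A.index.reset_index(drop=True).copy()
        out["cluster"] = self.model.labels
        out["type_name"] = [self.model.name_of(c) for c in self.model.labels]
        out["kept"] = self.model.keep_mask.astype(int)
        return out

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Day-type clustering (k-means++, k={m.k})",
            "-" * 44,
            f"days: {self.A.n_days}  retained after trimming: {int(m.keep_mask.sum())}",
            f"WSS/TSS: {m.wss / total_sum_of_squares(self.A.values):.3f}   "
            f"mean silhouette: {self.silhouette_mean:.3f}",
        ]
        counts = np.bincount(m.labels[m.keep_mask], minlength=m.k)
        for c in range(m.k):
            share = counts[c] / counts.sum() * 100
            total = m.centroids[c].sum() / 60
            lines.append(
                f"  {m.name_of(c):17s} {counts[c]:7d} days ({share:4.1f}%), "
                f"centroid total {total:4.1f} h"
            )
        w = self.weekday
        lines.append(
            f"weekday association: chi2={w.chi2:.1f}, p={w.p_value:.2e}, V={w.cramers_v:.3f}"
        )
        return "\n".join(lines)

    def plot_centroids(self, ax=None):
        """Hourly centroid profiles per day type (quick-look figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c in range(self.model.k):
            ax.plot(HOURS, self.model.centroids[c], label=self.model.name_of(c))
        ax.set_xlabel("clock hour")
        ax.set_ylabel("minutes of use per hour")
        ax.legend()
        return ax
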