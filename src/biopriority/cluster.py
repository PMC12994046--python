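"""Patient stratification: Gower dissimilarity, K-means / k-medoids, K
selection, cluster labeling by mean score, PCA projection, and a
centroid-separation permutation test.

Two clustering geometries are offered.  The default runs Lloyd's K-means
(k-means++ seeding, multiple restarts, per-iteration objective trace) on the
normalized alpha profiles, which are all numeric in [0, 1] so squared
Euclidean distance is well defined.  The alternative runs PAM k-medoids on a
Gower dissimilarity matrix, which respects the mixed ordinal / categorical /
continuous nature of the raw variables.  Centroid-based K-means is not
defined on Gower dissimilarities, hence the explicit two-mode design.

Cluster separation is assessed with a permutation test on a Wilks'-lambda
style statistic det(W)/det(W+B) (within / between scatter), avoiding the
multivariate-normal assumptions of parametric MANOVA at small N, plus
Mahalanobis distances between centroids under the pooled within-cluster
covariance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import mahalanobis
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.utils import check_random_state

from biopriority.registry import VariableRegistry
from biopriority.scoring import PriorityLabeling


# ---------------------------------------------------------------------------
# Gower dissimilarity
# ---------------------------------------------------------------------------

def gower_matrix(
    data: pd.DataFrame,
    registry: VariableRegistry | None = None,
    numeric_range: float | dict | None = None,
) -> pd.DataFrame:
    """Gower dissimilarity between all patient pairs.

    Per-variable dissimilarity: numeric -> |x_p - x_q| / range; ordinal ->
    absolute difference of rank-normalized level positions; categorical /
    binary -> 0/1 mismatch.  The Gower dissimilarity is the unweighted mean
    over variables, in [0, 1].

    The range of a registry continuous variable is its declared domain
    width; for plain numeric columns (``registry=None``, e.g. the alpha
    matrix) it is the observed range unless ``numeric_range`` (a scalar, or
    a per-column dict) supplies a known scale.  A numeric variable with zero
    range contributes 0 and is flagged with a warning.
    """
    n = len(data)
    parts = []
    for col in data.columns:
        kind = "numeric" if registry is None else registry[col].kind
        values = data[col]
        if kind in ("continuous", "numeric"):
            x = values.to_numpy(dtype=float)
            if kind == "continuous":
                lo, hi = registry[col].domain  # type: ignore[union-attr, misc]
                rng = hi - lo
            elif isinstance(numeric_range, dict):
                rng = numeric_range.get(col, x.max() - x.min())
            elif numeric_range is not None:
                rng = float(numeric_range)
            else:
                rng = x.max() - x.min()
            if rng == 0:
                warnings.warn(f"variable {col!r} has zero range; contributes 0 to Gower")
                parts.append(np.zeros((n, n)))
                continue
            parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        elif kind == "ordinal":
            levels = list(registry[col].levels)  # type: ignore[union-attr]
            pos = values.map({lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=float)
            denom = max(len(levels) - 1, 1)
            pos = pos / denom
            parts.append(np.abs(pos[:, None] - pos[None, :]))
        else:  # categorical / binary -> mismatch indicator
            x = values.to_numpy()
            parts.append((x[:, None] != x[None, :]).astype(float))
    dis = np.mean(parts, axis=0)
    np.fill_diagonal(dis, 0.0)
    return pd.DataFrame(dis, index=data.index, columns=data.index)


# ---------------------------------------------------------------------------
# K-means (Lloyd) and PAM k-medoids
# ---------------------------------------------------------------------------

def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """Lloyd iterations from given centers; returns per-iteration objective.

    Empty clusters are re-seeded at the point farthest from its assigned
    center. The objective (total within-cluster sum of squares) is recorded
    after each assignment step and is non-increasing.
    """
    k = centers.shape[0]
    path: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # re-seed empty clusters at the farthest point from its center
        for kk in range(k):
            if not np.any(labels == kk):
                far = d2[np.arange(len(X)), labels].argmax()
                centers[kk] = X[far]
                d2[:, kk] = ((X - centers[kk]) ** 2).sum(axis=1)
                labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(X)), labels].sum())
        path.append(obj)
        new_centers = np.stack([X[labels == kk].mean(axis=0) for kk in range(k)])
        shift = float(((new_centers - centers) ** 2).sum())
        centers = new_centers
        if shift <= tol:
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    obj = float(d2[np.arange(len(X)), labels].sum())
    path.append(obj)
    return labels, centers, obj, it, path


def _pam(
    D: np.ndarray, k: int, rng: np.random.RandomState, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM (BUILD + SWAP) k-medoids on a precomputed dissimilarity matrix."""
    n = D.shape[0]
    # BUILD: greedy medoid selection minimizing total dissimilarity
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    medoids_arr = np.array(medoids)
    # SWAP until no improving swap
    for _ in range(max_iter):
        assign = D[:, medoids_arr].argmin(axis=1)
        cost = float(D[np.arange(n), medoids_arr[assign]].sum())
        best = (cost, None)
        for mi in range(k):
            for j in range(n):
                if j in medoids_arr:
                    continue
                cand = medoids_arr.copy()
                cand[mi] = j
                c = float(D[:, cand].min(axis=1).sum())
                if c < best[0] - 1e-12:
                    best = (c, cand)
        if best[1] is None:
            break
        medoids_arr = best[1]
    assign = D[:, medoids_arr].argmin(axis=1)
    cost = float(D[np.arange(n), medoids_arr[assign]].sum())
    return assign, medoids_arr, cost


class PriorityKMeans(BaseEstimator, ClusterMixin):
    """K-way patient stratification on normalized profiles or Gower matrix.

    Parameters
    ----------
    n_clusters : int, default 3
        K; three clusters map onto High/Medium/Low priority groups.
    mode : {"euclidean", "gower"}, default "euclidean"
        "euclidean": Lloyd K-means on an (n_patients, n_vars) profile matrix.
        "gower": PAM k-medoids on a precomputed square dissimilarity matrix.
    n_init : int, default 10
        Restarts (k-means++ seedings) in euclidean mode; best objective kept.
    max_iter : int, default 300
    tol : float, default 1e-6
        Squared-center-shift convergence threshold.
    random_state : int or None

    Attributes
    ----------
    labels_ : ndarray of shape (n_patients,)
    cluster_centers_ : ndarray (euclidean mode) — per Eq.-style centroid
        definition each center is the mean of its members' profiles.
    medoid_indices_ : ndarray (gower mode)
    inertia_ : float
        Total within-cluster sum of squared distances (euclidean) or summed
        dissimilarity to medoids (gower).
    objective_path_ : list of float
        Objective after each Lloyd assignment step of the best restart;
        non-increasing.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        mode: str = "euclidean",
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.mode = mode
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None) -> "PriorityKMeans":
        rng = check_random_state(self.random_state)
        X = np.asarray(X, dtype=float)
        if self.mode == "euclidean":
            n_distinct = len(np.unique(X, axis=0))
            if self.n_clusters > n_distinct:
                raise ValueError(
                    f"K = {self.n_clusters} exceeds the {n_distinct} distinct profiles"
                )
            best = None
            for _ in range(self.n_init):
                seed_centers, _ = kmeans_plusplus(
                    X, self.n_clusters, random_state=rng.randint(0, 2**31 - 1)
                )
                labels, centers, obj, n_iter, path = _lloyd(
                    X, seed_centers.copy(), self.max_iter, self.tol
                )
                if best is None or obj < best[2] - 1e-12:
                    best = (labels, centers, obj, n_iter, path)
            labels, centers, obj, n_iter, path = best
            self.labels_ = labels
            self.cluster_centers_ = centers
            self.inertia_ = obj
            self.n_iter_ = n_iter
            self.objective_path_ = path
        elif self.mode == "gower":
            if X.shape[0] != X.shape[1]:
                raise ValueError("gower mode expects a square dissimilarity matrix")
            if self.n_clusters > X.shape[0]:
                raise ValueError("K exceeds the number of patients")
            labels, medoids, cost = _pam(X, self.n_clusters, rng, self.max_iter)
            self.labels_ = labels
            self.medoid_indices_ = medoids
            self.inertia_ = cost
            self.objective_path_ = [cost]
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def predict(self, X) -> np.ndarray:
        if self.mode != "euclidean":
            raise ValueError("predict is only available in euclidean mode")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmeans_cluster(
    X,
    n_clusters: int = 3,
    mode: str = "euclidean",
    seed: int | None = None,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> PriorityKMeans:
    """Thin functional wrapper over :class:`PriorityKMeans`."""
    return PriorityKMeans(
        n_clusters=n_clusters,
        mode=mode,
        n_init=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(X)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------

@dataclass
class KSelection:
    table: pd.DataFrame  # columns: K, objective, silhouette
    recommended_k: int
    flags: list[str] = field(default_factory=list)


def select_k(
    X,
    k_range=range(2, 9),
    mode: str = "euclidean",
    seed: int | None = None,
    n_restarts: int = 10,
) -> KSelection:
    """Objective (elbow curve) and mean silhouette over a range of K.

    The silhouette uses the same geometry as the clustering: squared-
    Euclidean K-means pairs with Euclidean silhouette, Gower k-medoids with
    the precomputed dissimilarity. Recommended K is the silhouette argmax;
    singleton clusters get silhouette 0 for their lone member and are
    flagged.
    """
    X = np.asarray(X, dtype=float)
    flags: list[str] = []
    rows = []
    for k in k_range:
        model = kmeans_cluster(X, n_clusters=k, mode=mode, seed=seed, n_restarts=n_restarts)
        labels = model.labels_
        if mode == "gower":
            sil_vals = silhouette_samples(X, labels, metric="precomputed")
        else:
            if len(np.unique(X, axis=0)) <= k:
                raise ValueError("degenerate data: fewer distinct profiles than K")
            sil_vals = silhouette_samples(X, labels)
        counts = np.bincount(labels, minlength=k)
        if (counts == 1).any():
            flags.append(f"K={k}: singleton cluster (silhouette of that point set to 0)")
            sil_vals = sil_vals.copy()
            for kk in np.where(counts == 1)[0]:
                sil_vals[labels == kk] = 0.0
        rows.append({"K": k, "objective": model.inertia_, "silhouette": float(sil_vals.mean())})
    table = pd.DataFrame(rows)
    rec = int(table.loc[table["silhouette"].idxmax(), "K"])
    return KSelection(table=table, recommended_k=rec, flags=flags)


# ---------------------------------------------------------------------------
# cluster labeling by mean score
# ---------------------------------------------------------------------------

def label_clusters(model: PriorityKMeans, scores: pd.Series) -> PriorityLabeling:
    """Rank clusters by mean member score and label High/Medium/Low.

    With K = 3 the top-mean cluster is High, the middle Medium and the
    bottom Low; other K get ordinal labels P1 (highest mean) .. PK. Ties on
    the mean are broken by the higher maximum member score (warned).
    """
    labels = model.labels_
    k = int(labels.max()) + 1
    means = np.array([scores.to_numpy()[labels == kk].mean() for kk in range(k)])
    maxes = np.array([scores.to_numpy()[labels == kk].max() for kk in range(k)])
    if len(np.unique(np.round(means, 12))) < k:
        warnings.warn("tied cluster mean scores; breaking ties by max member score")
    order = np.lexsort((-maxes, -means))  # descending mean, then descending max
    if k == 3:
        names = ("High", "Medium", "Low")
    elif k == 1:
        names = ("Medium",)
    else:
        names = tuple(f"P{i + 1}" for i in range(k))
    cluster_to_label = {int(order[i]): names[i] for i in range(k)}
    lab = pd.Series(
        [cluster_to_label[int(c)] for c in labels], index=scores.index, name="label"
    )
    return PriorityLabeling(labels=lab, method="cluster", thresholds=(np.nan, np.nan))


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    coordinates: pd.DataFrame  # (n_patients, 2): pc1, pc2
    explained_variance_ratio: tuple[float, float]
    loadings: pd.DataFrame  # (n_vars, 2)
    rank_deficient: bool = False


def pca_project(alpha: pd.DataFrame) -> ProjectionResult:
    """Project the (patients x variables) alpha matrix onto its top-2 PCs.

    Columns are centered but not rescaled (alpha entries already share the
    [0, 1] scale). Sign convention: each component's largest-magnitude
    loading entry is positive. Rank-1 data yields a zero-variance second
    component, flagged rather than raised.
    """
    if len(alpha) < 3:
        raise ValueError("PCA projection needs at least 3 patients")
    X = alpha.to_numpy(dtype=float)
    pca = PCA(n_components=2, svd_solver="full")
    Z = pca.fit_transform(X)
    load = pca.components_.T.copy()  # (n_vars, 2)
    for j in range(2):
        i_max = np.abs(load[:, j]).argmax()
        if load[i_max, j] < 0:
            load[:, j] *= -1
            Z[:, j] *= -1
    evr = pca.explained_variance_ratio_
    rank_def = bool(np.isclose(pca.explained_variance_[1], 0.0))
    if rank_def:
        warnings.warn("data effectively rank-1; second component has zero variance")
    return ProjectionResult(
        coordinates=pd.DataFrame(Z, index=alpha.index, columns=["pc1", "pc2"]),
        explained_variance_ratio=(float(evr[0]), float(evr[1])),
        loadings=pd.DataFrame(load, index=alpha.columns, columns=["pc1", "pc2"]),
        rank_deficient=rank_def,
    )


# ---------------------------------------------------------------------------
# centroid-separation permutation test
# ---------------------------------------------------------------------------

@dataclass
class SeparationTest:
    statistic: float  # Wilks'-lambda-style det(W)/det(W+B)
    p_value: float
    n_permutations: int
    mahalanobis_distances: pd.DataFrame
    seed: int | None = None


def _scatter(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for kk in np.unique(labels):
        Xi = X[labels == kk]
        mu = Xi.mean(axis=0)
        C = Xi - mu
        W += C.T @ C
        d = (mu - grand)[:, None]
        B += len(Xi) * (d @ d.T)
    return W, B


def _wilks(X: np.ndarray, labels: np.ndarray, ridge: float) -> float:
    W, B = _scatter(X, labels)
    p = X.shape[1]
    Wr = W + ridge * np.eye(p)
    sign_w, logdet_w = np.linalg.slogdet(Wr)
    sign_t, logdet_t = np.linalg.slogdet(Wr + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("non-positive-definite scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


def separation_test(
    X,
    assignments: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    ridge: float = 1e-8,
) -> SeparationTest:
    """Permutation MANOVA on cluster separation plus centroid Mahalanobis
    distances.

    Statistic: Wilks'-lambda-style ratio det(W)/det(W+B); small values mean
    strong separation. p = (1 + #{permuted <= observed}) / (1 + B) over
    random label shuffles. Mahalanobis distances between centroids use the
    pooled within-cluster covariance, ridge-regularized if near-singular.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(assignments)
    uniq, labels = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("separation test needs K >= 2")
    counts = np.bincount(labels)
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 members")

    try:
        observed = _wilks(X, labels, ridge)
    except np.linalg.LinAlgError:
        var = X.var(axis=0)
        bad = [str(c) for c in np.where(var <= 1e-12)[0]]
        raise np.linalg.LinAlgError(
            f"singular pooled scatter even after ridge; deficient variables "
            f"(zero variance columns at indices): {bad}"
        )

    rng = np.random.default_rng(seed)
    count_le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _wilks(X, perm, ridge) <= observed:
            count_le += 1
    p = (1 + count_le) / (1 + n_permutations)

    # Mahalanobis distances between centroids, pooled within covariance
    W, _ = _scatter(X, labels)
    pooled = W / (len(X) - k)
    pooled += ridge * np.eye(X.shape[1])
    try:
        VI = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        var = np.diag(pooled)
        bad = [str(c) for c in np.where(var <= ridge * 2)[0]]
        raise np.linalg.LinAlgError(
            f"singular pooled covariance after regularization; deficient "
            f"variable indices: {bad}"
        )
    centroids = np.stack([X[labels == kk].mean(axis=0) for kk in range(k)])
    D = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        D[a, b] = D[b, a] = mahalanobis(centroids[a], centroids[b], VI)
    dist = pd.DataFrame(D, index=uniq, columns=uniq)
    return SeparationTest(
        statistic=observed,
        p_value=float(p),
        n_permutations=n_permutations,
        mahalanobis_distances=dist,
        seed=seed,
    )
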