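"""Direct-rating AHP weight aggregation, rater agreement, weight stability.

Seven (in the reference setting) physicians each score every decision
variable on a 0-10 relevance scale.  The weight of variable *i* is its share
of the total rating mass:

    w_i = (sum_m mu_im) / W,   W = sum_i sum_m mu_im,

so the weights are nonnegative and sum to one.  This is the direct-rating
variant of the analytic hierarchy process: no pairwise comparison matrices or
eigenvector consistency machinery are involved.

Inter-rater reliability is summarized by Cohen's kappa over all rater pairs
after discretizing the 0-10 scores into equal-width bins, and robustness of
the downstream prioritization to elicitation noise is probed by perturbing
each weight by +/-10% and measuring how many patients keep their priority
group and cluster.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


class RatingsError(ValueError):
    """Invalid expert rating matrix."""


@dataclass(frozen=True)
class WeightVector:
    """Normalized variable weights in registry order.

    Attributes
    ----------
    weights : pandas.Series
        One nonnegative weight per variable id; sums to 1 for weights
        aggregated from ratings. Weight tables transcribed from publications
        may carry rounding error; ``from_series`` accepts a sum within
        ``sum_tol`` of 1 without renormalizing.
    total_mass : float
        W, the total rating mass behind the weights (NaN when unknown).
    """

    weights: pd.Series
    total_mass: float = float("nan")

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < 0).any():
            raise RatingsError("weights must be nonnegative")

    @classmethod
    def from_series(cls, weights: pd.Series, sum_tol: float = 0.01) -> "WeightVector":
        total = float(weights.sum())
        if abs(total - 1.0) > sum_tol:
            raise RatingsError(f"weights sum to {total:.6f}, expected 1 +/- {sum_tol}")
        return cls(weights.astype(float))

    def __getitem__(self, var_id: str) -> float:
        return float(self.weights[var_id])

    def __len__(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.weights.round(6).rename("weight")
        out.index.name = "variable_id"
        out.to_csv(path)


def _validate_ratings(ratings: pd.DataFrame) -> np.ndarray:
    mat = ratings.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise RatingsError("rating matrix contains missing entries")
    if (mat < 0).any() or (mat > 10).any():
        raise RatingsError("ratings must lie in [0, 10]")
    return mat


def aggregate_weights(ratings: pd.DataFrame) -> WeightVector:
    """Aggregate an expert rating matrix into a normalized weight vector.

    Parameters
    ----------
    ratings : DataFrame
        Rows = variables (registry order), columns = raters, entries in
        [0, 10].

    Returns
    -------
    WeightVector
        ``w_i = row_sum_i / W`` with ``W`` the grand total; sums to 1.
    """
    mat = _validate_ratings(ratings)
    total = mat.sum()
    if total <= 0:
        raise RatingsError("degenerate ratings: all entries zero (W = 0)")
    w = mat.sum(axis=1) / total
    return WeightVector(pd.Series(w, index=ratings.index, name="weight"), total_mass=float(total))


def load_ratings(path: str | Path) -> pd.DataFrame:
    """Read a long-format ratings CSV (variable_id, rater_id, score) → wide."""
    df = pd.read_csv(path)
    need = {"variable_id", "rater_id", "score"}
    if not need.issubset(df.columns):
        raise RatingsError(f"ratings file must have columns {sorted(need)}")
    wide = df.pivot(index="variable_id", columns="rater_id", values="score")
    # preserve first-appearance variable order from the file
    order = df["variable_id"].drop_duplicates().tolist()
    return wide.loc[order]


def load_weights(path: str | Path, sum_tol: float = 0.01) -> WeightVector:
    """Read a weights CSV (variable_id, weight).

    Published weight tables are accepted as-is (no renormalization) provided
    they sum to 1 within ``sum_tol``, which absorbs printed rounding.
    """
    df = pd.read_csv(path)
    ser = pd.Series(df["weight"].to_numpy(dtype=float), index=df["variable_id"], name="weight")
    return WeightVector.from_series(ser, sum_tol=sum_tol)


# ---------------------------------------------------------------------------
# Cohen's kappa over rater pairs
# ---------------------------------------------------------------------------

def _bin_scores(scores: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize 0-10 scores into ``n_bins`` equal-width bins (0..n_bins-1)."""
    edges = np.linspace(0.0, 10.0, n_bins + 1)
    return np.clip(np.digitize(scores, edges[1:-1], right=False), 0, n_bins - 1)


def _cohen_kappa(a: np.ndarray, b: np.ndarray, n_bins: int) -> tuple[float, bool]:
    """(kappa, degenerate_flag); kappa = 1 by convention when p_e = 1."""
    n = len(a)
    p_o = float(np.mean(a == b))
    pa = np.bincount(a, minlength=n_bins) / n
    pb = np.bincount(b, minlength=n_bins) / n
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-12:
        return 1.0, True
    return (p_o - p_e) / (1.0 - p_e), False


@dataclass
class KappaResult:
    """Pairwise Cohen's kappa between raters on binned relevance scores."""

    kappa: pd.DataFrame
    mean_kappa: float
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)


def pairwise_kappa(ratings: pd.DataFrame, n_bins: int = 5) -> KappaResult:
    """Cohen's kappa for every rater pair, variables as items.

    Scores are discretized into ``n_bins`` equal-width bins on [0, 10]. A
    pair in which both raters are constant in the same bin has chance
    agreement 1; its kappa is defined as 1 and the pair is flagged.
    """
    if ratings.shape[1] < 2:
        raise RatingsError("kappa needs at least two raters")
    if n_bins < 2:
        raise RatingsError("n_bins must be >= 2")
    _validate_ratings(ratings)
    raters = list(ratings.columns)
    binned = {r: _bin_scores(ratings[r].to_numpy(dtype=float), n_bins) for r in raters}
    km = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    degenerate: list[tuple[str, str]] = []
    values = []
    for r1, r2 in itertools.combinations(raters, 2):
        k, flag = _cohen_kappa(binned[r1], binned[r2], n_bins)
        km.loc[r1, r2] = km.loc[r2, r1] = k
        if flag:
            degenerate.append((r1, r2))
        values.append(k)
    return KappaResult(kappa=km, mean_kappa=float(np.mean(values)), degenerate_pairs=degenerate)


# ---------------------------------------------------------------------------
# +/-10% weight-stability sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Outcome of the one-at-a-time weight perturbation analysis.

    ``per_perturbation`` has one row per (variable, direction) with the
    fraction of patients keeping their priority-group label and their cluster
    assignment; the ``fraction_*`` attributes aggregate over all 2 x n_vars
    perturbations.
    """

    per_perturbation: pd.DataFrame
    fraction_rank_stable: float
    fraction_cluster_stable: float


def _matched_cluster_agreement(base: np.ndarray, other: np.ndarray) -> float:
    """Fraction of identical assignments after optimally matching cluster ids."""
    k = int(max(base.max(), other.max())) + 1
    overlap = np.zeros((k, k))
    for b, o in zip(base, other):
        overlap[b, o] += 1
    rows, cols = linear_sum_assignment(-overlap)
    return float(overlap[rows, cols].sum() / len(base))


def weight_sensitivity(
    weights: WeightVector,
    alpha: pd.DataFrame,
    perturbation: float = 0.10,
    label_method: str = "tertile",
    n_clusters: int = 3,
    seed: int | None = 0,
    n_init: int = 10,
    cluster_on: str = "alpha",
) -> StabilityReport:
    """Perturb each weight by +/-``perturbation``, renormalize, re-run scoring
    and clustering, and measure label/cluster retention.

    Parameters
    ----------
    weights : WeightVector
        Baseline weights.
    alpha : DataFrame
        Normalized decision matrix, rows = patients, columns = variables.
    perturbation : float
        Relative perturbation size (default 0.10); must be < 1.
    label_method : {"tertile", "fixed"}
        How priority-group labels are assigned from scores.
    cluster_on : {"alpha", "weighted_alpha"}
        Clustering input. "alpha" clusters the normalized profiles (the
        default pipeline geometry), which makes cluster assignments
        weight-independent, so the informative stability fraction is the
        priority-label one. "weighted_alpha" clusters w_i * alpha_ip so the
        perturbation propagates into the cluster geometry as well.
    """
    from biopriority.cluster import PriorityKMeans
    from biopriority.scoring import assign_priority_labels, priority_score

    if not 0 <= perturbation < 1:
        raise ValueError(f"invalid perturbation {perturbation}; need 0 <= p < 1")
    if cluster_on not in ("alpha", "weighted_alpha"):
        raise ValueError(f"unknown cluster_on {cluster_on!r}")

    def run(wv: WeightVector) -> tuple[np.ndarray, np.ndarray]:
        scores = priority_score(wv, alpha)
        labels = assign_priority_labels(scores, method=label_method).labels.to_numpy()
        if cluster_on == "weighted_alpha":
            X = alpha.mul(wv.weights.reindex(alpha.columns), axis=1).to_numpy(dtype=float)
        else:
            X = alpha.to_numpy(dtype=float)
        km = PriorityKMeans(n_clusters=n_clusters, random_state=seed, n_init=n_init)
        clusters = km.fit(X).labels_
        return labels, clusters

    base_labels, base_clusters = run(weights)
    rows = []
    w0 = weights.weights
    for vid in w0.index:
        for direction in (+1, -1):
            w = w0.copy()
            w[vid] = w[vid] * (1 + direction * perturbation)
            w = w / w.sum()
            labels, clusters = run(WeightVector(w))
            rows.append(
                {
                    "variable_id": vid,
                    "direction": "+" if direction > 0 else "-",
                    "fraction_rank_stable": float(np.mean(labels == base_labels)),
                    "fraction_cluster_stable": _matched_cluster_agreement(
                        base_clusters, clusters
                    ),
                }
            )
    table = pd.DataFrame(rows)
    return StabilityReport(
        per_perturbation=table,
        fraction_rank_stable=float(table["fraction_rank_stable"].mean()),
        fraction_cluster_stable=float(table["fraction_cluster_stable"].mean()),
    )
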