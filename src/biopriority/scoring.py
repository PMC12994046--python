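"""Composite priority score s = w'alpha, contributions, priority labels.

The composite score of patient p is the weighted sum of their normalized
variable values, s_p = sum_i w_i * alpha_ip, with the AHP weights summing to
one.  Linearity makes the score traceable: the contribution of variable i is
exactly w_i * alpha_ip, and a change of d in one alpha entry moves the score
by w_i * d (e.g. with an urgency weight of 0.076, a 0.1 increase in the
normalized urgency value raises the score by 0.0076).

Labels: the empirical tertiles of the score distribution (or the fixed
operational thresholds 0.29 / 0.18 adopted in the reference ENT setting) map
patients to High / Medium / Low priority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from biopriority.weights import WeightVector

LABELS = ("High", "Medium", "Low")


@dataclass
class PriorityLabeling:
    """Per-patient High/Medium/Low labels plus the rule that produced them."""

    labels: pd.Series
    method: str
    thresholds: tuple[float, float]  # (high, low) boundaries actually used

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(LABELS, fill_value=0)


class PriorityScorer(BaseEstimator, TransformerMixin):
    """Transformer computing weighted-sum priority scores from alpha.

    Parameters
    ----------
    weights : WeightVector
        Variable weights, ids matching the alpha columns.

    Attributes
    ----------
    weights_ : ndarray
        Weight values aligned to the alpha column order seen in ``fit``.
    """

    def __init__(self, weights: WeightVector = None):
        self.weights = weights

    def fit(self, X: pd.DataFrame, y=None) -> "PriorityScorer":
        if self.weights is None:
            raise ValueError("PriorityScorer requires a WeightVector")
        self._check_alignment(X)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        self.weights_ = self.weights.weights.reindex(X.columns).to_numpy(dtype=float)
        return self

    def _check_alignment(self, X: pd.DataFrame) -> None:
        w = self.weights.weights
        if len(w) != X.shape[1] or not set(w.index) == set(X.columns):
            raise ValueError(
                f"shape/id mismatch: weights for {len(w)} variables "
                f"{sorted(w.index)[:3]}..., alpha has {X.shape[1]} columns"
            )

    def transform(self, X: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "weights_"):
            raise AttributeError("PriorityScorer is not fitted yet; call fit first")
        mat = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        return pd.Series(mat @ self.weights_, index=X.index, name="score")


def priority_score(weights: WeightVector, alpha: pd.DataFrame) -> pd.Series:
    """s_p = sum_i w_i alpha_ip for every patient (rows of ``alpha``)."""
    return PriorityScorer(weights).fit(alpha).transform(alpha)


def contribution_report(
    weights: WeightVector, alpha: pd.DataFrame, patient_id
) -> pd.Series:
    """Per-variable contributions w_i * alpha_ip, sorted descending.

    The contributions sum exactly to the patient's composite score, giving a
    traceable decomposition for clinical review.
    """
    if patient_id not in alpha.index:
        raise KeyError(f"unknown patient {patient_id!r}")
    row = alpha.loc[patient_id]
    w = weights.weights.reindex(row.index)
    if w.isna().any():
        raise ValueError("weights and alpha variables do not match")
    contrib = (w * row.astype(float)).sort_values(ascending=False)
    contrib.name = "contribution"
    return contrib


def assign_priority_labels(
    scores: pd.Series,
    method: str = "tertile",
    high_threshold: float = 0.29,
    low_threshold: float = 0.18,
) -> PriorityLabeling:
    """Label every patient High / Medium / Low from their composite score.

    ``tertile``: boundaries at the empirical 1/3 and 2/3 quantiles (linear
    interpolation); scores on a boundary go to the higher-priority group.
    ``fixed``: strict operational thresholds — s > high_threshold is High,
    s < low_threshold is Low, otherwise Medium (boundary values are Medium).
    """
    if len(scores) == 0:
        raise ValueError("empty score vector")
    s = scores.astype(float)
    if method == "tertile":
        q_low, q_high = np.quantile(s.to_numpy(), [1 / 3, 2 / 3])
        if np.isclose(q_low, q_high) and s.nunique() == 1:
            warnings.warn("all scores identical; labeling every patient Medium")
            labels = pd.Series("Medium", index=s.index, name="label")
            return PriorityLabeling(labels, "tertile", (float(q_high), float(q_low)))
        labels = pd.Series(
            np.where(s >= q_high, "High", np.where(s >= q_low, "Medium", "Low")),
            index=s.index,
            name="label",
        )
        return PriorityLabeling(labels, "tertile", (float(q_high), float(q_low)))
    if method == "fixed":
        if not high_threshold > low_threshold:
            raise ValueError("fixed labeling needs high_threshold > low_threshold")
        labels = pd.Series(
            np.where(s > high_threshold, "High", np.where(s < low_threshold, "Low", "Medium")),
            index=s.index,
            name="label",
        )
        return PriorityLabeling(labels, "fixed", (high_threshold, low_threshold))
    raise ValueError(f"unknown labeling method {method!r}")


def save_scores(
    scores: pd.Series,
    labeling: PriorityLabeling,
    path,
    weights: WeightVector | None = None,
    alpha: pd.DataFrame | None = None,
    contributions: bool = False,
) -> None:
    """Write scores.csv: patient_id, score, label (+ contribution columns)."""
    out = pd.DataFrame({"score": scores, "label": labeling.labels})
    if contributions:
        if weights is None or alpha is None:
            raise ValueError("contribution columns need weights and alpha")
        w = weights.weights.reindex(alpha.columns)
        contrib = alpha.mul(w, axis=1)
        contrib.columns = [f"contrib_{c}" for c in contrib.columns]
        out = out.join(contrib)
    out.index.name = "patient_id"
    out.to_csv(path, float_format="%.12f")
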