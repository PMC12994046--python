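"""Expert-share normalization of raw patient values into alpha in [0, 1].

Each variable's levels (or clinical intervals, or binary states) carry
expert impact scores; the normalized value of a patient's raw entry is that
level's share of the variable's total impact:

    ordinal/categorical:  alpha = score(level) / sum(scores over levels)
    continuous:           alpha = rho_c / sum_j rho_j  for the interval
                          containing the raw value
    binary:               alpha = score_state / (score_present + score_absent)

Shares over a variable's levels sum to exactly 1, so alpha is bounded by the
top level's share (strictly below 1 for multi-level variables); [0, 1] is an
upper envelope, not an attained range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from biopriority.registry import CohortError, VariableRegistry, VariableSpec


def level_shares(spec: VariableSpec) -> pd.Series:
    """Normalized impact share of every level/interval/state of a variable."""
    if spec.kind == "binary":
        present, absent = spec.binary_scores  # type: ignore[misc]
        total = present + absent
        return pd.Series({1: present / total, 0: absent / total})
    scores = np.asarray(spec.impact_scores, dtype=float)
    shares = scores / scores.sum()
    if spec.kind == "continuous":
        index = list(range(len(shares)))
    else:
        index = list(spec.levels)  # type: ignore[arg-type]
    return pd.Series(shares, index=index)


def normalize_value(spec: VariableSpec, raw: object) -> float:
    """Normalized value in [0, 1] of one raw (non-missing) patient entry."""
    if spec.kind in ("ordinal", "categorical"):
        level = str(raw)
        if level not in spec.levels:  # type: ignore[operator]
            raise CohortError(
                f"variable {spec.id!r}: unknown level {raw!r}"
            )
        scores = np.asarray(spec.impact_scores, dtype=float)
        return float(scores[spec.levels.index(level)] / scores.sum())  # type: ignore[union-attr]
    if spec.kind == "continuous":
        c = spec.interval_index(float(raw))  # type: ignore[arg-type]
        scores = np.asarray(spec.impact_scores, dtype=float)
        return float(scores[c] / scores.sum())
    # binary
    present, absent = spec.binary_scores  # type: ignore[misc]
    if int(raw) == 1:  # type: ignore[arg-type]
        return float(present / (present + absent))
    return float(absent / (present + absent))


class AlphaNormalizer(BaseEstimator, TransformerMixin):
    """Transformer mapping a raw cohort table to the normalized matrix alpha.

    Parameters
    ----------
    registry : VariableRegistry
        Declares variable kinds, domains and expert impact scores.

    Attributes
    ----------
    feature_names_in_ : ndarray of str
        Variable ids consumed, in registry order.
    shares_ : dict
        Per-variable level -> share lookup used by :meth:`transform`.

    Notes
    -----
    ``transform`` accepts a cohort :class:`~pandas.DataFrame` indexed by
    patient id (extra columns such as ``age`` or ``dem_*`` are ignored) and
    returns an (n_patients, n_variables) DataFrame of shares in [0, 1].
    """

    def __init__(self, registry: VariableRegistry = None):
        self.registry = registry

    def fit(self, X: pd.DataFrame, y=None) -> "AlphaNormalizer":
        if self.registry is None:
            raise ValueError("AlphaNormalizer requires a registry")
        missing = [v.id for v in self.registry if v.id not in X.columns]
        if missing:
            raise CohortError(f"cohort lacks variable columns: {missing}")
        self.feature_names_in_ = np.asarray(self.registry.ids, dtype=object)
        self.n_features_in_ = len(self.registry)
        self.shares_ = {v.id: level_shares(v) for v in self.registry}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "shares_"):
            raise AttributeError("AlphaNormalizer is not fitted yet; call fit first")
        cols: dict[str, np.ndarray] = {}
        for spec in self.registry:
            raw = X[spec.id]
            if raw.isna().any():
                bad = raw.index[raw.isna()].tolist()
                raise CohortError(
                    f"variable {spec.id!r}: missing values for patients {bad}; "
                    "preprocess the cohort first"
                )
            try:
                cols[spec.id] = np.array(
                    [normalize_value(spec, v) for v in raw], dtype=float
                )
            except CohortError as exc:
                raise CohortError(f"(variable {spec.id!r}) {exc}") from exc
        out = pd.DataFrame(cols, index=X.index)
        return out[list(self.feature_names_in_)]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return self.feature_names_in_


def build_alpha_matrix(
    cohort: pd.DataFrame, registry: VariableRegistry
) -> pd.DataFrame:
    """Normalized decision matrix for a preprocessed cohort.

    Thin wrapper over :class:`AlphaNormalizer`. Returns a DataFrame with rows
    = patients (cohort order) and columns = variables (registry order); the
    conventional matrix alpha (variables x patients) is its transpose.
    """
    return AlphaNormalizer(registry).fit(cohort).transform(cohort)


def save_alpha(alpha: pd.DataFrame, path) -> None:
    """Write alpha with variables as rows and patients as columns (12 d.p.)."""
    out = alpha.T
    out.index.name = "variable_id"
    out.to_csv(path, float_format="%.12f")


def load_alpha(path) -> pd.DataFrame:
    """Read an alpha CSV written by :func:`save_alpha` (patients x variables)."""
    df = pd.read_csv(path, index_col="variable_id")
    out = df.T
    out.index.name = "patient_id"
    return out
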