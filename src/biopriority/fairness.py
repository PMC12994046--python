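"""Demographic-parity audit of priority-group assignment.

Parity here means the distribution of High/Medium/Low priority labels is
independent of a protected binary attribute (e.g. socioeconomic deprivation,
rural residence).  Independence is tested on the label x attribute
contingency table with a chi-square test when all expected cell counts are
at least 5, and with a Monte-Carlo permutation version of the same statistic
otherwise.  When several attributes are audited jointly, p-values are
Holm-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from biopriority.scoring import PriorityLabeling


@dataclass
class ParityResult:
    """Contingency table, test statistic and p-value for one attribute."""

    attribute: str
    table: pd.DataFrame  # priority group x attribute level
    statistic: float
    p_value: float
    test: str  # "chi-square" | "monte-carlo" | "degenerate"
    rates: pd.Series  # per-group attribute-positive rate
    flagged: bool = False


def _chi2_stat(table: np.ndarray) -> float:
    stat, _, _, _ = chi2_contingency(table, correction=False)
    return float(stat)


def demographic_parity_test(
    labeling: PriorityLabeling | pd.Series,
    attribute: pd.Series,
    min_expected: float = 5.0,
    n_monte_carlo: int = 9999,
    seed: int | None = None,
) -> ParityResult:
    """Test independence of priority labels and a binary/categorical attribute.

    Parameters
    ----------
    labeling : PriorityLabeling or Series
        Priority-group label per patient.
    attribute : Series
        Protected attribute per patient (same index as the labels).

    Notes
    -----
    A constant attribute makes parity trivially hold: the result carries
    statistic 0, p = 1 and is flagged. With sparse tables (any expected
    count < ``min_expected``) the chi-square reference distribution is
    replaced by a Monte-Carlo permutation null of the same statistic,
    p = (1 + #{permuted >= observed}) / (1 + B).
    """
    labels = labeling.labels if isinstance(labeling, PriorityLabeling) else labeling
    attr = attribute.reindex(labels.index)
    if attr.isna().any():
        missing = attr.index[attr.isna()].tolist()
        raise ValueError(f"attribute undefined for labeled patients: {missing[:5]}")

    table = pd.crosstab(labels, attr)
    name = str(attribute.name or "attribute")
    positive = table.columns.max()
    rates = (table[positive] / table.sum(axis=1)).rename(f"rate_{name}")

    if table.shape[1] < 2 or table.shape[0] < 2:
        warnings.warn(f"attribute {name!r} (or labeling) is constant; parity trivially holds")
        return ParityResult(
            attribute=name,
            table=table,
            statistic=0.0,
            p_value=1.0,
            test="degenerate",
            rates=rates,
            flagged=True,
        )

    arr = table.to_numpy(dtype=float)
    stat, p, _, expected = chi2_contingency(arr, correction=False)
    if (expected >= min_expected).all():
        return ParityResult(
            attribute=name,
            table=table,
            statistic=float(stat),
            p_value=float(p),
            test="chi-square",
            rates=rates,
        )

    # Monte-Carlo permutation null for sparse tables
    rng = np.random.default_rng(seed)
    lab_arr = labels.to_numpy()
    attr_arr = attr.to_numpy()
    count_ge = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(attr_arr)
        t = pd.crosstab(pd.Series(lab_arr), pd.Series(perm)).to_numpy(dtype=float)
        if t.shape[0] < 2 or t.shape[1] < 2:
            continue
        if _chi2_stat(t) >= stat - 1e-12:
            count_ge += 1
    p_mc = (1 + count_ge) / (1 + n_monte_carlo)
    return ParityResult(
        attribute=name,
        table=table,
        statistic=float(stat),
        p_value=float(p_mc),
        test="monte-carlo",
        rates=rates,
    )


def audit_attributes(
    labeling: PriorityLabeling | pd.Series,
    cohort: pd.DataFrame,
    attributes: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Audit several protected attributes with Holm-adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    results = [
        demographic_parity_test(labeling, cohort[a], **kwargs) for a in attributes
    ]
    out = pd.DataFrame(
        {
            "attribute": [r.attribute for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "test": [r.test for r in results],
        }
    )
    if len(out) > 1:
        out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    else:
        out["p_holm"] = out["p_value"]
    return out
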