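"""Synthetic cohorts, expert ratings and demographics with known ground truth.

The generator emulates the study conditions of the reference ENT setting:
~205 patients described by 20 mixed-type biopsychosocial variables with a
latent three-group severity structure (Low / Medium / High), a 20 x 7 expert
rating matrix, and binary demographic attributes for the fairness audit.

Group structure: within each variable, a patient's level is drawn from a
softmax distribution over the variable's normalized impact shares,
exp(b_g * alpha_level), where the group-specific sharpness b_g is solved so
that the mean normalized value of successive groups differs by
``effect_size`` (clipped, with a warning, where a variable's share range
cannot accommodate the gap).  This yields mean alpha profiles ordered
High > Medium > Low in every variable whenever effect_size > 0.

Missingness is applied completely at random; every generated value is valid
for the registry by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from biopriority.normalize import level_shares
from biopriority.registry import VariableRegistry, VariableSpec, load_registry
from biopriority.weights import WeightVector, load_weights

GROUP_NAMES = ("Low", "Medium", "High")  # latent group 0, 1, 2

_REFERENCE_DATE = date(2025, 1, 1)


def default_registry() -> VariableRegistry:
    """The shipped 20-variable ENT biopsychosocial registry."""
    with resources.as_file(
        resources.files("biopriority.data") / "default_registry.yaml"
    ) as p:
        return load_registry(p)


def panel_weights() -> WeightVector:
    """The published ENT expert-panel weight vector (printed rounding kept)."""
    with resources.as_file(
        resources.files("biopriority.data") / "ent_panel_weights.csv"
    ) as p:
        return load_weights(p)


@dataclass
class SynthesisConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the reference setting: 205 patients, 20 registry
    variables, 7 raters, three equal-prevalence latent severity groups with a
    mean-alpha separation of 0.25 between successive groups, rater noise SD 1
    on the 0-10 scale, no missingness, and two group-independent binary
    demographic attributes (socioeconomic deprivation, rural residence).
    """

    n_patients: int = 205
    n_raters: int = 7
    group_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    effect_size: float = 0.25
    rating_consensus_sd: float = 1.0
    missing_rate: float = 0.0
    demographics: dict = field(
        default_factory=lambda: {
            "dem_ses": (0.35, 0.35, 0.35),
            "dem_rural": (0.30, 0.30, 0.30),
        }
    )
    listing_window_days: int = 365
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.group_proportions), 1.0):
            raise ValueError("group proportions must sum to 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


# ---------------------------------------------------------------------------
# expert ratings
# ---------------------------------------------------------------------------

def generate_ratings(
    config: SynthesisConfig,
    registry: VariableRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate the expert rating matrix around a latent consensus.

    A latent consensus relevance score per variable is drawn uniformly on
    [0, 10]; each rater reports consensus + Gaussian noise
    (SD = ``rating_consensus_sd``) clipped to [0, 10].

    Returns the (n_variables x n_raters) matrix and the latent consensus for
    recovery tests.
    """
    registry = registry if registry is not None else default_registry()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    consensus = rng.uniform(0.0, 10.0, size=len(registry))
    noise = rng.normal(0.0, config.rating_consensus_sd, size=(len(registry), config.n_raters))
    mat = np.clip(consensus[:, None] + noise, 0.0, 10.0)
    raters = [f"R{m + 1}" for m in range(config.n_raters)]
    ratings = pd.DataFrame(mat, index=pd.Index(registry.ids, name="variable_id"), columns=raters)
    return ratings, pd.Series(consensus, index=registry.ids, name="consensus")


def save_ratings(ratings: pd.DataFrame, path) -> None:
    """Write ratings in long format (variable_id, rater_id, score)."""
    long = ratings.stack().rename("score").reset_index()
    long.columns = ["variable_id", "rater_id", "score"]
    long.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _mean_alpha(b: float, shares: np.ndarray) -> float:
    return float(_softmax(b * shares) @ shares)


_B_MAX = 400.0  # sharpness bound; softmax is numerically stable after shift


def _solve_sharpness(shares: np.ndarray, gap: float, direction: int) -> float:
    """Sharpness b >= 0 so that |E_b[alpha] - E_0[alpha]| = gap.

    direction +1 pushes mass to high-impact levels, -1 to low-impact ones.
    Clipped at the feasible extreme (with a warning) when the share range
    cannot accommodate the gap.
    """
    if gap == 0:
        return 0.0
    base = _mean_alpha(0.0, shares)
    extreme = _mean_alpha(direction * _B_MAX, shares)
    feasible = abs(extreme - base)
    if gap >= feasible - 1e-9:
        warnings.warn(
            f"effect_size {gap:.3g} infeasible for a variable with share span "
            f"{feasible:.3g}; clipping to the extreme distribution"
        )
        return _B_MAX
    f = lambda b: abs(_mean_alpha(direction * b, shares) - base) - gap
    return float(brentq(f, 0.0, _B_MAX, xtol=1e-10))


def _variable_sampling_table(spec: VariableSpec) -> tuple[list, np.ndarray]:
    """(raw sampled values per level, normalized shares per level)."""
    shares = level_shares(spec)
    if spec.kind in ("ordinal", "categorical"):
        return list(shares.index), shares.to_numpy(dtype=float)
    if spec.kind == "binary":
        # order (0, 1) so raw values align with shares
        return [0, 1], np.array([shares[0], shares[1]], dtype=float)
    # continuous: one slot per interval; the raw value is drawn uniformly
    # inside the chosen interval at sampling time
    return list(range(len(spec.intervals))), shares.to_numpy(dtype=float)  # type: ignore[arg-type]


def group_level_distributions(
    registry: VariableRegistry, effect_size: float
) -> dict[str, np.ndarray]:
    """Per-variable (3, n_levels) level probabilities for Low/Medium/High."""
    out: dict[str, np.ndarray] = {}
    for spec in registry:
        _, shares = _variable_sampling_table(spec)
        b_hi = _solve_sharpness(shares, effect_size, +1)
        b_lo = _solve_sharpness(shares, effect_size, -1)
        probs = np.stack(
            [
                _softmax(-b_lo * shares),  # Low
                _softmax(0.0 * shares),  # Medium
                _softmax(b_hi * shares),  # High
            ]
        )
        out[spec.id] = probs
    return out


def generate_cohort(
    config: SynthesisConfig,
    registry: VariableRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a synthetic cohort with latent severity groups.

    Returns
    -------
    cohort : DataFrame
        Indexed by patient_id with one column per registry variable (raw
        coded values, possibly missing), plus ``age``, ``diagnosis``,
        ``entry_date`` and the configured ``dem_*`` attributes.
    truth : Series
        Latent group per patient, 0 = Low, 1 = Medium, 2 = High.
    """
    registry = registry if registry is not None else default_registry()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    groups = rng.choice(3, size=n, p=np.asarray(config.group_proportions))
    probs = group_level_distributions(registry, config.effect_size)

    ids = [f"P{i + 1:04d}" for i in range(n)]
    data: dict[str, list] = {}
    for spec in registry:
        values_table, _ = _variable_sampling_table(spec)
        p3 = probs[spec.id]
        col: list = []
        for g in groups:
            idx = rng.choice(len(values_table), p=p3[g])
            if spec.kind == "continuous":
                lo, hi = spec.intervals[idx]  # type: ignore[index]
                col.append(float(rng.uniform(lo, hi)))
            else:
                col.append(values_table[idx])
        data[spec.id] = col

    cohort = pd.DataFrame(data, index=pd.Index(ids, name="patient_id"))

    # auxiliary columns
    cohort["age"] = rng.integers(15, 91, size=n)
    cohort["diagnosis"] = rng.choice(
        ["otologic", "rhinologic", "pharyngolaryngeal", "head_neck_mass"], size=n
    )
    offsets = rng.integers(0, config.listing_window_days, size=n)
    cohort["entry_date"] = [
        (_REFERENCE_DATE + timedelta(days=int(d))).isoformat() for d in offsets
    ]
    for attr, prevalence in config.demographics.items():
        prev = np.asarray(prevalence, dtype=float)[groups]
        cohort[attr] = (rng.random(n) < prev).astype(int)

    # MCAR missingness over decision-variable cells only
    if config.missing_rate > 0:
        var_ids = registry.ids
        mask = rng.random((n, len(var_ids))) < config.missing_rate
        block = cohort[var_ids].to_numpy(dtype=object)
        block[mask] = np.nan
        cohort[var_ids] = block

    truth = pd.Series(groups, index=cohort.index, name="group")
    return cohort, truth


def entry_days_from_cohort(cohort: pd.DataFrame, reference: str = "end") -> pd.Series:
    """Integer list-entry day offsets from the cohort's entry dates.

    ``reference="end"`` (default) measures from the latest entry date, giving
    non-positive offsets: the whole cohort is a standing backlog already on
    the list when a simulation starts, each patient carrying the wait they
    have accrued. ``reference="start"`` measures from the earliest entry
    date (non-negative offsets: arrivals during the horizon).
    """
    dates = pd.to_datetime(cohort["entry_date"])
    origin = dates.max() if reference == "end" else dates.min()
    if reference not in ("end", "start"):
        raise ValueError(f"unknown reference {reference!r}")
    return ((dates - origin).dt.days).rename("entry_day")
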