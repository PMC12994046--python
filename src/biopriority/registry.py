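"""Decision-variable registry and patient cohort data model.

A prioritization framework is defined over an ordered set of mixed-type
biopsychosocial decision variables (clinical severity, urgency, functional
limitation, psychosocial context, expected surgical benefit, resource
demand...).  Each variable carries expert-assigned clinical impact scores per
level (ordinal/categorical), per interval (continuous) or per state (binary);
these scores drive the share-based normalization in
:mod:`biopriority.normalize`.

The cohort itself is a plain :class:`pandas.DataFrame` indexed by
``patient_id`` with one column per variable id plus the optional auxiliary
columns ``age``, ``diagnosis``, ``entry_date`` and ``dem_*`` demographic
indicators used by the fairness audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("ordinal", "categorical", "continuous", "binary")

#: auxiliary cohort columns that are never decision variables
AUX_COLUMNS = ("age", "diagnosis", "entry_date")


class RegistryError(ValueError):
    """Malformed or inconsistent variable registry."""


class CohortError(ValueError):
    """Cohort values inconsistent with the variable registry."""


@dataclass(frozen=True)
class VariableSpec:
    """One decision variable: identity, kind, domain and expert impact scores.

    Parameters
    ----------
    id : str
        Short token, e.g. ``"Sever"``. Unique within a registry.
    label : str
        Free-text description.
    kind : {"ordinal", "categorical", "continuous", "binary"}
    levels : sequence of str, optional
        Ordered level tokens (ordinal/categorical kinds).
    intervals : sequence of (float, float), optional
        Ordered, contiguous, non-overlapping half-open ranges ``[lo, hi)``
        covering the clinical domain (continuous kind). The last interval is
        treated as closed so the domain upper bound is attainable.
    impact_scores : sequence of float, optional
        One positive expert impact score per level/interval (1-10 scale).
    binary_scores : (float, float), optional
        ``(score_present, score_absent)`` for binary kind.
    """

    id: str
    label: str = ""
    kind: str = "ordinal"
    levels: tuple[str, ...] | None = None
    intervals: tuple[tuple[float, float], ...] | None = None
    impact_scores: tuple[float, ...] | None = None
    binary_scores: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise RegistryError(
                f"variable {self.id!r}: unknown kind {self.kind!r}; "
                f"expected one of {VALID_KINDS}"
            )
        populated = [
            self.levels is not None,
            self.intervals is not None,
            self.binary_scores is not None,
        ]
        if sum(populated) != 1:
            raise RegistryError(
                f"variable {self.id!r}: exactly one of levels/intervals/"
                "binary_scores must be populated"
            )
        if self.kind in ("ordinal", "categorical"):
            if self.levels is None:
                raise RegistryError(f"variable {self.id!r}: {self.kind} kind requires levels")
            if self.impact_scores is None or len(self.impact_scores) != len(self.levels):
                raise RegistryError(
                    f"variable {self.id!r}: needs one impact score per level "
                    f"({len(self.levels)} levels, "
                    f"{0 if self.impact_scores is None else len(self.impact_scores)} scores)"
                )
            if len(set(self.levels)) != len(self.levels):
                raise RegistryError(f"variable {self.id!r}: duplicate levels")
        elif self.kind == "continuous":
            if self.intervals is None:
                raise RegistryError(f"variable {self.id!r}: continuous kind requires intervals")
            if self.impact_scores is None or len(self.impact_scores) != len(self.intervals):
                raise RegistryError(
                    f"variable {self.id!r}: needs one impact score per interval"
                )
            for (lo, hi) in self.intervals:
                if not lo < hi:
                    raise RegistryError(
                        f"variable {self.id!r}: empty or inverted interval [{lo}, {hi})"
                    )
            for (_, hi_prev), (lo, _) in zip(self.intervals, self.intervals[1:]):
                if lo != hi_prev:
                    raise RegistryError(
                        f"variable {self.id!r}: intervals must be contiguous and "
                        f"non-overlapping (gap/overlap at {hi_prev} vs {lo})"
                    )
        else:  # binary
            if self.binary_scores is None or len(self.binary_scores) != 2:
                raise RegistryError(
                    f"variable {self.id!r}: binary kind requires (present, absent) scores"
                )
        scores = self.impact_scores if self.binary_scores is None else self.binary_scores
        if any(s <= 0 for s in scores):
            raise RegistryError(f"variable {self.id!r}: impact scores must be > 0")

    # -- domain helpers -------------------------------------------------
    @property
    def domain(self) -> tuple[float, float] | None:
        """(lo, hi) of the continuous domain, or None for discrete kinds."""
        if self.intervals is None:
            return None
        return (self.intervals[0][0], self.intervals[-1][1])

    def interval_index(self, raw: float) -> int:
        """Index of the half-open interval containing ``raw`` (last closed)."""
        assert self.intervals is not None
        lo, hi = self.domain  # type: ignore[misc]
        x = float(raw)
        if not (lo <= x <= hi):
            raise CohortError(
                f"variable {self.id!r}: value {raw!r} outside domain [{lo}, {hi}]"
            )
        for c, (a, b) in enumerate(self.intervals):
            if a <= x < b:
                return c
        return len(self.intervals) - 1  # == hi, last interval closed

    def is_valid(self, raw: object) -> bool:
        """True if a non-missing raw value lies in this variable's domain."""
        try:
            self.validate_value(raw)
        except CohortError:
            return False
        return True

    def validate_value(self, raw: object) -> None:
        if self.kind in ("ordinal", "categorical"):
            if str(raw) not in self.levels:  # type: ignore[operator]
                raise CohortError(
                    f"variable {self.id!r}: unknown level {raw!r} "
                    f"(declared: {list(self.levels)})"  # type: ignore[arg-type]
                )
        elif self.kind == "continuous":
            try:
                x = float(raw)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise CohortError(f"variable {self.id!r}: non-numeric value {raw!r}")
            self.interval_index(x)
        else:
            if raw not in (0, 1, "0", "1", True, False):
                raise CohortError(
                    f"variable {self.id!r}: binary value must be 0/1, got {raw!r}"
                )


@dataclass(frozen=True)
class VariableRegistry:
    """Ordered collection of :class:`VariableSpec`; defines matrix row order."""

    variables: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variables]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RegistryError(f"duplicate variable ids: {dup}")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __getitem__(self, var_id: str) -> VariableSpec:
        for v in self.variables:
            if v.id == var_id:
                return v
        raise KeyError(var_id)

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variables]


def _spec_from_block(block: dict) -> VariableSpec:
    if "id" not in block:
        raise RegistryError(f"variable block without 'id': {block!r}")
    vid = str(block["id"])
    kind = block.get("kind")
    if kind is None:
        raise RegistryError(f"variable {vid!r}: missing 'kind'")
    kwargs: dict = {"id": vid, "label": str(block.get("label", "")), "kind": kind}
    try:
        if kind in ("ordinal", "categorical"):
            kwargs["levels"] = tuple(str(x) for x in block["levels"])
            kwargs["impact_scores"] = tuple(float(s) for s in block["scores"])
        elif kind == "continuous":
            kwargs["intervals"] = tuple((float(a), float(b)) for a, b in block["intervals"])
            kwargs["impact_scores"] = tuple(float(s) for s in block["scores"])
        elif kind == "binary":
            kwargs["binary_scores"] = tuple(float(s) for s in block["scores"])
    except KeyError as exc:
        raise RegistryError(f"variable {vid!r}: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise RegistryError(f"variable {vid!r}: malformed field ({exc})") from exc
    return VariableSpec(**kwargs)


def load_registry(path: str | Path) -> VariableRegistry:
    """Read a variable registry from a YAML file.

    The file holds a top-level ``variables`` list of blocks, each with ``id``,
    ``kind``, and ``levels``/``intervals`` + ``scores`` (or a 2-item
    ``scores`` for binary kind). Order in the file is preserved and defines
    the row order of every downstream matrix.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise RegistryError(f"cannot parse registry file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "variables" not in raw:
        raise RegistryError(f"registry file {path} must contain a 'variables' list")
    specs = tuple(_spec_from_block(b) for b in raw["variables"])
    return VariableRegistry(specs)


def save_registry(registry: VariableRegistry, path: str | Path) -> None:
    blocks = []
    for v in registry:
        b: dict = {"id": v.id, "label": v.label, "kind": v.kind}
        if v.kind in ("ordinal", "categorical"):
            b["levels"] = list(v.levels)  # type: ignore[arg-type]
            b["scores"] = list(v.impact_scores)  # type: ignore[arg-type]
        elif v.kind == "continuous":
            b["intervals"] = [list(iv) for iv in v.intervals]  # type: ignore[union-attr]
            b["scores"] = list(v.impact_scores)  # type: ignore[arg-type]
        else:
            b["scores"] = list(v.binary_scores)  # type: ignore[arg-type]
        blocks.append(b)
    Path(path).write_text(yaml.safe_dump({"variables": blocks}, sort_keys=False))


# ---------------------------------------------------------------------------
# cohort I/O and validation
# ---------------------------------------------------------------------------

def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in ("", "NA", "NaN", "nan"):
        return True
    return pd.isna(value)


def validate_cohort(cohort: pd.DataFrame, registry: VariableRegistry) -> None:
    """Check every non-missing raw value against its variable's domain."""
    if cohort.index.has_duplicates:
        dup = cohort.index[cohort.index.duplicated()].unique().tolist()
        raise CohortError(f"duplicate patient ids: {dup}")
    missing_cols = [v.id for v in registry if v.id not in cohort.columns]
    if missing_cols:
        raise CohortError(f"cohort lacks variable columns: {missing_cols}")
    for spec in registry:
        col = cohort[spec.id]
        for pid, value in col.items():
            if _is_missing(value):
                continue
            try:
                spec.validate_value(value)
            except CohortError as exc:
                raise CohortError(f"patient {pid!r}: {exc}") from exc


def load_cohort(
    path: str | Path,
    registry: VariableRegistry | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Read a cohort CSV (column 1 ``patient_id``, one column per variable id).

    Missing values may be encoded as empty fields or ``NA``. Binary variables
    are coerced to 0/1 integers; continuous to floats.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "patient_id":
        raise CohortError("first cohort column must be 'patient_id'")
    df = df.set_index("patient_id")
    df = df.where(~df.map(_is_missing), other=np.nan)
    if registry is not None:
        for spec in registry:
            if spec.id not in df.columns:
                continue
            if spec.kind == "continuous":
                df[spec.id] = pd.to_numeric(df[spec.id], errors="raise")
            elif spec.kind == "binary":
                df[spec.id] = pd.to_numeric(df[spec.id], errors="raise").astype("Int64")
    for aux in ("age",):
        if aux in df.columns:
            df[aux] = pd.to_numeric(df[aux], errors="coerce")
    for col in df.columns:
        if col.startswith("dem_"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if registry is not None and validate:
        validate_cohort(df, registry)
    return df


# ---------------------------------------------------------------------------
# missing-data preprocessing
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    """Patients removed for excess missingness, with their missing fractions."""

    excluded: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    imputed_cells: int = 0

    @property
    def n_excluded(self) -> int:
        return int(len(self.excluded))


def _age_band(age: float | None, width: int = 10) -> str:
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "unknown"
    lo = int(age) // width * width
    return f"{lo}-{lo + width - 1}"


def _mode_with_declared_order(values: Sequence, spec: VariableSpec):
    """Most frequent value; ties broken by the declared level order."""
    counts = pd.Series(list(values)).value_counts()
    top = counts.max()
    tied = set(counts[counts == top].index)
    if spec.kind in ("ordinal", "categorical"):
        for level in spec.levels:  # type: ignore[union-attr]
            if level in tied:
                return level
    else:  # binary: prefer 0 then 1 as "declared order" (absent, present)
        for v in (0, 1):
            if v in tied:
                return v
    return counts.idxmax()


def preprocess_cohort(
    cohort: pd.DataFrame,
    registry: VariableRegistry,
    missing_threshold: float = 0.10,
    age_band_width: int = 10,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the missing-data rules: exclusion then subgroup imputation.

    Patients missing strictly more than ``missing_threshold`` of the registry
    variables are removed and listed in the report. Remaining missing values
    are imputed within clinically homogeneous subgroups defined by
    (age band, diagnosis): subgroup mean for continuous variables, subgroup
    mode for ordinal/categorical/binary (mode ties broken by declared level
    order). Subgroups with no donor values fall back to the whole-cohort
    mean/mode.

    Returns the completed cohort (no missing values among registry variables)
    and an :class:`ExclusionReport`.
    """
    validate_cohort(cohort, registry)
    var_ids = registry.ids
    values = cohort[var_ids]
    n_vars = len(var_ids)

    for vid in var_ids:
        if values[vid].isna().all():
            raise CohortError(
                f"variable {vid!r} is missing for ALL patients; "
                "unrecoverable missingness"
            )

    missing_frac = values.isna().sum(axis=1) / n_vars
    drop_mask = missing_frac > missing_threshold
    report = ExclusionReport(excluded=missing_frac[drop_mask].rename("missing_fraction"))
    kept = cohort.loc[~drop_mask].copy()

    if kept[var_ids].isna().to_numpy().any():
        ages = kept["age"] if "age" in kept.columns else pd.Series(np.nan, index=kept.index)
        diagnoses = (
            kept["diagnosis"] if "diagnosis" in kept.columns
            else pd.Series("unknown", index=kept.index)
        )
        subgroup = pd.Series(
            [
                (_age_band(a, age_band_width), str(d))
                for a, d in zip(ages, diagnoses.fillna("unknown"))
            ],
            index=kept.index,
        )
        n_imputed = 0
        for spec in registry:
            col = kept[spec.id]
            missing_ids = col.index[col.isna()]
            if len(missing_ids) == 0:
                continue
            for pid in missing_ids:
                donors = col[(subgroup == subgroup[pid]) & col.notna()]
                if donors.empty:
                    donors = col[col.notna()]  # whole-cohort fallback
                if spec.kind == "continuous":
                    fill = float(donors.astype(float).mean())
                else:
                    fill = _mode_with_declared_order(donors.tolist(), spec)
                kept.loc[pid, spec.id] = fill
                n_imputed += 1
        report.imputed_cells = n_imputed

    validate_cohort(kept, registry)
    assert not kept[var_ids].isna().to_numpy().any()
    return kept, report
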