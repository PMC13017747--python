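"""Core containers for cohort feature tables and domain maps.

A cohort is a rectangular table with one row per individual: a unique id,
numeric risk-factor columns (missing values allowed), and a binary death
outcome (1 = died within the prediction window, 0 = survived). Risk factors
are partitioned into named domains (demography, socioeconomic, ...) by a
:class:`DomainMap`; the domain partition drives the coalition analysis in
:mod:`riskdomains.domain_importance`.

Cohorts are read and written as UTF-8 CSV with a header row, ``.`` decimal
separator and empty cells for missing values. Domain maps and run
configuration travel as YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

__all__ = [
    "CANONICAL_DOMAINS",
    "CohortTable",
    "DomainMap",
    "SplitSpec",
    "SchemaError",
    "ValidationError",
    "load_cohort",
    "load_domain_map",
    "write_cohort",
    "write_domain_map",
    "split_cohort",
    "concat_cohorts",
]

#: The seven canonical risk-factor domains, in conventional reporting order.
CANONICAL_DOMAINS = (
    "demography",
    "socioeconomic",
    "psychology",
    "social_connections",
    "childhood_adversity",
    "adulthood_adversity",
    "health_behaviors",
)

AGE_BOUNDS = (50.0, 110.0)


class SchemaError(ValueError):
    """A declared column is absent from the data."""


class ValidationError(ValueError):
    """Data violates a cohort invariant (non-binary outcome, bad age, ...)."""


@dataclass
class CohortTable:
    """One row per individual: id, numeric risk factors, binary outcome.

    Parameters
    ----------
    ids
        Unique individual identifiers, one per row.
    features
        Numeric risk-factor matrix, column-named. Missing values are NaN.
    outcome
        Binary death indicator (1 = death within the prediction window).
        No missing values allowed.
    age_col, gender_col
        Names of the age (years) and gender (1 = female, 0 = male) columns
        inside ``features``.
    source
        Optional per-row cohort-origin label (set by :func:`concat_cohorts`).
    """

    ids: pd.Index
    features: pd.DataFrame
    outcome: pd.Series
    age_col: str = "age"
    gender_col: str = "gender"
    source: pd.Series | None = None

    def __post_init__(self) -> None:
        self.ids = pd.Index(self.ids)
        self.features = self.features.reset_index(drop=True)
        self.outcome = pd.Series(np.asarray(self.outcome), name="outcome")
        if self.source is not None:
            self.source = pd.Series(np.asarray(self.source), name="source")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.features)
        if len(self.ids) != n or len(self.outcome) != n:
            raise ValidationError(
                f"ids ({len(self.ids)}), features ({n}) and outcome "
                f"({len(self.outcome)}) must have equal length"
            )
        if self.ids.has_duplicates:
            dupes = self.ids[self.ids.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate ids: {dupes}")
        if self.features.columns.has_duplicates:
            raise ValidationError("feature column names must be unique")
        if self.outcome.isna().any():
            bad = self.ids[self.outcome.isna().to_numpy()].tolist()[:5]
            raise ValidationError(f"missing outcome for ids {bad}")
        vals = set(pd.unique(self.outcome))
        if not vals <= {0, 1}:
            bad_mask = ~self.outcome.isin([0, 1]).to_numpy()
            bad = self.ids[bad_mask].tolist()[:5]
            raise ValidationError(
                f"outcome must be 0/1; offending ids {bad} "
                f"(values {sorted(vals - {0, 1})})"
            )
        for col, kind in ((self.age_col, "age"), (self.gender_col, "gender")):
            if col not in self.features.columns:
                raise SchemaError(f"declared {kind} column {col!r} not in features")
        age = self.features[self.age_col]
        ok = age.isna() | ((age >= AGE_BOUNDS[0]) & (age <= AGE_BOUNDS[1]))
        if not ok.all():
            bad = self.ids[~ok.to_numpy()].tolist()[:5]
            raise ValidationError(
                f"age outside [{AGE_BOUNDS[0]:g}, {AGE_BOUNDS[1]:g}] for ids {bad}"
            )
        gender = self.features[self.gender_col]
        ok = gender.isna() | gender.isin([0, 1])
        if not ok.all():
            bad = self.ids[~ok.to_numpy()].tolist()[:5]
            raise ValidationError(f"gender must be 0/1 (1 = female); offending ids {bad}")

    # -- conveniences -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def prevalence(self) -> float:
        """Fraction of rows with the death outcome."""
        return float(self.outcome.mean())

    def take(self, positions: Sequence[int]) -> "CohortTable":
        """Row subset by integer position (keeps ids)."""
        pos = np.asarray(positions)
        return CohortTable(
            ids=self.ids[pos],
            features=self.features.iloc[pos],
            outcome=self.outcome.iloc[pos],
            age_col=self.age_col,
            gender_col=self.gender_col,
            source=None if self.source is None else self.source.iloc[pos],
        )

    def to_frame(self, id_col: str = "id") -> pd.DataFrame:
        df = pd.DataFrame({id_col: self.ids})
        df = pd.concat([df, self.features.reset_index(drop=True)], axis=1)
        df["outcome"] = self.outcome.to_numpy()
        if self.source is not None:
            df["source"] = self.source.to_numpy()
        return df


@dataclass(frozen=True)
class DomainMap:
    """Partition of risk-factor columns into named domains.

    ``assignment`` maps each feature column to exactly one domain name;
    ``domains`` is the ordered list of distinct domain names (at most the
    seven canonical ones, but arbitrary names are allowed).
    """

    assignment: Mapping[str, str]
    domains: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        assignment = dict(self.assignment)
        object.__setattr__(self, "assignment", assignment)
        domains = tuple(self.domains) or tuple(dict.fromkeys(assignment.values()))
        object.__setattr__(self, "domains", domains)
        declared = set(domains)
        used = set(assignment.values())
        if not used <= declared:
            raise ValidationError(f"assignment references undeclared domains {sorted(used - declared)}")
        empty = declared - used
        if empty:
            raise ValidationError(f"domains with no assigned feature: {sorted(empty)}")

    def features_for(self, domains: Iterable[str]) -> list[str]:
        """Feature columns assigned to any of ``domains`` (assignment order)."""
        wanted = set(domains)
        unknown = wanted - set(self.domains)
        if unknown:
            raise ValidationError(f"unknown domains {sorted(unknown)}")
        return [f for f, d in self.assignment.items() if d in wanted]

    def check_against(self, table: CohortTable) -> None:
        """Every feature column of ``table`` must be assigned exactly once."""
        missing = [c for c in table.feature_names if c not in self.assignment]
        if missing:
            raise ValidationError(
                f"feature columns absent from domain map: {missing}"
            )

    def restricted_to(self, columns: Iterable[str]) -> "DomainMap":
        cols = set(columns)
        assignment = {f: d for f, d in self.assignment.items() if f in cols}
        domains = tuple(d for d in self.domains if d in set(assignment.values()))
        return DomainMap(assignment=assignment, domains=domains)

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {d: [] for d in self.domains}
        for f, d in self.assignment.items():
            out[d].append(f)
        return out


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default the conventional 7:3)."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


# ---------------------------------------------------------------------------
# I/O


def _read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_domain_map(path: str | Path) -> tuple[DomainMap, dict]:
    """Read a domain-map config (YAML or JSON).

    Expected keys: ``outcome_col``, ``id_col``, ``age_col``, ``gender_col``
    and ``domains`` mapping each domain name to its list of feature columns.
    Returns the :class:`DomainMap` and the raw config dict.
    """
    cfg = _read_config(path)
    for key in ("outcome_col", "id_col", "age_col", "gender_col", "domains"):
        if key not in cfg:
            raise SchemaError(f"domain-map config missing key {key!r}")
    assignment: dict[str, str] = {}
    for domain, cols in cfg["domains"].items():
        for col in cols:
            if col in assignment:
                raise ValidationError(
                    f"feature {col!r} assigned to both {assignment[col]!r} and {domain!r}"
                )
            assignment[col] = domain
    dm = DomainMap(assignment=assignment, domains=tuple(cfg["domains"]))
    return dm, cfg


def load_cohort(path: str | Path, domain_map_path: str | Path) -> tuple[CohortTable, DomainMap]:
    """Load a cohort CSV together with its domain-map config.

    Rows with a missing outcome are rejected; rows with missing feature
    values are retained (missingness is handled downstream by the models).
    """
    dm, cfg = load_domain_map(domain_map_path)
    df = pd.read_csv(path, float_precision="round_trip")
    for key in ("id_col", "outcome_col", "age_col", "gender_col"):
        col = cfg[key]
        if col not in df.columns:
            raise SchemaError(f"{key} {col!r} not found in {path}")
    id_col, outcome_col = cfg["id_col"], cfg["outcome_col"]
    feature_cols = [c for c in df.columns if c not in (id_col, outcome_col, "source")]
    unmapped = [c for c in feature_cols if c not in dm.assignment]
    if unmapped:
        raise ValidationError(f"feature columns absent from domain map: {unmapped}")
    if df[outcome_col].isna().any():
        bad = df.loc[df[outcome_col].isna(), id_col].tolist()[:5]
        raise ValidationError(f"missing outcome for ids {bad}")
    table = CohortTable(
        ids=pd.Index(df[id_col]),
        features=df[feature_cols],
        outcome=df[outcome_col],
        age_col=cfg["age_col"],
        gender_col=cfg["gender_col"],
        source=df["source"] if "source" in df.columns else None,
    )
    dm.check_against(table)
    return table, dm


def write_cohort(table: CohortTable, path: str | Path, id_col: str = "id") -> None:
    """Write a cohort to CSV (empty cell = missing; round-trips exactly)."""
    table.to_frame(id_col=id_col).to_csv(path, index=False)


def write_domain_map(
    dm: DomainMap,
    path: str | Path,
    *,
    outcome_col: str = "outcome",
    id_col: str = "id",
    age_col: str = "age",
    gender_col: str = "gender",
) -> None:
    cfg = {
        "outcome_col": outcome_col,
        "id_col": id_col,
        "age_col": age_col,
        "gender_col": gender_col,
        "domains": dm.as_dict(),
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# Splitting and pooling


def split_cohort(table: CohortTable, spec: SplitSpec) -> tuple[CohortTable, CohortTable]:
    """Partition a cohort into train/test subsets.

    The train set has exactly ``round(train_fraction * n)`` rows. With
    ``stratified=True`` (the default) the partition is stratified by the
    outcome so train and test prevalences agree up to discreteness. The
    same seed always produces the identical partition.
    """
    n = table.n
    if n < 10:
        raise ValidationError(f"cohort too small to split (n={n})")
    classes = set(pd.unique(table.outcome))
    if spec.stratified and len(classes) < 2:
        raise ValidationError("stratified split requires both outcome classes")
    n_train = int(round(spec.train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=n_train,
        random_state=spec.seed,
        shuffle=True,
        stratify=table.outcome.to_numpy() if spec.stratified else None,
    )
    return table.take(np.sort(train_idx)), table.take(np.sort(test_idx))


def concat_cohorts(
    tables: Sequence[CohortTable],
    shared_only: bool = True,
    labels: Sequence[str] | None = None,
) -> CohortTable:
    """Pool cohorts row-wise, restricted to their shared feature columns.

    Mirrors pooled-cohort evaluation (e.g. two surveys sharing 25 of their
    risk factors): only columns present in every cohort are kept, and a
    ``source`` label column records each row's cohort of origin.
    """
    if not tables:
        raise ValidationError("no cohorts to concatenate")
    labels = list(labels) if labels is not None else [f"cohort{i}" for i in range(len(tables))]
    if len(labels) != len(tables):
        raise ValidationError("labels must match tables")
    if shared_only:
        shared = [c for c in tables[0].feature_names if all(c in t.feature_names for t in tables)]
        if not shared:
            raise ValidationError("cohorts share no feature columns")
    else:
        shared = list(dict.fromkeys(c for t in tables for c in t.feature_names))
    first = tables[0]
    for t in tables:
        if t.age_col != first.age_col or t.gender_col != first.gender_col:
            raise ValidationError("cohorts disagree on age/gender column names")
    feats = pd.concat([t.features.reindex(columns=shared) for t in tables], ignore_index=True)
    ids = pd.Index(np.concatenate([np.asarray(t.ids, dtype=object) for t in tables]))
    if ids.has_duplicates:  # disambiguate pooled ids by cohort label
        ids = pd.Index(
            np.concatenate([[f"{lab}:{i}" for i in t.ids] for t, lab in zip(tables, labels)])
        )
    outcome = pd.concat([t.outcome for t in tables], ignore_index=True)
    source = pd.Series(np.concatenate([[lab] * t.n for t, lab in zip(tables, labels)]), name="source")
    return CohortTable(
        ids=ids,
        features=feats,
        outcome=outcome,
        age_col=first.age_col,
        gender_col=first.gender_col,
        source=source,
    )
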