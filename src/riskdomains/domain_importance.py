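"""Leave-one-domain-out importance: retraining over all domain coalitions.

The question answered here is "how much does each *group* of risk factors
(demography, socioeconomic, ...) contribute to predictive performance?".
Single-feature attributions cannot answer it because features within a
domain are redundant; instead a model is retrained on every non-empty
subset (coalition) S of domains — 2^D - 1 subsets, i.e. 127 for seven
domains — and each coalition's test-set metric defines a value function
v(S). The importance of domain d is then the mean of its marginal
contributions

    m_d(S) = v(S ∪ {d}) - v(S)   over all S ⊆ D \\ {d}, including S = ∅,

where v(∅) is the no-information value of the metric (prevalence for
PR-AUC, 0.5 for ROC-AUC, 0 for R², pseudo-R² and IMV). The default weights
all 2^(D-1) marginals equally; Shapley weighting
|S|! (D-|S|-1)! / D! is available as an option and satisfies the
efficiency identity sum_d importance_d = v(full) - v(∅).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import factorial
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CohortTable, DomainMap, SplitSpec, split_cohort
from .metrics import compute_all_metrics
from .model_zoo import FittedModel, ModelSpec, fit_model, predict_proba

__all__ = [
    "Coalition",
    "CoalitionLedger",
    "DomainImportance",
    "enumerate_coalitions",
    "coalition_value",
    "empty_coalition_value",
    "domain_importance",
    "run_domain_analysis",
]

MAX_DOMAINS = 12  # exhaustive enumeration bound


@dataclass(frozen=True)
class Coalition:
    """A subset of domains, canonically ordered for hashing and caching."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(sorted(set(self.members))))

    @classmethod
    def of(cls, *names: str) -> "Coalition":
        return cls(members=tuple(names))

    def __contains__(self, domain: str) -> bool:
        return domain in self.members

    def __len__(self) -> int:
        return len(self.members)

    def with_(self, domain: str) -> "Coalition":
        return Coalition(members=self.members + (domain,))

    def key(self) -> str:
        return "+".join(self.members) if self.members else "(empty)"


def enumerate_coalitions(domains: Sequence[str]) -> list[Coalition]:
    """All 2^D - 1 non-empty domain subsets, ordered by size then name."""
    doms = sorted(set(domains))
    if len(doms) > MAX_DOMAINS:
        raise ValueError(
            f"{len(doms)} domains exceed the exhaustive bound of {MAX_DOMAINS}; "
            "coalition subsampling is not supported"
        )
    if not doms:
        raise ValueError("need at least one domain")
    out = []
    for size in range(1, len(doms) + 1):
        for combo in combinations(doms, size):
            out.append(Coalition(members=combo))
    return out


def empty_coalition_value(test: CohortTable, metric_name: str) -> float:
    """Value of the no-information predictor v(∅) for each metric."""
    if metric_name == "pr_auc":
        return test.prevalence
    if metric_name == "roc_auc":
        return 0.5
    if metric_name in ("r2", "pseudo_r2", "imv"):
        return 0.0
    raise ValueError(f"unsupported metric {metric_name!r}")


@dataclass
class CoalitionLedger:
    """Cached value-function evaluations v(S) for domain subsets.

    Keys are canonical "a+b+c" strings ("(empty)" for the empty coalition).
    A complete ledger holds all 2^D entries including v(∅).
    """

    metric_name: str
    values: dict[str, float] = field(default_factory=dict)
    empty_value: float | None = None

    def get(self, coalition: Coalition) -> float:
        if len(coalition) == 0:
            if self.empty_value is None:
                raise KeyError("empty coalition value not set")
            return self.empty_value
        return self.values[coalition.key()]

    def set(self, coalition: Coalition, value: float) -> None:
        if len(coalition) == 0:
            self.empty_value = float(value)
        else:
            self.values[coalition.key()] = float(value)

    def __contains__(self, coalition: Coalition) -> bool:
        if len(coalition) == 0:
            return self.empty_value is not None
        return coalition.key() in self.values

    def missing(self, domains: Sequence[str]) -> list[Coalition]:
        missing = [c for c in enumerate_coalitions(domains) if c not in self]
        if self.empty_value is None:
            missing.insert(0, Coalition(members=()))
        return missing

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "metric_name": self.metric_name,
                    "empty_value": self.empty_value,
                    "values": self.values,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CoalitionLedger":
        raw = json.loads(Path(path).read_text())
        return cls(
            metric_name=raw["metric_name"],
            values=dict(raw["values"]),
            empty_value=raw["empty_value"],
        )


def coalition_value(
    coalition: Coalition,
    train: CohortTable,
    test: CohortTable,
    model_spec: ModelSpec,
    metric_name: str,
    domain_map: DomainMap,
    ledger: CoalitionLedger | None = None,
    fit_hook: Callable[[Coalition], None] | None = None,
) -> float:
    """v(S): fit the model on exactly the features of the coalition's domains
    (training rows only) and score the requested metric on the test rows.

    If a ledger already contains the coalition no refit is performed.
    ``fit_hook`` is called once per actual fit (used to assert caching).
    """
    if len(coalition) == 0:
        raise ValueError("coalition must be non-empty; use empty_coalition_value")
    if ledger is not None and coalition in ledger:
        return ledger.get(coalition)
    features = domain_map.features_for(coalition.members)
    fitted = fit_model(model_spec, train, feature_subset=features)
    if fit_hook is not None:
        fit_hook(coalition)
    p = predict_proba(fitted, test)
    value = compute_all_metrics(test.outcome.to_numpy(), p)[metric_name]
    if ledger is not None:
        ledger.set(coalition, value)
    return value


@dataclass
class DomainImportance:
    """Per-domain mean marginal contribution to the evaluation metric.

    ``table`` columns: domain, mean, se, n_marginals, weighting, metric.
    With seed replication the SE is across seeds; for a single ledger it is
    across the 2^(D-1) marginal contributions.
    """

    table: pd.DataFrame
    weighting: str
    metric_name: str

    def value(self, domain: str) -> float:
        row = self.table[self.table["domain"] == domain]
        if row.empty:
            raise KeyError(domain)
        return float(row["mean"].iloc[0])

    def ranking(self) -> list[str]:
        t = self.table.sort_values(["mean", "domain"], ascending=[False, True])
        return t["domain"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _marginals(ledger: CoalitionLedger, domains: Sequence[str], domain: str):
    """(|S|, m_d(S)) over all S ⊆ D \\ {d} including the empty set."""
    others = [d for d in domains if d != domain]
    out = []
    for size in range(len(others) + 1):
        for combo in combinations(others, size):
            s = Coalition(members=combo)
            out.append((len(s), ledger.get(s.with_(domain)) - ledger.get(s)))
    return out


def domain_importance(
    ledger: CoalitionLedger,
    domains: Sequence[str],
    weighting: str = "unweighted_mean",
) -> DomainImportance:
    """Aggregate a complete ledger into per-domain importances.

    ``unweighted_mean`` (default) averages all 2^(D-1) marginals equally;
    ``shapley`` applies the |S|!(D-|S|-1)!/D! weights and hence satisfies
    the efficiency identity.
    """
    if weighting not in ("unweighted_mean", "shapley"):
        raise ValueError(f"unknown weighting {weighting!r}")
    doms = sorted(set(domains))
    missing = ledger.missing(doms)
    if missing:
        raise ValueError(f"ledger incomplete; missing {[c.key() for c in missing]}")
    d_count = len(doms)
    rows = []
    for domain in doms:
        marg = _marginals(ledger, doms, domain)
        vals = np.array([m for _, m in marg])
        if weighting == "shapley":
            w = np.array(
                [factorial(s) * factorial(d_count - s - 1) / factorial(d_count) for s, _ in marg]
            )
            mean = float(np.sum(w * vals))
        else:
            mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append(
            {
                "domain": domain,
                "mean": mean,
                "se": se,
                "n_marginals": int(vals.size),
                "weighting": weighting,
                "metric": ledger.metric_name,
            }
        )
    return DomainImportance(
        table=pd.DataFrame(rows), weighting=weighting, metric_name=ledger.metric_name
    )


def run_domain_analysis(
    cohort: CohortTable,
    domain_map: DomainMap,
    model_spec: ModelSpec | None = None,
    split_spec: SplitSpec | None = None,
    seeds: Sequence[int] = (0,),
    metric_name: str = "pr_auc",
    weighting: str = "unweighted_mean",
) -> tuple[DomainImportance, list[CoalitionLedger]]:
    """Full leave-one-domain-out analysis with seed replication.

    Per seed: one 7:3 split shared by every coalition (marginals must
    compare models on identical test rows), 2^D - 1 retrained models plus
    the no-information baseline, then per-domain importances. Importances
    are averaged across seeds with the SE across seeds. The default
    coalition model is LightGBM and the default metric PR-AUC.
    """
    model_spec = model_spec or ModelSpec(name="lightgbm")
    split_spec = split_spec or SplitSpec()
    domains = sorted(domain_map.domains)
    coalitions = enumerate_coalitions(domains)
    ledgers: list[CoalitionLedger] = []
    per_seed: dict[str, list[float]] = {d: [] for d in domains}
    for seed in seeds:
        train, test = split_cohort(cohort, replace(split_spec, seed=seed))
        ledger = CoalitionLedger(metric_name=metric_name)
        ledger.empty_value = empty_coalition_value(test, metric_name)
        for coalition in coalitions:
            coalition_value(
                coalition,
                train,
                test,
                replace(model_spec, seed=seed),
                metric_name,
                domain_map,
                ledger=ledger,
            )
        imp = domain_importance(ledger, domains, weighting=weighting)
        for d in domains:
            per_seed[d].append(imp.value(d))
        ledgers.append(ledger)
    rows = []
    for d in domains:
        v = np.asarray(per_seed[d])
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        rows.append(
            {
                "domain": d,
                "mean": float(v.mean()),
                "se": se,
                "n_marginals": 2 ** (len(domains) - 1),
                "weighting": weighting,
                "metric": metric_name,
            }
        )
    final = DomainImportance(
        table=pd.DataFrame(rows), weighting=weighting, metric_name=metric_name
    )
    return final, ledgers
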