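"""Mutation-level evidence encoded into the SNV feature block.

Two feature-set policies exist. "all" keeps the continuous tool scores and
drops any (sample, gene) row whose score block contains missing values —
impact predictors cannot score every mutation type, and those scores cannot
be imputed. "small" omits the score block entirely and keeps every row,
carrying the categorical predictions as ordinals with missing encoded as 0;
the smaller feature set buys a larger training set.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MISSING, MUTATION_TYPES, RunConfig, _Missing
from .io import MutationRecord


@dataclass
class FeatureSetSpec:
    """Resolved description of one feature-set policy ("all" or "small")."""

    name: str
    score_features: tuple[str, ...]
    ordinal_features: tuple[str, ...]
    onehot_types: tuple[str, ...]
    domain_features: tuple[str, ...]

    @classmethod
    def from_config(cls, config: RunConfig, name: str | None = None) -> "FeatureSetSpec":
        name = name or config.feature_set
        if name not in ("all", "small"):
            raise ValueError(f"unknown feature set {name!r}")
        return cls(
            name=name,
            score_features=config.tools if name == "all" else (),
            ordinal_features=config.tools,
            onehot_types=MUTATION_TYPES,
            domain_features=config.cancer_domains,
        )

    def columns(self) -> list[str]:
        cols = [f"type_{t}" for t in self.onehot_types]
        cols += [f"{t}_ord" for t in self.ordinal_features]
        cols += [f"{t}_score" for t in self.score_features]
        cols += [f"domain_{d}" for d in self.domain_features]
        return cols


def ordinal_encode(pred: str | _Missing, category_order: tuple[str, ...]) -> int:
    """MISSING -> 0; k-th category of the benign-to-damaging order -> k."""
    if pred is MISSING:
        return 0
    try:
        return category_order.index(pred) + 1
    except ValueError:
        raise ValueError(
            f"prediction {pred!r} not in declared category order {category_order}"
        ) from None


def onehot_mutation_type(
    mutation_type: str, vocabulary: tuple[str, ...] = MUTATION_TYPES
) -> np.ndarray:
    """0/1 indicator vector over the type vocabulary; unknown maps to other."""
    t = mutation_type if mutation_type in vocabulary else "other"
    vec = np.zeros(len(vocabulary), dtype=int)
    vec[vocabulary.index(t)] = 1
    return vec


def domain_features(
    pair_domains: set[str], cancer_domains: tuple[str, ...]
) -> np.ndarray:
    """Bit d = 1 iff any mutation of the pair hits onco-domain d."""
    return np.array([int(d in pair_domains) for d in cancer_domains], dtype=int)


def orient_score(tool: str, score: float | _Missing, config: RunConfig):
    """Put every tool's score on a larger-means-more-damaging scale."""
    if score is MISSING:
        return MISSING
    return score if config.tool_orientation[tool] else 1.0 - score


@dataclass
class PairAggregate:
    """Mutation evidence of one (sample, gene) pair collapsed to one summary."""

    sample_id: str
    gene: str
    mutation_type: str
    scores: dict[str, float | _Missing] = field(default_factory=dict)  # oriented, max
    ordinals: dict[str, int] = field(default_factory=dict)  # max
    domains: frozenset[str] = frozenset()


def aggregate_pair(
    mutations: list[MutationRecord], config: RunConfig
) -> PairAggregate:
    """Collapse all mutations of one pair, keeping the most damaging evidence.

    Per-tool scores are oriented and aggregated by max; ordinals by max;
    domains by union. The representative mutation type belongs to the
    mutation with the highest mean oriented score, ties broken by the
    configured severity order.
    """
    if not mutations:
        raise ValueError("aggregate_pair requires at least one mutation")
    first = mutations[0]

    scores: dict[str, float | _Missing] = {}
    ordinals: dict[str, int] = {}
    for tool in config.tools:
        oriented = [
            orient_score(tool, m.tool_scores.get(tool, MISSING), config)
            for m in mutations
        ]
        present = [s for s in oriented if s is not MISSING]
        scores[tool] = max(present) if present else MISSING
        ordinals[tool] = max(
            ordinal_encode(m.tool_preds.get(tool, MISSING), config.tool_categories[tool])
            for m in mutations
        )

    def sort_key(m: MutationRecord) -> tuple[float, int]:
        oriented = [
            orient_score(t, m.tool_scores.get(t, MISSING), config) for t in config.tools
        ]
        present = [s for s in oriented if s is not MISSING]
        mean = float(np.mean(present)) if present else -np.inf
        severity = (
            config.severity_order.index(m.mutation_type)
            if m.mutation_type in config.severity_order
            else len(config.severity_order)
        )
        return (-mean, severity)

    representative = min(mutations, key=sort_key)
    domains = frozenset().union(*(m.domains for m in mutations))
    return PairAggregate(
        sample_id=first.sample_id,
        gene=first.gene,
        mutation_type=representative.mutation_type,
        scores=scores,
        ordinals=ordinals,
        domains=domains,
    )


def aggregate_all(
    mutations: list[MutationRecord], config: RunConfig
) -> list[PairAggregate]:
    by_pair: dict[tuple[str, str], list[MutationRecord]] = defaultdict(list)
    for m in mutations:
        by_pair[(m.sample_id, m.gene)].append(m)
    return [aggregate_pair(muts, config) for _, muts in sorted(by_pair.items())]


def assemble_snv_features(
    mutations: list[MutationRecord],
    config: RunConfig,
    feature_set: str | None = None,
) -> pd.DataFrame:
    """SNV feature table with one row per mutated (sample, gene) pair.

    Under "all", rows with any missing score are dropped; under "small"
    the score block is omitted and every row kept.
    """
    spec = FeatureSetSpec.from_config(config, feature_set)
    rows = []
    for agg in aggregate_all(mutations, config):
        if spec.name == "all" and any(
            agg.scores[t] is MISSING for t in spec.score_features
        ):
            continue
        row: dict[str, object] = {"sample": agg.sample_id, "gene": agg.gene}
        onehot = onehot_mutation_type(agg.mutation_type, spec.onehot_types)
        row.update({f"type_{t}": int(v) for t, v in zip(spec.onehot_types, onehot)})
        row.update({f"{t}_ord": agg.ordinals[t] for t in spec.ordinal_features})
        row.update({f"{t}_score": float(agg.scores[t]) for t in spec.score_features})
        bits = domain_features(set(agg.domains), spec.domain_features)
        row.update({f"domain_{d}": int(b) for d, b in zip(spec.domain_features, bits)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", "gene", *spec.columns()])
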