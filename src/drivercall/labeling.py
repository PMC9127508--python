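"""Assign TSG/OG/DRIVER/NEUTRAL labels to altered (sample, gene) pairs.

Four strategies are supported. The two mutation-exact strategies match the
precise genomic change (gene, position, ref, alt) against a curated
mutation-level driver list; the two gene-level strategies label every
alteration (mutation or copy-number change) of a listed gene. Neutral genes
are labeled NEUTRAL identically under every strategy. Pairs matched by no
list stay UNLABELED and are reserved for prediction.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .config import MISSING, RunConfig
from .io import DriverResources, MutationRecord

logger = logging.getLogger(__name__)

MUTATION = "MUTATION"
CNV = "CNV"
BOTH = "BOTH"

_TSG_TAGS = frozenset({"tsg", "possible tsg"})
_OG_TAGS = frozenset({"oncogene", "possible oncogene"})


@dataclass(frozen=True)
class LabeledPair:
    sample_id: str
    gene: str
    alteration_kind: str  # MUTATION | CNV | BOTH
    label: str  # NEUTRAL | DRIVER | TSG | OG | UNLABELED
    strategy: str


def filter_mutation_drivers(
    resources: DriverResources, config: RunConfig
) -> dict[tuple[str, int, str, str], str]:
    """Retain mutation-level driver rows passing the evidence threshold.

    Rows with evidence strictly above ``config.evidence_threshold`` are
    kept. Rows with MISSING evidence are kept only when the resource is
    declared pre-curated. Returns a map (gene, pos, ref, alt) -> label.
    """
    out: dict[tuple[str, int, str, str], str] = {}
    for row in resources.mutation_drivers.itertuples(index=False):
        ev = row.evidence_score
        if ev is MISSING:
            if not config.mutation_drivers_precurated:
                continue
        elif not ev > config.evidence_threshold:
            continue
        key = (row.gene, int(row.pos), row.ref.upper(), row.alt.upper())
        out[key] = row.label
    return out


def label_mutation_exact(
    mutations: list[MutationRecord],
    driver_set: dict[tuple[str, int, str, str], str],
    neutral_genes: set[str],
    binary: bool,
) -> list[LabeledPair]:
    """Label mutated pairs by exact (gene, pos, ref, alt) driver matches.

    A pair with at least one matching mutation is a driver for that sample
    even if its other mutations do not match (the gene, not the mutation,
    is the classification unit). Any mutation in a neutral-list gene makes
    the pair NEUTRAL. A pair matching both TSG- and OG-labeled driver
    mutations is set UNLABELED with a warning.
    """
    strategy = "MUTATION_EXACT_BINARY" if binary else "MUTATION_EXACT_TSG_OG"
    by_pair: dict[tuple[str, str], list[MutationRecord]] = defaultdict(list)
    for m in mutations:
        by_pair[(m.sample_id, m.gene)].append(m)

    out: list[LabeledPair] = []
    for (sample, gene), muts in sorted(by_pair.items()):
        if gene in neutral_genes:
            label = "NEUTRAL"
        else:
            hits = {
                driver_set[(m.gene, m.pos, m.ref, m.alt)]
                for m in muts
                if (m.gene, m.pos, m.ref, m.alt) in driver_set
            }
            if not hits:
                label = "UNLABELED"
            elif binary:
                label = "DRIVER"
            else:
                roles = {h for h in hits if h in ("TSG", "OG")}
                if len(roles) == 1:
                    label = roles.pop()
                elif len(roles) > 1:
                    logger.warning(
                        "pair (%s, %s) matches both TSG and OG driver mutations; "
                        "left UNLABELED",
                        sample,
                        gene,
                    )
                    label = "UNLABELED"
                else:
                    label = "UNLABELED"
        out.append(LabeledPair(sample, gene, MUTATION, label, strategy))
    return out


def gene_role_sets(
    gene_drivers: pd.DataFrame, cancer_type: str | None
) -> tuple[set[str], set[str]]:
    """Resolve gene-level TSG and OG sets for one labeling run.

    ``cancer_type=None`` selects PAN rows; otherwise rows matching the
    cancer type. Unknown tags are ignored loudly; genes carrying both
    TSG-type and OG-type tags are excluded from both sets.
    """
    if cancer_type is None:
        rows = gene_drivers[gene_drivers["cancer_type"] == "PAN"]
    else:
        rows = gene_drivers[gene_drivers["cancer_type"] == cancer_type]
    tsg: set[str] = set()
    og: set[str] = set()
    for row in rows.itertuples(index=False):
        tag = row.tag.strip().lower()
        if tag in _TSG_TAGS:
            tsg.add(row.gene)
        elif tag in _OG_TAGS:
            og.add(row.gene)
        else:
            logger.warning("unknown driver tag %r for gene %s ignored", row.tag, row.gene)
    dual = tsg & og
    if dual:
        logger.warning("dual-role genes excluded from driver sets: %s", sorted(dual))
    return tsg - dual, og - dual


def label_gene_level(
    mutated_pairs: set[tuple[str, str]],
    cnv_pairs: set[tuple[str, str]],
    gene_drivers: pd.DataFrame,
    neutral_genes: set[str],
    cancer_type: str | None = None,
) -> list[LabeledPair]:
    """Label every altered pair (mutation or CNV != 0) at the gene level."""
    strategy = "GENE_PAN" if cancer_type is None else "GENE_CANCER_SPECIFIC"
    tsg, og = gene_role_sets(gene_drivers, cancer_type)
    universe = mutated_pairs | cnv_pairs
    out: list[LabeledPair] = []
    for sample, gene in sorted(universe):
        if (sample, gene) in mutated_pairs and (sample, gene) in cnv_pairs:
            kind = BOTH
        elif (sample, gene) in mutated_pairs:
            kind = MUTATION
        else:
            kind = CNV
        if gene in neutral_genes:
            label = "NEUTRAL"
        elif gene in tsg:
            label = "TSG"
        elif gene in og:
            label = "OG"
        else:
            label = "UNLABELED"
        out.append(LabeledPair(sample, gene, kind, label, strategy))
    return out


def build_label_table(
    pairs: list[LabeledPair],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Deduplicate pairs and split labeled from UNLABELED rows.

    The same (sample, gene) key appearing with identical labels but
    different alteration kinds merges to one row with kind BOTH;
    conflicting labels for one key are a fatal error (prevented upstream).
    Returns (labeled table, unlabeled table, per-class counts).
    """
    merged: dict[tuple[str, str], LabeledPair] = {}
    for p in pairs:
        key = (p.sample_id, p.gene)
        if key not in merged:
            merged[key] = p
            continue
        prev = merged[key]
        if prev.label != p.label:
            raise ValueError(
                f"conflicting labels for pair {key}: {prev.label} vs {p.label}"
            )
        kind = prev.alteration_kind if prev.alteration_kind == p.alteration_kind else BOTH
        merged[key] = LabeledPair(p.sample_id, p.gene, kind, p.label, p.strategy)

    rows = [
        {
            "sample": p.sample_id,
            "gene": p.gene,
            "alteration_kind": p.alteration_kind,
            "label": p.label,
            "strategy": p.strategy,
        }
        for p in sorted(merged.values(), key=lambda p: (p.sample_id, p.gene))
    ]
    df = pd.DataFrame(
        rows, columns=["sample", "gene", "alteration_kind", "label", "strategy"]
    )
    labeled = df[df["label"] != "UNLABELED"].reset_index(drop=True)
    unlabeled = df[df["label"] == "UNLABELED"].reset_index(drop=True)
    counts = {
        lab: int((labeled["label"] == lab).sum())
        for lab in ("NEUTRAL", "DRIVER", "TSG", "OG")
    }
    logger.info("label counts: %s (+%d unlabeled)", counts, len(unlabeled))
    return labeled, unlabeled, counts
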