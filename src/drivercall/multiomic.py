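"""Multi-omic feature block: SNV + RNA + CNV + miRNA evidence per pair.

The row universe is the union of mutated pairs and pairs with a nonzero
copy-number score. CNV-only rows carry no mutation evidence; their SNV
block is zeroed and flagged by ``has_mutation = 0`` so the learner can
distinguish "benign score" from "no mutation". miRNA features are
sample-level: every gene of a sample shares the same onco-miRNA
expression block.
"""
from __future__ import annotations

import logging

import pandas as pd

from .config import RunConfig
from .expression import DEGProfile, RNA_FEATURES, assemble_rna_features
from .io import CNVMatrix, MiRNAMatrix, MutationRecord
from .network import NodeStats
from .snv import FeatureSetSpec, assemble_snv_features

logger = logging.getLogger(__name__)


def neigh_cnv_fc(
    gene: str,
    neighbors: set[str],
    cnv_map: dict[str, int],
    logfc_map: dict[str, float],
    tau: float,
) -> tuple[float, float]:
    """Neighborhood fold-change sum restricted to CNV-altered neighbors.

    A neighbor contributes iff its copy-number score is nonzero and its
    |logFC| exceeds tau; the normalized variant divides by the number of
    contributing neighbors.
    """
    contrib = [
        logfc_map[v]
        for v in neighbors
        if cnv_map.get(v, 0) != 0 and v in logfc_map and abs(logfc_map[v]) > tau
    ]
    if not contrib:
        return 0.0, 0.0
    total = float(sum(contrib))
    return total, total / len(contrib)


def mirna_block(mirna: MiRNAMatrix, sample: str, onco_mirnas: tuple[str, ...]) -> list[float]:
    """Sample-level expression of each declared onco-miRNA, in manifest order."""
    if sample not in mirna.expression.columns:
        logger.warning("sample %s absent from miRNA matrix; zero block used", sample)
        return [0.0] * len(onco_mirnas)
    col = mirna.expression[sample]
    out = []
    for m in onco_mirnas:
        if m in col.index:
            out.append(float(col[m]))
        else:
            logger.warning("onco-miRNA %s absent from matrix; 0 used", m)
            out.append(0.0)
    return out


def assemble_multiomic(
    mutations: list[MutationRecord],
    deg_profiles: dict[str, DEGProfile],
    node_stats: dict[str, NodeStats],
    cnv: CNVMatrix,
    mirna: MiRNAMatrix,
    config: RunConfig,
    feature_set: str | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Concatenate SNV, RNA, CNV and miRNA evidence per altered pair.

    ``samples`` restricts the row universe (default: samples having an
    expression profile). The "all"/"small" missing-score policy applies
    only to rows that carry a mutation; CNV-only rows are never dropped.
    """
    spec = FeatureSetSpec.from_config(config, feature_set)
    if samples is None:
        samples = sorted(deg_profiles)
    sample_set = set(samples)

    mutated_pairs = {
        (m.sample_id, m.gene) for m in mutations if m.sample_id in sample_set
    }
    cnv_pairs = {(s, g) for s, g in cnv.altered_pairs() if s in sample_set}
    universe = mutated_pairs | cnv_pairs

    snv = assemble_snv_features(
        [m for m in mutations if m.sample_id in sample_set], config, spec.name
    )
    snv = snv.set_index(["sample", "gene"])
    rna = assemble_rna_features(deg_profiles, node_stats, universe, config)
    rna = rna.set_index(["sample", "gene"])

    onco = config.onco_mirnas or mirna.onco_mirnas
    mirna_cols = [f"mirna_{m}" for m in onco]
    mirna_cache = {s: mirna_block(mirna, s, tuple(onco)) for s in samples}

    lfc_maps = {s: p.logfc_map() for s, p in deg_profiles.items()}
    cnv_maps = {
        s: cnv.scores[s].to_dict() for s in samples if s in cnv.scores.columns
    }

    rows = []
    for sample, gene in sorted(universe):
        has_mut = (sample, gene) in mutated_pairs
        if has_mut and (sample, gene) not in snv.index:
            # dropped by the "all" missing-score policy
            continue
        row: dict[str, object] = {"sample": sample, "gene": gene}
        if has_mut:
            row.update(snv.loc[(sample, gene)].to_dict())
        else:
            row.update({c: 0 for c in spec.columns()})
        row["has_mutation"] = int(has_mut)

        if (sample, gene) in rna.index:
            row.update(rna.loc[(sample, gene)].to_dict())
        else:
            logger.warning(
                "pair (%s, %s) has no expression row; zero RNA block used", sample, gene
            )
            row.update({c: 0.0 for c in RNA_FEATURES})

        if gene in cnv.scores.index and sample in cnv.scores.columns:
            row["cnv_score"] = int(cnv.scores.loc[gene, sample])
        else:
            row["cnv_score"] = 0

        ns = node_stats.get(gene)
        lfc_map = lfc_maps.get(sample, {})
        if ns is not None and sample in cnv_maps:
            cnv_map = cnv_maps[sample]
            neigh = ns.neighbors_by_hop.get(config.hops, set())
            nfc, nnfc = neigh_cnv_fc(gene, neigh, cnv_map, lfc_map, config.tau)
        else:
            nfc = nnfc = 0.0
        row["neigh_CNV_FC"] = nfc
        row["neigh_CNV_normFC"] = nnfc

        row.update(dict(zip(mirna_cols, mirna_cache[sample])))
        rows.append(row)

    columns = (
        ["sample", "gene"]
        + spec.columns()
        + list(RNA_FEATURES)
        + ["cnv_score", "neigh_CNV_FC", "neigh_CNV_normFC"]
        + mirna_cols
        + ["has_mutation"]
    )
    return pd.DataFrame(rows, columns=columns)
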