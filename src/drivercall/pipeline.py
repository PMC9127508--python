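"""End-to-end orchestration: cohort container, featurization, experiments.

A :class:`Cohort` bundles the six inputs the pipeline consumes. The
featurize step computes network statistics and single-sample expression
profiles once, applies one labeling strategy, and assembles the requested
feature block restricted to altered (sample, gene) pairs. The experiment
runner splits samples, trains a balanced ensemble, and evaluates held-out
pairs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import expression, labeling, model as model_mod, multiomic, network, snv
from .config import RunConfig
from .io import (
    CNVMatrix,
    CountsMatrix,
    DriverResources,
    EdgeList,
    MiRNAMatrix,
    MutationRecord,
    read_cnv,
    read_counts,
    read_driver_resources,
    read_mirna,
    read_mutations,
    read_network,
)

logger = logging.getLogger(__name__)

BLOCKS = ("snv", "rna", "multiomic")


@dataclass
class Cohort:
    """All inputs of one pipeline run."""

    mutations: list[MutationRecord]
    counts: CountsMatrix
    cnv: CNVMatrix
    mirna: MiRNAMatrix
    edges: EdgeList
    resources: DriverResources
    #: optional unfiltered edge table, kept so a cohort can be re-written
    #: to disk with its decoy edges intact
    raw_edge_table: pd.DataFrame | None = None


def load_cohort(directory: str | Path, config: RunConfig) -> Cohort:
    """Read a cohort from the documented file layout in ``directory``."""
    d = Path(directory)
    return Cohort(
        mutations=read_mutations(d / "mutations.tsv", config),
        counts=read_counts(d / "counts.tsv", d / "conditions.tsv"),
        cnv=read_cnv(d / "cnv.tsv"),
        mirna=read_mirna(d / "mirna.tsv", d / "onco_mirnas.tsv"),
        edges=read_network(d / "network.tsv", config),
        resources=read_driver_resources(
            d / "driver_mutations.tsv", d / "driver_genes.tsv", d / "neutral_genes.tsv"
        ),
    )


def label_cohort(
    cohort: Cohort,
    config: RunConfig,
    strategy: str,
    cancer_type: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Apply one labeling strategy; returns (labeled, unlabeled, counts)."""
    neutral = cohort.resources.neutral_genes
    if strategy in ("MUTATION_EXACT_BINARY", "MUTATION_EXACT_TSG_OG"):
        drivers = labeling.filter_mutation_drivers(cohort.resources, config)
        pairs = labeling.label_mutation_exact(
            cohort.mutations,
            drivers,
            neutral,
            binary=(strategy == "MUTATION_EXACT_BINARY"),
        )
    elif strategy in ("GENE_PAN", "GENE_CANCER_SPECIFIC"):
        mutated = {(m.sample_id, m.gene) for m in cohort.mutations}
        cnv_pairs = cohort.cnv.altered_pairs()
        ct = None if strategy == "GENE_PAN" else cancer_type
        if strategy == "GENE_CANCER_SPECIFIC" and cancer_type is None:
            raise ValueError("GENE_CANCER_SPECIFIC requires a cancer_type")
        pairs = labeling.label_gene_level(
            mutated, cnv_pairs, cohort.resources.gene_drivers, neutral, ct
        )
    else:
        raise ValueError(f"unknown labeling strategy {strategy!r}")
    return labeling.build_label_table(pairs)


@dataclass
class FeaturizedCohort:
    """Feature table joined with labels for one (strategy, block) choice."""

    labeled: pd.DataFrame  # sample, gene, label + feature columns
    unlabeled: pd.DataFrame  # sample, gene + feature columns
    phi: float | None
    node_stats: dict


def featurize(
    cohort: Cohort,
    config: RunConfig,
    block: str = "multiomic",
    strategy: str = "GENE_PAN",
    cancer_type: str | None = None,
    phi_override: float | None = None,
) -> FeaturizedCohort:
    """Label altered pairs and build the requested feature block.

    ``phi_override`` reuses a stored cohort dispersion instead of
    re-estimating it (scoring future samples against a frozen cohort
    model).
    """
    if block not in BLOCKS:
        raise ValueError(f"unknown feature block {block!r}; expected one of {BLOCKS}")
    labeled, unlabeled, counts = label_cohort(cohort, config, strategy, cancer_type)
    logger.info("strategy %s: %s", strategy, counts)

    phi = None
    stats: dict = {}
    if block == "snv":
        features = snv.assemble_snv_features(cohort.mutations, config)
    else:
        stats = network.node_centralities(cohort.edges, max_hops=config.hops)
        if phi_override is not None:
            phi = phi_override
        else:
            phi = expression.estimate_common_bcv(cohort.counts).phi
        profiles = expression.all_sample_degs(cohort.counts, phi, config)
        if block == "rna":
            universe = set(
                zip(
                    pd.concat([labeled, unlabeled])["sample"],
                    pd.concat([labeled, unlabeled])["gene"],
                )
            )
            features = expression.assemble_rna_features(
                profiles, stats, universe, config
            )
        else:
            features = multiomic.assemble_multiomic(
                cohort.mutations,
                profiles,
                stats,
                cohort.cnv,
                cohort.mirna,
                config,
                samples=cohort.counts.tumor_samples,
            )

    lab = labeled.merge(features, on=["sample", "gene"], how="inner")
    unlab = unlabeled.merge(features, on=["sample", "gene"], how="inner")
    lab = lab.drop(columns=["alteration_kind", "strategy"])
    unlab = unlab.drop(columns=["alteration_kind", "strategy", "label"])
    return FeaturizedCohort(labeled=lab, unlabeled=unlab, phi=phi, node_stats=stats)


@dataclass
class ExperimentResult:
    trained: model_mod.TrainedModel
    train_report: model_mod.EvaluationReport
    test_report: model_mod.EvaluationReport
    train_samples: list[str]
    test_samples: list[str]
    featurized: FeaturizedCohort


def run_experiment(
    cohort: Cohort,
    config: RunConfig,
    model_config: model_mod.ModelConfig,
    block: str = "multiomic",
    strategy: str = "GENE_PAN",
    cancer_type: str | None = None,
    featurized: FeaturizedCohort | None = None,
) -> ExperimentResult:
    """Featurize, split at the sample level, train, and evaluate."""
    if featurized is None:
        featurized = featurize(cohort, config, block, strategy, cancer_type)
    lab = featurized.labeled
    train_s, test_s = split_labeled(lab, config)
    tr = lab[lab["sample"].isin(train_s)]
    te = lab[lab["sample"].isin(test_s)]
    trained = model_mod.train(tr, tr["label"], model_config)
    return ExperimentResult(
        trained=trained,
        train_report=model_mod.evaluate(trained, tr, tr["label"]),
        test_report=model_mod.evaluate(trained, te, te["label"]),
        train_samples=train_s,
        test_samples=test_s,
        featurized=featurized,
    )


def split_labeled(labeled: pd.DataFrame, config: RunConfig) -> tuple[list[str], list[str]]:
    return model_mod.split_samples(
        labeled["sample"].tolist(), config.split_ratio, config.seed
    )
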