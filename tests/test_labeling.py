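import logging

import pandas as pd
import pytest

from drivercall import labeling, pipeline
from drivercall.config import MISSING, RunConfig
from drivercall.io import DriverResources

from conftest import DATA_DIR

STRATEGIES = [
    ("MUTATION_EXACT_BINARY", None),
    ("MUTATION_EXACT_TSG_OG", None),
    ("GENE_PAN", None),
    ("GENE_CANCER_SPECIFIC", "TOY"),
]


@pytest.mark.parametrize("strategy,cancer_type", STRATEGIES)
def test_toy_fixture_matches_hand_enumerated_tables(toy, strategy, cancer_type):
    cohort, config = toy
    labeled, unlabeled, _ = pipeline.label_cohort(cohort, config, strategy, cancer_type)
    got = (
        pd.concat([labeled, unlabeled])
        .sort_values(["sample", "gene"])
        .reset_index(drop=True)
    )
    expected = pd.read_csv(DATA_DIR / f"toy_labels_{strategy}.tsv", sep="\t")
    pd.testing.assert_frame_equal(got, expected)


def test_evidence_threshold_is_strict(toy):
    cohort, config = toy
    drivers = labeling.filter_mutation_drivers(cohort.resources, config)
    assert ("G1", 100, "A", "T") in drivers  # evidence 20 > 15
    assert ("G1", 150, "C", "G") not in drivers  # evidence exactly 15: dropped


def test_missing_evidence_kept_only_when_precurated():
    mut = pd.DataFrame(
        [("G1", 10, "A", "T", "TSG", MISSING), ("G2", 20, "C", "G", "OG", 50.0)],
        columns=["gene", "pos", "ref", "alt", "label", "evidence_score"],
    )
    resources = DriverResources(
        mut, pd.DataFrame(columns=["gene", "tag", "cancer_type"]), set()
    )
    strict = labeling.filter_mutation_drivers(resources, RunConfig())
    assert set(strict) == {("G2", 20, "C", "G")}
    curated = labeling.filter_mutation_drivers(
        resources, RunConfig(mutation_drivers_precurated=True)
    )
    assert set(curated) == {("G1", 10, "A", "T"), ("G2", 20, "C", "G")}


def test_gene_is_the_classification_unit(toy):
    """One exact driver match labels the pair even with extra non-matching muts."""
    cohort, config = toy
    drivers = labeling.filter_mutation_drivers(cohort.resources, config)
    pairs = labeling.label_mutation_exact(
        cohort.mutations, drivers, cohort.resources.neutral_genes, binary=False
    )
    by_key = {(p.sample_id, p.gene): p.label for p in pairs}
    # (S1, G1) carries the exact match at pos 100 plus a non-matching mutation
    assert by_key[("S1", "G1")] == "TSG"
    # same gene, different position in S2: stays unlabeled
    assert by_key[("S2", "G1")] == "UNLABELED"


def test_tsg_og_conflict_is_unlabeled_with_warning(toy, caplog):
    cohort, config = toy
    drivers = labeling.filter_mutation_drivers(cohort.resources, config)
    with caplog.at_level(logging.WARNING):
        pairs = labeling.label_mutation_exact(
            cohort.mutations, drivers, cohort.resources.neutral_genes, binary=False
        )
    by_key = {(p.sample_id, p.gene): p.label for p in pairs}
    assert by_key[("S3", "G5")] == "UNLABELED"
    assert "both TSG and OG" in caplog.text
    # in the binary strategy the same pair is simply DRIVER
    binary = labeling.label_mutation_exact(
        cohort.mutations, drivers, cohort.resources.neutral_genes, binary=True
    )
    assert {(p.sample_id, p.gene): p.label for p in binary}[("S3", "G5")] == "DRIVER"


def test_gene_role_sets_exclude_dual_role_and_ignore_unknown_tags(caplog):
    gene_drivers = pd.DataFrame(
        [
            ("G1", "tsg", "PAN"),
            ("G2", "Possible Oncogene", "PAN"),  # tags are case-insensitive
            ("G3", "tsg", "PAN"),
            ("G3", "oncogene", "PAN"),
            ("G4", "fusion", "PAN"),
            ("G5", "tsg", "BRCA"),
        ],
        columns=["gene", "tag", "cancer_type"],
    )
    with caplog.at_level(logging.WARNING):
        tsg, og = labeling.gene_role_sets(gene_drivers, None)
    assert tsg == {"G1"} and og == {"G2"}
    assert "fusion" in caplog.text and "G3" in caplog.text
    tsg_brca, og_brca = labeling.gene_role_sets(gene_drivers, "BRCA")
    assert tsg_brca == {"G5"} and og_brca == set()


def test_neutral_label_is_identical_across_strategies(toy):
    cohort, config = toy
    for strategy, ct in STRATEGIES:
        labeled, _, _ = pipeline.label_cohort(cohort, config, strategy, ct)
        neutral = labeled[labeled["gene"] == "G3"]
        assert (neutral["label"] == "NEUTRAL").all() and len(neutral) == 1


def test_build_label_table_merges_kinds_and_rejects_conflicts():
    mk = labeling.LabeledPair
    merged, _, counts = labeling.build_label_table(
        [
            mk("S1", "G1", "MUTATION", "TSG", "GENE_PAN"),
            mk("S1", "G1", "CNV", "TSG", "GENE_PAN"),
        ]
    )
    assert merged["alteration_kind"].tolist() == ["BOTH"]
    assert counts["TSG"] == 1
    with pytest.raises(ValueError, match="conflicting"):
        labeling.build_label_table(
            [
                mk("S1", "G1", "MUTATION", "TSG", "GENE_PAN"),
                mk("S1", "G1", "CNV", "OG", "GENE_PAN"),
            ]
        )


def test_cancer_specific_strategy_requires_cancer_type(toy):
    cohort, config = toy
    with pytest.raises(ValueError, match="cancer_type"):
        pipeline.label_cohort(cohort, config, "GENE_CANCER_SPECIFIC", None)
    with pytest.raises(ValueError, match="unknown labeling strategy"):
        pipeline.label_cohort(cohort, config, "MAJORITY_VOTE", None)
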