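import numpy as np
import pandas as pd
import pytest

from drivercall import expression, synth
from drivercall.config import RunConfig
from drivercall.io import CountsMatrix, NORMAL, TUMOR

from oracles import oracle_neigh_fc


def test_cpm_requires_positive_library_size():
    df = pd.DataFrame({"S1": [1, 2], "S2": [0, 0]}, index=["G1", "G2"])
    with pytest.raises(ValueError, match="zero library size"):
        expression.cpm_matrix(df)


def test_cpm_values_by_hand():
    df = pd.DataFrame({"S1": [250, 750]}, index=["G1", "G2"])
    cpms = expression.cpm_matrix(df)
    assert cpms.loc["G1", "S1"] == pytest.approx(250_000.0)
    assert cpms.loc["G2", "S1"] == pytest.approx(750_000.0)


def test_bcv_recovery_on_nb_counts():
    counts = synth.simulate_nb_counts(2000, 15, 15, bcv=0.4, seed=42)
    est = expression.estimate_common_bcv(counts)
    assert 0.3 <= est.bcv <= 0.5
    assert not est.at_boundary
    assert est.n_genes_used > 1900


def test_bcv_near_zero_on_poisson_counts():
    counts = synth.simulate_nb_counts(2000, 15, 15, bcv=0.0, seed=42)
    est = expression.estimate_common_bcv(counts)
    assert est.bcv < 0.05


def test_bcv_needs_replication():
    counts = synth.simulate_nb_counts(50, 1, 5, bcv=0.4, seed=0)
    with pytest.raises(ValueError, match="two samples per condition"):
        expression.estimate_common_bcv(counts)


def test_logfc_recovery_of_planted_fold_changes():
    """Planted 4-fold genes (a small fraction, so CPM stays valid) are
    recovered per gene with median |error| <= 0.3 log2 units."""
    n_genes = 2000
    logfc = np.zeros(n_genes)
    planted = np.arange(0, n_genes, 40)  # 50 genes
    logfc[planted] = 2.0
    counts = synth.simulate_nb_counts(n_genes, 15, 15, bcv=0.4, seed=42, logfc=logfc)
    config = RunConfig()
    phi = expression.estimate_common_bcv(counts).phi
    profiles = expression.all_sample_degs(counts, phi, config)
    per_gene = np.vstack([p.logfc for p in profiles.values()]).mean(axis=0)
    normal_mean = counts.counts[counts.normal_samples].mean(axis=1).to_numpy()
    sel = np.zeros(n_genes, bool)
    sel[planted] = True
    sel &= normal_mean >= 200
    assert sel.sum() >= 20
    assert np.median(np.abs(per_gene[sel] - 2.0)) <= 0.3


def _toy_counts():
    df = pd.DataFrame(
        {
            "T1": [400, 100, 50],
            "T2": [100, 100, 50],
            "N1": [100, 100, 50],
            "N2": [100, 100, 50],
        },
        index=["G1", "G2", "G3"],
    )
    cond = {"T1": TUMOR, "T2": TUMOR, "N1": NORMAL, "N2": NORMAL}
    return CountsMatrix(df, cond)


def test_single_sample_deg_by_hand():
    counts = _toy_counts()
    config = RunConfig()
    prof = expression.single_sample_deg(counts, "T1", phi=0.16, config=config)
    # library sizes: T1=550, others=250; prior 0.5
    cpm_t = 400 / 550 * 1e6
    cpm_n = 100 / 250 * 1e6
    expected = np.log2(cpm_t + 0.5) - np.log2(cpm_n + 0.5)
    assert prof.logfc[0] == pytest.approx(expected, abs=1e-12)
    assert bool(prof.is_deg[0]) == bool(abs(expected) > config.tau)
    assert np.all((prof.p_value >= 0) & (prof.p_value <= 1))
    mean_cpm = np.mean([cpm_t, cpm_n, cpm_n])
    assert prof.logcpm[0] == pytest.approx(np.log2(mean_cpm + 0.5), abs=1e-12)


def test_single_sample_deg_rejects_non_tumor_sample():
    counts = _toy_counts()
    with pytest.raises(ValueError, match="not a tumor sample"):
        expression.single_sample_deg(counts, "N1", 0.1, RunConfig())


def test_neigh_fc_matches_definition():
    logfc_map = {"A": 2.0, "B": -1.5, "C": 0.5, "D": 3.0}
    total, norm = expression.neigh_fc("X", {"A", "B", "C", "E"}, logfc_map, tau=1.0)
    assert total == pytest.approx(2.0 - 1.5)
    assert norm == pytest.approx((2.0 - 1.5) / 2)
    assert expression.neigh_fc("X", {"C"}, logfc_map, tau=1.0) == (0.0, 0.0)


def test_neigh_fc_matches_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(30)]
    for _ in range(50):
        logfc_map = {
            g: float(rng.normal(0, 2)) for g in genes if rng.random() < 0.8
        }
        neighbors = {g for g in genes if rng.random() < 0.3}
        tau = float(rng.uniform(0.2, 2.0))
        got = expression.neigh_fc("X", neighbors, logfc_map, tau)
        want = oracle_neigh_fc("X", neighbors, logfc_map, tau)
        assert got == pytest.approx(want, abs=1e-9)


def test_rna_feature_assembly_on_toy(toy):
    cohort, config = toy
    from drivercall import network

    phi = expression.estimate_common_bcv(cohort.counts).phi
    profiles = expression.all_sample_degs(cohort.counts, phi, config)
    stats = network.node_centralities(cohort.edges, max_hops=config.hops)
    pairs = {("S1", "G1"), ("S1", "G2"), ("S3", "G6")}
    table = expression.assemble_rna_features(profiles, stats, pairs, config)
    assert list(table.columns) == ["sample", "gene", *expression.RNA_FEATURES]
    assert len(table) == 3
    g6 = table[table["gene"] == "G6"].iloc[0]
    # G6 is off-network: zero centralities and neighborhood features
    assert g6["degree"] == 0 and g6["closeness"] == 0 and g6["neigh_FC"] == 0
    g1 = table[(table["sample"] == "S1") & (table["gene"] == "G1")].iloc[0]
    assert g1["logFC_x_degree"] == pytest.approx(g1["logFC"] * g1["degree"])
    assert g1["is_deg"] == int(abs(g1["logFC"]) > config.tau)
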