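import filecmp
import logging

import numpy as np
import pandas as pd
import pytest

from drivercall import model as model_mod
from drivercall import pipeline, synth


def test_infeasible_config_is_fatal():
    with pytest.raises(ValueError, match="planted classes"):
        synth.SynthConfig(n_genes=20, n_tsg=10, n_og=10, n_neutral=10)
    with pytest.raises(ValueError, match="normal"):
        synth.SynthConfig(n_samples=10, n_normal=10)


def test_planted_classes_are_disjoint_and_sized(small_synth):
    cfg, cohort, truth = small_synth
    tsg = {g for g, c in truth.gene_class.items() if c == "TSG"}
    og = {g for g, c in truth.gene_class.items() if c == "OG"}
    neutral = {g for g, c in truth.gene_class.items() if c == "NEUTRAL"}
    assert len(tsg) == cfg.n_tsg and len(og) == cfg.n_og and len(neutral) == cfg.n_neutral
    assert not (tsg & og) and not (tsg & neutral) and not (og & neutral)
    assert (cohort.counts.counts.to_numpy() >= 0).all()


def test_ground_truth_is_consistent_with_emitted_files(small_synth):
    cfg, cohort, truth = small_synth
    mutated = {(m.sample_id, m.gene) for m in cohort.mutations}
    cnv_altered = cohort.cnv.altered_pairs()
    assert set(truth.pair_class) == mutated | cnv_altered
    # neutral-list genes in the resources match the planted neutral class
    planted_neutral = {g for g, c in truth.gene_class.items() if c == "NEUTRAL"}
    assert cohort.resources.neutral_genes == planted_neutral
    # every gene-level driver row refers to a planted driver or a named decoy
    tags = cohort.resources.gene_drivers
    real = tags[~tags["tag"].isin(["fusion"])]
    roles = {g for g, c in truth.gene_class.items() if c in ("TSG", "OG")}
    decoy_dual = set(real["gene"]) - roles
    assert len(decoy_dual) == 1  # the planted dual-role decoy


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = synth.SynthConfig(n_samples=20, n_normal=6, n_genes=50, n_tsg=4, n_og=4,
                            n_neutral=12, seed=3)
    for d in ("a", "b"):
        cohort, truth = synth.simulate_cohort(cfg)
        synth.write_cohort(cohort, truth, tmp_path / d, synth.default_run_config(cfg))
    files = sorted(p.name for p in (tmp_path / "a").iterdir())
    assert "ground_truth.tsv" in files
    match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", files, shallow=False)
    assert mismatch == [] and errors == []
    assert sorted(match) == files


def test_written_cohort_loads_without_warnings(small_synth, tmp_path, caplog):
    cfg, cohort, truth = small_synth
    run_cfg = synth.default_run_config(cfg)
    synth.write_cohort(cohort, truth, tmp_path, run_cfg)
    with caplog.at_level(logging.WARNING):
        loaded = pipeline.load_cohort(tmp_path, run_cfg)
    assert caplog.text == ""
    assert len(loaded.mutations) == len(cohort.mutations)
    pd.testing.assert_frame_equal(
        loaded.counts.counts, cohort.counts.counts, check_names=False
    )
    # decoy sub-threshold edges present in the file are filtered on read
    raw = pd.read_csv(tmp_path / "network.tsv", sep="\t")
    assert len(raw) > len(loaded.edges)

    def canonical(edges):
        return {
            (min(a, b), max(a, b), e, d)
            for a, b, e, d in edges.edges.itertuples(index=False)
        }

    assert canonical(loaded.edges) == canonical(cohort.edges)


def test_network_is_scale_free_ish_with_hub_biased_drivers(default_cohort):
    cfg, cohort, truth = default_cohort
    degs = {}
    for a, b in cohort.edges.pairs():
        degs[a] = degs.get(a, 0) + 1
        degs[b] = degs.get(b, 0) + 1
    drivers = [g for g, c in truth.gene_class.items() if c in ("TSG", "OG")]
    driver_deg = np.mean([degs.get(g, 0) for g in drivers])
    overall_deg = np.mean(list(degs.values()))
    assert driver_deg > overall_deg  # hub bias


def test_bcv_recovery_band_on_default_cohort(default_experiment):
    assert 0.3 <= np.sqrt(default_experiment.featurized.phi) <= 0.5


def test_og_recall_rises_with_damaging_score_shift():
    """Non-strict monotonicity of OG recall across three separation levels
    between driver and benign impact-score distributions, at fixed seed."""
    recalls = []
    for lo, hi in [(0.15, 0.4), (0.4, 0.65), (0.65, 0.9)]:
        scfg = synth.SynthConfig(seed=0, driver_score_range=(lo, hi))
        cohort, _ = synth.simulate_cohort(scfg)
        run_cfg = synth.default_run_config(scfg)
        run_cfg.feature_set = "all"
        fz = pipeline.featurize(cohort, run_cfg, "snv", "GENE_PAN")
        lab = fz.labeled
        train_s, test_s = pipeline.split_labeled(lab, run_cfg)
        tr = lab[lab["sample"].isin(train_s)]
        te = lab[lab["sample"].isin(test_s)]
        mc = model_mod.ModelConfig(
            algorithm="balanced_bagging", grid={"n_estimators": [100]}, seed=run_cfg.seed
        )
        trained = model_mod.train(tr, tr["label"], mc)
        report = model_mod.evaluate(trained, te, te["label"])
        recalls.append(report.per_class["OG"]["recall"])
    assert all(a <= b + 1e-12 for a, b in zip(recalls, recalls[1:])), recalls


def test_toy_worked_example_structure(toy):
    cohort, config = toy
    assert cohort.counts.tumor_samples == ["S1", "S2", "S3"]
    assert cohort.counts.normal_samples == ["N1", "N2"]
    # every toy library sums to 1000 reads so CPM values are hand-checkable
    assert (cohort.counts.counts.sum(axis=0) == 1000).all()
    # the boundary edge (max score exactly 700) and the self-loop were dropped
    kept = set(map(frozenset, cohort.edges.pairs()))
    assert frozenset({"G1", "G6"}) not in kept
    assert frozenset({"G6"}) not in kept
    assert len(cohort.edges) == 4
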