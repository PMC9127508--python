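"""Shared fixtures.

The default synthetic cohort and the model trained on it are expensive
(seconds each), so they are built once per session and shared by the unit
and acceptance tests that only read them.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from drivercall import model as model_mod
from drivercall import pipeline, synth
from drivercall.config import RunConfig

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy():
    """The hand-checkable 6-gene / 3-tumor-sample worked example."""
    return synth.toy_worked_example()


@pytest.fixture(scope="session")
def small_synth():
    """A reduced synthetic cohort for fast pipeline/CLI exercises."""
    cfg = synth.SynthConfig(
        n_samples=30, n_normal=8, n_genes=80, n_tsg=6, n_og=6, n_neutral=20, seed=7
    )
    cohort, truth = synth.simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: the package's stated study conditions."""
    cfg = synth.SynthConfig()
    cohort, truth = synth.simulate_cohort(cfg)
    return cfg, cohort, truth


@dataclass
class ExperimentBundle:
    synth_config: synth.SynthConfig
    cohort: pipeline.Cohort
    truth: synth.GroundTruth
    run_config: RunConfig
    model_config: model_mod.ModelConfig
    featurized: pipeline.FeaturizedCohort
    train_samples: list
    test_samples: list
    train_table: pd.DataFrame
    test_table: pd.DataFrame
    trained: model_mod.TrainedModel
    test_report: model_mod.EvaluationReport


@pytest.fixture(scope="session")
def default_experiment(default_cohort) -> ExperimentBundle:
    """Multi-omic "small" features + balanced bagging on the default cohort."""
    scfg, cohort, truth = default_cohort
    run_config = synth.default_run_config(scfg)
    run_config.feature_set = "small"
    model_config = model_mod.ModelConfig(
        algorithm="balanced_bagging", grid={"n_estimators": [100]}, seed=run_config.seed
    )
    fz = pipeline.featurize(cohort, run_config, "multiomic", "GENE_PAN")
    lab = fz.labeled
    train_s, test_s = pipeline.split_labeled(lab, run_config)
    tr = lab[lab["sample"].isin(train_s)]
    te = lab[lab["sample"].isin(test_s)]
    trained = model_mod.train(tr, tr["label"], model_config)
    report = model_mod.evaluate(trained, te, te["label"])
    return ExperimentBundle(
        synth_config=scfg,
        cohort=cohort,
        truth=truth,
        run_config=run_config,
        model_config=model_config,
        featurized=fz,
        train_samples=train_s,
        test_samples=test_s,
        train_table=tr,
        test_table=te,
        trained=trained,
        test_report=report,
    )
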