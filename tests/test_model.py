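import json

import numpy as np
import pandas as pd
import pytest

from drivercall import model as model_mod
from drivercall.io import EdgeList

from oracles import oracle_metrics


def _feature_frame(seed=0, n_samples=20, pairs_per_sample=12):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_samples):
        for j in range(pairs_per_sample):
            label = rng.choice(["NEUTRAL", "TSG", "OG"], p=[0.6, 0.25, 0.15])
            f1 = rng.normal(2 if label == "TSG" else 0, 1)
            f2 = rng.normal(2 if label == "OG" else 0, 1)
            rows.append(
                {"sample": f"S{i:02d}", "gene": f"G{j:02d}", "label": label,
                 "f1": f1, "f2": f2, "f3": rng.normal()}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splitting

def test_split_is_deterministic_sample_level_and_exhaustive():
    ids = [f"S{i}" for i in range(10)] * 3
    train, test = model_mod.split_samples(ids, 0.7, seed=1)
    assert len(train) == 7 and len(test) == 3
    assert set(train) | set(test) == set(ids)
    assert set(train) & set(test) == set()
    assert (train, test) == model_mod.split_samples(ids, 0.7, seed=1)
    assert (train, test) != model_mod.split_samples(ids, 0.7, seed=2)


def test_split_never_empties_a_side():
    train, test = model_mod.split_samples(["A", "B"], 0.99, seed=0)
    assert len(train) == 1 and len(test) == 1
    with pytest.raises(ValueError):
        model_mod.split_samples(["A"], 0.7, seed=0)


# ---------------------------------------------------------------------------
# training and evaluation

def test_train_evaluate_with_single_grid_point():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [20]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    assert trained.feature_names == ["f1", "f2", "f3"]
    report = model_mod.evaluate(trained, df, df["label"])
    assert 0.0 <= report.accuracy <= 1.0
    assert set(report.per_class) == {"NEUTRAL", "OG", "TSG"}
    assert report.confusion.to_numpy().sum() == len(df)


def test_grid_search_groups_by_sample():
    df = _feature_frame(n_samples=12)
    mc = model_mod.ModelConfig(
        grid={"n_estimators": [10, 20], "max_depth": [None, 5]}, cv_folds=3, seed=0
    )
    trained = model_mod.train(df, df["label"], mc)
    assert trained.best_params["n_estimators"] in (10, 20)
    assert trained.best_params["max_depth"] in (None, 5)


def test_train_rejects_nan_features_and_single_class():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [5]})
    bad = df.copy()
    bad.loc[0, "f1"] = np.nan
    with pytest.raises(ValueError, match="missing values"):
        model_mod.train(bad, bad["label"], mc)
    with pytest.raises(ValueError, match="single class"):
        model_mod.train(df, ["TSG"] * len(df), mc)


def test_metrics_match_independent_oracle():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [20]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    report = model_mod.evaluate(trained, df, df["label"])
    oracle = oracle_metrics(report.confusion.to_numpy(), list(report.confusion.index))
    assert report.accuracy == pytest.approx(oracle["accuracy"], abs=1e-9)
    for cls, vals in oracle["per_class"].items():
        for metric in ("precision", "recall", "f1"):
            got = report.per_class[cls][metric]
            want = vals[metric]
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)


def test_zero_support_class_gets_nan_metrics():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [20]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    subset = df[df["label"] != "OG"]
    report = model_mod.evaluate(trained, subset, subset["label"])
    assert np.isnan(report.per_class["OG"]["recall"])
    assert np.isnan(report.per_class["OG"]["f1"])
    # macro-F1 over present classes ignores the NaN class
    assert not np.isnan(report.macro_f1(["NEUTRAL", "TSG"]))


def test_report_serializes_to_json(tmp_path):
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [10]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    report = model_mod.evaluate(trained, df, df["label"])
    path = tmp_path / "metrics.json"
    report.to_json(path)
    raw = json.loads(path.read_text())
    assert raw["accuracy"] == pytest.approx(report.accuracy)
    assert raw["confusion"]["classes"] == list(report.confusion.index)


# ---------------------------------------------------------------------------
# controls

def test_permuted_label_control_collapses_f1():
    df = _feature_frame(n_samples=30)
    train_s, test_s = model_mod.split_samples(df["sample"].tolist(), 0.7, 0)
    tr = df[df["sample"].isin(train_s)]
    te = df[df["sample"].isin(test_s)]
    mc = model_mod.ModelConfig(grid={"n_estimators": [30]}, seed=0)
    trained = model_mod.train(tr, tr["label"], mc)
    true_f1 = model_mod.evaluate(trained, te, te["label"]).macro_f1(["TSG", "OG"])
    reports = model_mod.permuted_label_control(tr, tr["label"], te, te["label"], mc, n_shuffles=2)
    assert len(reports) == 2
    for rep in reports:
        assert rep.macro_f1(["TSG", "OG"]) < true_f1


def _ring_edges(n=12):
    rows = [(f"g{i}", f"g{(i + 1) % n}", 800, 0) for i in range(n)]
    rows += [(f"g{i}", f"g{(i + 5) % n}", 900, 0) for i in range(0, n, 3)]
    return EdgeList(pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "experimental_score", "database_score"]
    ))


def test_node_label_randomization_preserves_degree_multiset():
    edges = _ring_edges()
    out = model_mod.randomize_network_control(edges, "node_label", seed=0)
    def degs(e):
        d = {}
        for a, b in e.pairs():
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
        return d
    assert sorted(degs(edges).values()) == sorted(degs(out).values())
    assert len(out) == len(edges)


def test_degree_preserving_randomization_preserves_each_degree():
    edges = _ring_edges()
    out = model_mod.randomize_network_control(edges, "degree_preserving", seed=0)
    def degs(e):
        d = {}
        for a, b in e.pairs():
            d[a] = d.get(a, 0) + 1
            d[b] = d.get(b, 0) + 1
        return d
    assert degs(edges) == degs(out)  # per-node degrees identical
    assert set(map(frozenset, out.pairs())) != set(map(frozenset, edges.pairs()))
    with pytest.raises(ValueError, match="unknown randomization"):
        model_mod.randomize_network_control(edges, "rewire_all", seed=0)


# ---------------------------------------------------------------------------
# ranking

def test_predict_and_rank_orders_by_driver_score_with_lexicographic_ties():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [20]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    preds, rankings = model_mod.predict_and_rank(trained, df)
    assert set(preds.columns) >= {"sample", "gene", "predicted", "driver_score"}
    np.testing.assert_allclose(
        preds["driver_score"], 1.0 - preds["p_NEUTRAL"], atol=1e-12
    )
    for sample, genes in rankings.items():
        sub = preds[preds["sample"] == sample].set_index("gene")
        scores = [sub.loc[g, "driver_score"] for g in genes]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))
        for g1, g2, s1, s2 in zip(genes, genes[1:], scores, scores[1:]):
            if s1 == s2:
                assert g1 < g2


def test_predict_refuses_mismatched_manifest():
    df = _feature_frame()
    mc = model_mod.ModelConfig(grid={"n_estimators": [5]}, seed=0)
    trained = model_mod.train(df, df["label"], mc)
    with pytest.raises(ValueError, match="manifest"):
        model_mod.predict_and_rank(trained, df.drop(columns=["f2"]))


def test_precision_at_rank_hand_arithmetic():
    rankings = {"S1": ["g1", "g2", "g3", "g4", "g5"]}
    reference = {"g1", "g3", "g9"}
    prec = model_mod.precision_at_rank(rankings, reference, k_max=5)
    np.testing.assert_allclose(prec, [1 / 1, 1 / 2, 2 / 3, 2 / 4, 2 / 5], atol=1e-12)


def test_precision_at_rank_exclusion_and_short_lists():
    rankings = {"S1": ["g1", "g2", "g3"], "S2": ["g4", "g5"]}
    reference = {"g1", "g4", "g5"}
    # exclude g1: S1 candidates become [g2, g3] with no hits
    prec = model_mod.precision_at_rank(rankings, reference, 3, exclude={"g1"})
    # k=3: S1 has 2 candidates -> 0/2; S2 has 2 -> 2/2
    np.testing.assert_allclose(prec, [(0 + 1) / 2, (0 + 1) / 2, (0 + 1) / 2])
    assert model_mod.precision_at_rank({}, reference, 2).tolist() == [0.0, 0.0]


def test_importance_consensus_averages_and_filters():
    df = _feature_frame()
    df = df.rename(columns={"f3": "domain_PF1"})
    mc = model_mod.ModelConfig(grid={"n_estimators": [10]}, seed=0)
    m1 = model_mod.train(df, df["label"], mc)
    m2 = model_mod.train(df, df["label"], model_mod.ModelConfig(
        algorithm="balanced_random_forest", grid={"n_estimators": [10]}, seed=1))
    rep = model_mod.importance_consensus([m1, m2], top_k=2)
    np.testing.assert_allclose(
        rep.consensus.to_numpy(),
        rep.per_model.mean(axis=1).to_numpy(), atol=1e-12,
    )
    assert len(rep.top) == 2
    assert set(rep.top_domains.index) <= {"domain_PF1"}
    with pytest.raises(ValueError, match="manifest"):
        model_mod.importance_consensus([m1, model_mod.train(
            df.rename(columns={"f1": "g1"}), df["label"], mc)])
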