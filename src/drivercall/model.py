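"""Training, evaluation, controls, ranking and feature-importance reporting.

Splitting is done at the sample level: all (sample, gene) pairs of one
patient fall on the same side of the train/test split, and the
cross-validation folds used for hyperparameter tuning group by sample as
well, so no patient leaks between folds. Tuning selects macro-F1 (the F1
of the driver class in the binary problem), since accuracy is dominated by
the neutral majority.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    make_scorer,
    precision_recall_curve,
    roc_curve,
)
from sklearn.model_selection import GridSearchCV, GroupKFold, StratifiedGroupKFold

from .ensembles import ALGORITHMS, _BalancedEnsemble, make_classifier
from .io import EdgeList

logger = logging.getLogger(__name__)

#: Default hyperparameter grid (estimator count x tree depth).
DEFAULT_GRID: dict[str, list] = {
    "n_estimators": [50, 100, 200],
    "max_depth": [None, 10, 20],
}


@dataclass
class ModelConfig:
    algorithm: str = "balanced_bagging"
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedModel:
    model: _BalancedEnsemble
    feature_names: list[str]
    classes: list[str]
    algorithm: str
    best_params: dict


@dataclass
class EvaluationReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # class -> precision/recall/f1/support
    confusion: pd.DataFrame  # rows true, columns predicted
    curves: dict[str, dict[str, list]] = field(default_factory=dict)

    def macro_f1(self, classes: Sequence[str] | None = None) -> float:
        classes = classes or list(self.per_class)
        vals = [self.per_class[c]["f1"] for c in classes if c in self.per_class]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": {
                "classes": list(self.confusion.index),
                "matrix": self.confusion.to_numpy().tolist(),
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def split_samples(
    sample_ids: Sequence[str], ratio: float, seed: int
) -> tuple[list[str], list[str]]:
    """Deterministic sample-level train/test split.

    All pairs belonging to one sample land on the same side; the split is a
    seeded permutation of the sorted sample list.
    """
    samples = sorted(set(sample_ids))
    if len(samples) < 2:
        raise ValueError("need at least two samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(np.floor(len(samples) * ratio + 0.5))
    n_train = min(max(n_train, 1), len(samples) - 1)
    train = sorted(samples[i] for i in order[:n_train])
    test = sorted(samples[i] for i in order[n_train:])
    return train, test


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("sample", "gene", "label", "strategy", "alteration_kind")]


def train(
    features: pd.DataFrame,
    labels: Sequence[str],
    model_config: ModelConfig,
) -> TrainedModel:
    """Grid-search, tune and refit a balanced ensemble on training pairs.

    ``features`` must contain ``sample``/``gene`` key columns; CV folds
    group by sample. With a single grid point the model is fit directly.
    """
    y = np.asarray(labels)
    classes = sorted(np.unique(y))
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    cols = feature_columns(features)
    X = features[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values; apply policies upstream")
    groups = features["sample"].to_numpy()

    grid_size = int(np.prod([len(v) for v in model_config.grid.values()]))
    if grid_size == 1:
        params = {k: v[0] for k, v in model_config.grid.items()}
        clf = make_classifier(
            model_config.algorithm, random_state=model_config.seed, **params
        )
        clf.fit(X, y)
        best_params = params
    else:
        if "DRIVER" in classes:
            scorer = make_scorer(
                f1_score, pos_label="DRIVER", average="binary", zero_division=0
            )
        else:
            scorer = make_scorer(f1_score, average="macro", zero_division=0)
        n_splits = min(model_config.cv_folds, len(np.unique(groups)))
        try:
            cv = list(
                StratifiedGroupKFold(
                    n_splits=n_splits, shuffle=True, random_state=model_config.seed
                ).split(X, y, groups)
            )
        except ValueError:
            cv = list(GroupKFold(n_splits=n_splits).split(X, y, groups))
        search = GridSearchCV(
            make_classifier(model_config.algorithm, random_state=model_config.seed),
            param_grid=model_config.grid,
            scoring=scorer,
            cv=cv,
            refit=True,
            n_jobs=1,
        )
        search.fit(X, y)
        clf = search.best_estimator_
        best_params = dict(search.best_params_)
        logger.info("grid search selected %s (score %.3f)", best_params, search.best_score_)

    return TrainedModel(
        model=clf,
        feature_names=cols,
        classes=[str(c) for c in clf.classes_],
        algorithm=model_config.algorithm,
        best_params=best_params,
    )


def evaluate(
    trained: TrainedModel, features: pd.DataFrame, labels: Sequence[str]
) -> EvaluationReport:
    """Confusion-matrix metrics plus one-vs-rest PR/ROC point sets.

    A class with zero support gets NaN ("undefined") metrics rather than 0.
    """
    y = np.asarray(labels)
    X = features[trained.feature_names].to_numpy(dtype=float)
    pred = trained.model.predict(X)
    proba = trained.model.predict_proba(X)
    classes = trained.classes
    cm = confusion_matrix(y, pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())

    per_class: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(classes):
        support = int(cm[i].sum())
        predicted = int(cm[:, i].sum())
        tp = int(cm[i, i])
        precision = tp / predicted if predicted > 0 else float("nan")
        recall = tp / support if support > 0 else float("nan")
        if support == 0:
            f1 = float("nan")
        elif np.isnan(precision) or precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }

    curves: dict[str, dict[str, list]] = {}
    for i, cls in enumerate(classes):
        y_bin = (y == cls).astype(int)
        if y_bin.sum() in (0, len(y_bin)):
            continue
        prec, rec, _ = precision_recall_curve(y_bin, proba[:, i])
        fpr, tpr, _ = roc_curve(y_bin, proba[:, i])
        curves[cls] = {
            "pr_precision": prec.tolist(),
            "pr_recall": rec.tolist(),
            "roc_fpr": fpr.tolist(),
            "roc_tpr": tpr.tolist(),
        }

    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    return EvaluationReport(accuracy, per_class, confusion, curves)


def permuted_label_control(
    train_features: pd.DataFrame,
    train_labels: Sequence[str],
    test_features: pd.DataFrame,
    test_labels: Sequence[str],
    model_config: ModelConfig,
    n_shuffles: int = 1,
) -> list[EvaluationReport]:
    """Retrain on uniformly permuted training labels; test labels untouched.

    An honest model's driver-class F1 should collapse toward chance under
    this control; persistence indicates leakage or overfitting.
    """
    reports = []
    for k in range(n_shuffles):
        rng = np.random.default_rng(model_config.seed + 104729 * (k + 1))
        y_perm = rng.permutation(np.asarray(train_labels))
        trained = train(train_features, y_perm, model_config)
        reports.append(evaluate(trained, test_features, test_labels))
    return reports


def randomize_network_control(edges: EdgeList, mode: str, seed: int) -> EdgeList:
    """Randomized networks for the structure-vs-signal control.

    ``node_label`` permutes node identities (degree multiset preserved,
    per-gene degrees not). ``degree_preserving`` applies double-edge swaps
    (10x|E| attempts), preserving every node's degree exactly; on
    degenerate graphs the best-effort result is returned with the achieved
    swap count logged.
    """
    rng = np.random.default_rng(seed)
    df = edges.edges
    if mode == "node_label":
        nodes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        out = df.assign(
            gene_a=df["gene_a"].map(mapping), gene_b=df["gene_b"].map(mapping)
        )
        return EdgeList(out.reset_index(drop=True))
    if mode != "degree_preserving":
        raise ValueError(f"unknown randomization mode {mode!r}")

    edge_list = [tuple(sorted(p)) for p in edges.pairs()]
    edge_set = set(edge_list)
    m = len(edge_list)
    swaps = 0
    for _ in range(10 * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if len({a, b, c, d}) < 4:
            continue
        new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.remove(edge_list[i])
        edge_set.remove(edge_list[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[i], edge_list[j] = new1, new2
        swaps += 1
    logger.info("degree-preserving randomization: %d swaps on %d edges", swaps, m)
    score_cols = df[["experimental_score", "database_score"]].iloc[: len(edge_list)]
    out = pd.DataFrame(edge_list, columns=["gene_a", "gene_b"])
    out["experimental_score"] = score_cols["experimental_score"].to_numpy()
    out["database_score"] = score_cols["database_score"].to_numpy()
    return EdgeList(out)


def predict_and_rank(
    trained: TrainedModel, features: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-pair class calls plus a per-sample driver ranking.

    The driver score is 1 - P(NEUTRAL); within each sample genes are
    ranked by descending score, ties broken lexicographically. The same
    gene may legitimately receive TSG in one sample and OG in another.
    """
    missing = [c for c in trained.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature manifest mismatch; missing columns {missing}")
    X = features[trained.feature_names].to_numpy(dtype=float)
    proba = trained.model.predict_proba(X)
    classes = trained.classes
    pred = [classes[i] for i in np.argmax(proba, axis=1)]
    if "NEUTRAL" in classes:
        driver_score = 1.0 - proba[:, classes.index("NEUTRAL")]
    else:
        driver_score = np.max(proba, axis=1)
    out = pd.DataFrame(
        {
            "sample": features["sample"].to_numpy(),
            "gene": features["gene"].to_numpy(),
            "predicted": pred,
            "driver_score": driver_score,
        }
    )
    for i, cls in enumerate(classes):
        out[f"p_{cls}"] = proba[:, i]
    rankings: dict[str, list[str]] = {}
    for sample, grp in out.groupby("sample"):
        grp = grp.sort_values(["driver_score", "gene"], ascending=[False, True])
        rankings[str(sample)] = list(grp["gene"])
    return out, rankings


def precision_at_rank(
    rankings: dict[str, list[str]],
    reference_genes: set[str],
    k_max: int,
    exclude: set[str] | None = None,
) -> np.ndarray:
    """Mean over samples of precision@k against a reference driver list.

    Excluded genes (e.g. genes the model trained on) are removed from each
    ranking before computing precision, so they count in neither the
    numerator nor the candidate list. Samples with fewer than k genes use
    the available count as denominator.
    """
    exclude = exclude or set()
    per_k = np.zeros(k_max)
    n_samples = 0
    for genes in rankings.values():
        genes = [g for g in genes if g not in exclude]
        if not genes:
            continue
        n_samples += 1
        hits = np.cumsum([g in reference_genes for g in genes])
        for k in range(1, k_max + 1):
            avail = min(k, len(genes))
            per_k[k - 1] += hits[avail - 1] / avail
    if n_samples == 0:
        return np.zeros(k_max)
    return per_k / n_samples


@dataclass
class ImportanceReport:
    consensus: pd.Series  # feature -> mean contribution across models
    per_model: pd.DataFrame  # feature x model
    top: pd.Series  # top-k consensus listing
    top_domains: pd.Series
    top_mirnas: pd.Series


def importance_consensus(
    models: list[TrainedModel], top_k: int = 20
) -> ImportanceReport:
    """Average impurity-based feature contributions across models.

    Each model's contribution vector already averages over its base
    estimators and sums to one; the consensus is the mean over models.
    Domain and miRNA sublists keep only features with consensus > 0.
    """
    if not models:
        raise ValueError("importance_consensus needs at least one model")
    names = models[0].feature_names
    for m in models[1:]:
        if m.feature_names != names:
            raise ValueError("models do not share a feature manifest")
    cols = {}
    for i, m in enumerate(models):
        if not hasattr(m.model, "feature_importances_"):
            raise ValueError("importance requires tree-ensemble models")
        cols[f"model_{i}_{m.algorithm}"] = m.model.feature_importances_
    per_model = pd.DataFrame(cols, index=names)
    consensus = per_model.mean(axis=1)
    top = consensus.sort_values(ascending=False).head(top_k)
    dom = consensus[consensus.index.str.startswith("domain_")]
    mir = consensus[consensus.index.str.startswith("mirna_")]
    return ImportanceReport(
        consensus=consensus,
        per_model=per_model,
        top=top,
        top_domains=dom[dom > 0].sort_values(ascending=False),
        top_mirnas=mir[mir > 0].sort_values(ascending=False),
    )
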