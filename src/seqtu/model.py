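"""RBF-SVM junction classifier, cross-validation and TU assembly.

A junction (consecutive same-strand gene pair) is classified as
co-transcribed or not from its six continuity/variance features. Features
are min–max scaled inside the model pipeline; the classifier is a support
vector machine with a radial-basis kernel at customary defaults
(cost C=1, gamma=1/n_features, uniform class weight). Training reports a
stratified five-fold cross-validation accuracy and per-example held-out
decision scores for ROC analysis; predicted positive junctions are chained
into maximal runs of genes, each run becoming one transcription unit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import sklearn.metrics as skm
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .annotation_io import GenePair, GenomeAnnotation, STRANDS
from .features import FEATURE_NAMES

MODEL_FORMAT_VERSION = 1

TRAINING_MODES = ("illumina_only", "illumina_plus_long_read")


@dataclass
class TrainingSet:
    """Feature matrix plus binary labels (1 = co-transcribed)."""

    X: np.ndarray
    y: np.ndarray
    mode: str = "illumina_plus_long_read"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature matrix and labels must have equal length")
        if self.mode not in TRAINING_MODES:
            raise ValueError(f"unknown training mode {self.mode!r}")

    @property
    def n_positive(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.y == 0).sum())


@dataclass
class TUModel:
    """A fitted junction classifier: min–max scaler + RBF SVM."""

    pipeline: Pipeline
    cost: float
    gamma: float | str
    class_weight: Mapping | str | None
    mode: str
    seed: int
    n_features: int = len(FEATURE_NAMES)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features}, got {X.shape}"
            )
        scores = self.pipeline.decision_function(X)
        return scores > 0, scores

    def save(self, path: str | os.PathLike) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "pipeline": self.pipeline,
                "cost": self.cost,
                "gamma": self.gamma,
                "class_weight": self.class_weight,
                "mode": self.mode,
                "seed": self.seed,
                "n_features": self.n_features,
            },
            os.fspath(path),
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TUModel":
        payload = joblib.load(os.fspath(path))
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        return cls(
            pipeline=payload["pipeline"],
            cost=payload["cost"],
            gamma=payload["gamma"],
            class_weight=payload["class_weight"],
            mode=payload["mode"],
            seed=payload["seed"],
            n_features=payload["n_features"],
        )


@dataclass(frozen=True)
class TU:
    """A predicted transcription unit: an ordered run of co-transcribed genes."""

    gene_ids: tuple[str, ...]
    strand: str
    start: int
    end: int
    dataset_id: str = "dataset"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class TUSet:
    """One dataset's TU prediction; the TUs partition the annotated genes."""

    tus: list[TU]
    annotation_ref: str

    def joined_junctions(self) -> set[tuple[str, str]]:
        """Consecutive gene-id pairs placed in the same TU."""
        joined: set[tuple[str, str]] = set()
        for tu in self.tus:
            for a, b in zip(tu.gene_ids, tu.gene_ids[1:]):
                joined.add((a, b))
        return joined

    def gene_ids(self) -> set[str]:
        return {g for tu in self.tus for g in tu.gene_ids}

    def __len__(self) -> int:
        return len(self.tus)


def _make_pipeline(cost: float, gamma, class_weight) -> Pipeline:
    return Pipeline(
        [
            ("scaler", MinMaxScaler()),
            ("svm", SVC(kernel="rbf", C=cost, gamma=gamma, class_weight=class_weight)),
        ]
    )


def train(
    ts: TrainingSet,
    folds: int = 5,
    seed: int = 0,
    cost: float = 1.0,
    gamma: float | str = "auto",
    class_weight=None,
) -> tuple[TUModel, float, pd.DataFrame]:
    """Fit the junction classifier with stratified k-fold cross-validation.

    Returns the model refitted on all data, the pooled cross-validation
    accuracy, and a frame of held-out (label, decision score, fold)
    triples for ROC analysis. ``gamma='auto'`` is 1/n_features.

    Raises
    ------
    ValueError
        If only one class is present ("degenerate training set") or a
        class has fewer examples than folds.
    """
    classes, counts = np.unique(ts.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate training set: both classes required")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} examples per class for {folds}-fold CV "
            f"(got {dict(zip(classes.tolist(), counts.tolist()))})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pipe = _make_pipeline(cost, gamma, class_weight)
    scores = cross_val_predict(pipe, ts.X, ts.y, cv=skf, method="decision_function")
    fold_of = np.empty(len(ts.y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(ts.X, ts.y)):
        fold_of[test_idx] = k
    fold_predictions = pd.DataFrame(
        {"y_true": ts.y, "score": scores, "fold": fold_of}
    )
    cv_accuracy = float(((scores > 0).astype(int) == ts.y).mean())
    final = _make_pipeline(cost, gamma, class_weight)
    final.fit(ts.X, ts.y)
    model = TUModel(
        pipeline=final,
        cost=cost,
        gamma=gamma,
        class_weight=class_weight,
        mode=ts.mode,
        seed=seed,
    )
    return model, cv_accuracy, fold_predictions


def predict_pairs(model: TUModel, candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label (True = co-transcribed) and decision score per candidate row."""
    return model.predict(candidates)


def assemble_tus(
    annotation: GenomeAnnotation,
    pair_predictions: Iterable[tuple[GenePair, bool]] | Mapping[tuple[str, str], bool],
    dataset_id: str = "dataset",
) -> TUSet:
    """Chain positive junctions into transcription units.

    Maximal runs of consecutive same-strand genes connected by positive
    junction predictions become multi-gene TUs; every other gene becomes a
    single-gene TU. The result partitions the annotated gene set. Every
    consecutive same-strand pair must carry a prediction (use False to
    force a split).
    """
    if isinstance(pair_predictions, Mapping):
        decision = dict(pair_predictions)
    else:
        decision = {pair.key: bool(label) for pair, label in pair_predictions}
    tus: list[TU] = []
    for strand in STRANDS:
        genes = annotation.genes_on_strand(strand)
        if not genes:
            continue
        run = [genes[0]]
        for left, right in zip(genes, genes[1:]):
            key = (left.id, right.id)
            if key not in decision:
                raise KeyError(f"missing prediction for junction {key}")
            if decision[key]:
                run.append(right)
            else:
                tus.append(_run_to_tu(run, strand, dataset_id))
                run = [right]
        tus.append(_run_to_tu(run, strand, dataset_id))
    tus.sort(key=lambda tu: (tu.start, tu.strand))
    return TUSet(tus=tus, annotation_ref=annotation.genome_id)


def _run_to_tu(run, strand: str, dataset_id: str) -> TU:
    return TU(
        gene_ids=tuple(g.id for g in run),
        strand=strand,
        start=run[0].start,
        end=max(g.end for g in run),
        dataset_id=dataset_id,
    )


SIZE_CATEGORIES = ("1", "2", "3", "4", "5+")


def tu_size_distribution(tuset: TUSet) -> dict[str, float]:
    """Percentage of TUs per gene-count category {1, 2, 3, 4, 5+}."""
    if not tuset.tus:
        raise ValueError("empty TU set")
    counts = dict.fromkeys(SIZE_CATEGORIES, 0)
    for tu in tuset.tus:
        key = str(tu.n_genes) if tu.n_genes < 5 else "5+"
        counts[key] += 1
    total = len(tuset.tus)
    return {k: 100.0 * v / total for k, v in counts.items()}


def distinct_tus(tusets: Sequence[TUSet]) -> set[tuple[str, tuple[str, ...]]]:
    """Distinct TUs across datasets, identified by (strand, gene-id tuple)."""
    return {(tu.strand, tu.gene_ids) for ts in tusets for tu in ts.tus}


def roc_curve(fold_predictions: pd.DataFrame):
    """ROC points and AUC from held-out cross-validation scores."""
    y = np.asarray(fold_predictions["y_true"])
    s = np.asarray(fold_predictions["score"])
    if len(np.unique(y)) < 2:
        raise ValueError("single-class truth: ROC undefined")
    fpr, tpr, thresholds = skm.roc_curve(y, s)
    auc = float(skm.roc_auc_score(y, s))
    return fpr, tpr, thresholds, auc
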