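"""End-to-end orchestration: simulate -> label -> train -> predict -> assemble.

Thin glue over the component modules, used by the command-line interface
and by evaluation experiments (depth titration) that must re-run the
prediction path many times on rebuilt coverage tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenePair, GenomeAnnotation, derive_gene_pairs
from .coverage import CoverageTrack, Reads, build_coverage
from .features import feature_matrix
from .labeling import (
    LabeledPair,
    construct_ctus,
    fit_length_densities,
    select_negative_pairs,
    select_positive_pairs_by_spanning,
)
from .model import TrainingSet, TUModel, TUSet, assemble_tus, train
from .synthetic_data import SimConfig, SimTruth, simulate_coverage, simulate_evidence, simulate_genome


@dataclass
class SimData:
    """One simulated dataset: truth, reads, coverage and evidence."""

    config: SimConfig
    truth: SimTruth
    reads: Reads
    track: CoverageTrack
    evidence: Reads


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int | None = None,
    evidence_kind: str = "long_read",
) -> SimData:
    """Generate genome, coverage and spanning evidence in one call.

    Component seeds are derived deterministically from the master seed
    (``config.seed`` unless overridden).
    """
    config = config or SimConfig()
    master = config.seed if seed is None else seed
    truth = simulate_genome(config, seed=master)
    reads, track = simulate_coverage(truth, config, seed=master + 1)
    evidence = simulate_evidence(truth, config, seed=master + 2, kind=evidence_kind)
    return SimData(config=config, truth=truth, reads=reads, track=track, evidence=evidence)


def build_training_examples(
    annotation: GenomeAnnotation,
    pairs: Sequence[GenePair],
    track: CoverageTrack,
    mode: str = "illumina_plus_long_read",
    evidence: Reads | None = None,
    seed: int = 0,
    evidence_stranded: bool = True,
) -> tuple[list[LabeledPair], TrainingSet]:
    """Assemble labeled junctions and their feature matrix.

    Negatives come from the gap/fold-change filters. Positives are
    constructed TUs; in ``illumina_plus_long_read`` mode, pairs certified
    by spanning evidence are added. The negative and positive criteria are
    mutually exclusive over gene pairs, so the label sets are disjoint.
    """
    labeled = list(select_negative_pairs(pairs, track))
    densities = fit_length_densities(annotation, pairs)
    for ctu in construct_ctus(annotation, densities, track, seed=seed):
        labeled.append(LabeledPair(pair=ctu, label="positive", source="cTU"))
    if mode == "illumina_plus_long_read":
        if evidence is None:
            raise ValueError("spanning evidence required for illumina_plus_long_read mode")
        labeled.extend(
            select_positive_pairs_by_spanning(pairs, evidence, track, stranded=evidence_stranded)
        )
    X = feature_matrix([lp.pair for lp in labeled], track)
    y = np.array([1 if lp.label == "positive" else 0 for lp in labeled], dtype=int)
    return labeled, TrainingSet(X=X, y=y, mode=mode)


@dataclass
class PipelineResult:
    model: TUModel
    cv_accuracy: float
    fold_predictions: pd.DataFrame
    tuset: TUSet
    pairs: list[GenePair]
    labeled: list[LabeledPair]
    training_set: TrainingSet
    scores: np.ndarray


def predict_and_assemble(
    model: TUModel,
    annotation: GenomeAnnotation,
    pairs: Sequence[GenePair],
    track: CoverageTrack,
    dataset_id: str = "dataset",
    split_on_opposite: bool = False,
) -> TUSet:
    """Classify every candidate junction on a track and chain TUs."""
    X = feature_matrix(list(pairs), track)
    labels, _ = model.predict(X)
    if split_on_opposite:
        labels = labels & ~np.array([p.has_opposite_strand_gene_between for p in pairs])
    return assemble_tus(annotation, zip(pairs, labels), dataset_id=dataset_id)


def run_tu_prediction(
    annotation: GenomeAnnotation,
    track: CoverageTrack,
    evidence: Reads | None = None,
    mode: str = "illumina_plus_long_read",
    seed: int = 0,
    dataset_id: str = "dataset",
    folds: int = 5,
    split_on_opposite: bool = False,
    evidence_stranded: bool = True,
) -> PipelineResult:
    """The full prediction pipeline on one dataset.

    Labels training junctions, trains the RBF-SVM classifier with
    stratified cross-validation, classifies all candidate pairs and
    assembles the TU set.
    """
    pairs = derive_gene_pairs(annotation)
    labeled, training_set = build_training_examples(
        annotation, pairs, track, mode=mode, evidence=evidence, seed=seed,
        evidence_stranded=evidence_stranded,
    )
    model, cv_accuracy, fold_predictions = train(training_set, folds=folds, seed=seed)
    X = feature_matrix(pairs, track)
    labels, scores = model.predict(X)
    if split_on_opposite:
        labels = labels & ~np.array([p.has_opposite_strand_gene_between for p in pairs])
    tuset = assemble_tus(annotation, zip(pairs, labels), dataset_id=dataset_id)
    return PipelineResult(
        model=model,
        cv_accuracy=cv_accuracy,
        fold_predictions=fold_predictions,
        tuset=tuset,
        pairs=pairs,
        labeled=labeled,
        training_set=training_set,
        scores=scores,
    )


def assembly_closure(
    model: TUModel,
    annotation: GenomeAnnotation,
    dataset_id: str = "resample",
    split_on_opposite: bool = False,
) -> Callable[[CoverageTrack], TUSet]:
    """Freeze a trained model into a track -> TUSet callable for
    depth-resampling experiments (features are re-extracted per track)."""
    pairs = derive_gene_pairs(annotation)

    def _run(track: CoverageTrack) -> TUSet:
        return predict_and_assemble(
            model, annotation, pairs, track, dataset_id=dataset_id,
            split_on_opposite=split_on_opposite,
        )

    return _run
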