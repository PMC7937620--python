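"""End-to-end experiment glue: gene sampling, masked representation,
cross-validated (or held-out) classification, and evaluation.

Every sampled gene has its own tags masked at representation time, so a
gene's resolved tag can never leak its label into its image, and training
and evaluation images come from one distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import evaluation
from .classifiers import LabeledSample, fit_score, permute_augment
from .network import DiseaseAnnotation, GeneNetwork
from .representation import (
    RepresentationDataset,
    default_radius,
    fuse_networks,
    represent_all,
    represent_all_baseline,
)

__all__ = ["ExperimentResult", "run_experiment"]


@dataclass
class ExperimentResult:
    kind: str
    representation: str
    seed: int
    auc: float
    report: evaluation.EvaluationReport
    predictions: pd.DataFrame
    params: dict = field(default_factory=dict)


def _sample_genes(
    annotation: DiseaseAnnotation, universe: list[str], seed: int
) -> tuple[list[str], list[str]]:
    target = annotation.target_class
    in_universe = set(universe)
    positives = sorted(
        g for g in annotation.tags if target in annotation.tags[g] and g in in_universe
    )
    pool = sorted(
        g
        for g in annotation.tags
        if target not in annotation.tags[g] and g in in_universe
    )
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} eligible negatives for {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(pool), size=len(positives), replace=False))
    return positives, [pool[i] for i in chosen]


def run_experiment(
    networks: list[GeneNetwork],
    annotation: DiseaseAnnotation,
    kind: str = "cnn",
    representation: str = "environment",
    seed: int = 0,
    m: int = 21,
    k: int | None = None,
    protocol: str = "cv",
    n_folds: int = 5,
    test_fraction: float = 0.2,
    mask_eval: bool = True,
    shuffle_labels: bool = False,
    n_aug: int = 0,
    cnn_kwargs: dict | None = None,
) -> ExperimentResult:
    """One full balanced binary classification experiment.

    ``representation`` is ``"environment"`` (per-vertex image with the class
    diagonal), ``"baseline"`` (consecutive leaf-order neighbors, no class
    information), or ``"fused"`` (mean image over all views; the first
    network is the reference). Single-view modes use ``networks[0]``.

    ``protocol="cv"`` pools out-of-fold scores from a stratified K-fold split
    (every gene is scored exactly once, by a model that never saw it);
    ``protocol="holdout"`` uses a single stratified train/test split.
    ``n_aug`` adds that many neighbor-permuted copies of each training sample
    for the CNN (ignored for classical learners).
    """
    reference = networks[0]
    if k is None:
        k = default_radius(reference.n, m)

    positives, negatives = _sample_genes(annotation, reference.genes, seed)
    genes = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    if shuffle_labels:
        labels = np.random.default_rng(seed + 104729).permutation(labels)

    mask = set(genes) if mask_eval else set()
    dataset: RepresentationDataset
    if representation == "environment":
        dataset = represent_all(
            reference, annotation, k=k, m=m, genes=genes, mask_centers=mask
        )
    elif representation == "baseline":
        dataset = represent_all_baseline(reference, m=m, genes=genes)
    elif representation == "fused":
        dataset = fuse_networks(
            networks, reference, annotation, k=k, m=m, genes=genes,
            mask_centers=mask,
        )
    else:
        raise ValueError(f"unknown representation {representation!r}")

    samples = [
        LabeledSample(gene=g, image=dataset.images[i], label=int(labels[i]))
        for i, g in enumerate(genes)
    ]

    def _scores_for(train_idx: np.ndarray, test_idx: np.ndarray) -> np.ndarray:
        train_s = [samples[i] for i in train_idx]
        if kind == "cnn" and n_aug:
            train_s = permute_augment(train_s, n_aug, seed)
        _, scores = fit_score(
            kind, train_s, [samples[i] for i in test_idx], seed,
            cnn_kwargs=cnn_kwargs,
        )
        return scores

    if protocol == "cv":
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        scores = np.zeros(len(samples))
        for train_idx, test_idx in skf.split(labels, labels):
            scores[test_idx] = _scores_for(train_idx, test_idx)
        eval_idx = np.arange(len(samples))
    elif protocol == "holdout":
        train_idx, test_idx = train_test_split(
            np.arange(len(samples)),
            test_size=test_fraction,
            stratify=labels,
            random_state=seed,
        )
        scores = _scores_for(train_idx, test_idx)
        eval_idx = test_idx
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    y_eval = labels[eval_idx]
    report = evaluation.evaluate(scores, y_eval)
    predictions = pd.DataFrame(
        {
            "gene": [genes[i] for i in eval_idx],
            "label": y_eval,
            "score": scores,
        }
    )
    return ExperimentResult(
        kind=kind,
        representation=representation,
        seed=seed,
        auc=float(report.auc),
        report=report,
        predictions=predictions,
        params={
            "m": m, "k": k, "protocol": protocol, "n_folds": n_folds,
            "test_fraction": test_fraction, "mask_eval": mask_eval,
            "shuffle_labels": shuffle_labels, "n_aug": n_aug,
        },
    )
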