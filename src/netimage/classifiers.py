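"""Binary classification of target-class genes from representation images.

The CNN consumes the m x m matrices directly; the five classical learners
(two SVMs, decision tree, extra trees, Gaussian naive Bayes) consume
row-major flattened vectors, standardized on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cnn import SimpleCNN
from .network import DiseaseAnnotation
from .representation import RepresentationDataset

__all__ = [
    "LabeledSample",
    "TrainedClassifier",
    "CLASSICAL_KINDS",
    "ALL_KINDS",
    "assemble_dataset",
    "flatten",
    "fit_score",
    "train",
    "cross_validate",
]

CLASSICAL_KINDS = (
    "svm_gaussian",
    "svm_polynomial",
    "decision_tree",
    "extra_trees",
    "naive_bayes",
)
ALL_KINDS = ("cnn",) + CLASSICAL_KINDS


@dataclass
class LabeledSample:
    gene: str
    image: np.ndarray
    label: int


@dataclass
class TrainedClassifier:
    """A fitted model with a uniform probability-score interface."""

    kind: str
    seed: int
    _model: object
    _scaler: StandardScaler | None = None

    def scores(self, samples: Sequence[LabeledSample]) -> np.ndarray:
        if self.kind == "cnn":
            x = np.stack([s.image for s in samples])
            return self._model.predict_proba(x)
        x = np.stack([flatten(s) for s in samples])
        if self._scaler is not None:
            x = self._scaler.transform(x)
        if self.kind in ("svm_gaussian", "svm_polynomial"):
            # logistic squash of the margin: monotone, so ranking metrics see
            # the raw SVM decision values (Platt scaling is unstable at n~50)
            return 1.0 / (1.0 + np.exp(-self._model.decision_function(x)))
        return self._model.predict_proba(x)[:, 1]


def assemble_dataset(
    dataset: RepresentationDataset,
    annotation: DiseaseAnnotation,
    seed: int,
) -> list[LabeledSample]:
    """Balanced samples: all target-class genes as positives, an equal-count
    seeded draw from genes annotated only with other classes as negatives."""
    target = annotation.target_class
    positives = [
        g for g in dataset.genes if target in annotation.tags_of(g)
    ]
    pool = [
        g
        for g in dataset.genes
        if annotation.tags_of(g) and target not in annotation.tags_of(g)
    ]
    if len(pool) < len(positives):
        raise ValueError(
            f"only {len(pool)} eligible negatives for {len(positives)} positives"
        )
    rng = np.random.default_rng(seed)
    negatives = [pool[i] for i in sorted(rng.choice(len(pool), size=len(positives), replace=False))]
    by_gene = {g: i for i, g in enumerate(dataset.genes)}
    samples = [
        LabeledSample(gene=g, image=dataset.images[by_gene[g]], label=1)
        for g in positives
    ]
    samples += [
        LabeledSample(gene=g, image=dataset.images[by_gene[g]], label=0)
        for g in negatives
    ]
    return samples


def flatten(sample: LabeledSample) -> np.ndarray:
    """Row-major flattening of the sample's image (21x21 -> 441)."""
    return np.asarray(sample.image, dtype=float).reshape(-1)


def permute_augment(
    samples: Sequence[LabeledSample], n_aug: int, seed: int
) -> list[LabeledSample]:
    """Augment training samples by permuting neighbor rows/columns.

    The neighbor order inside an image is an artifact of the leaf sequence;
    applying one symmetric permutation to rows and columns 1..m-1 (the center
    stays at 0) preserves every edge weight and class value, so the label is
    invariant. Returns the originals plus ``n_aug`` permuted copies each.
    """
    if n_aug <= 0:
        return list(samples)
    rng = np.random.default_rng(seed)
    m = samples[0].image.shape[0]
    out = list(samples)
    for _ in range(n_aug):
        perm = np.concatenate(([0], 1 + rng.permutation(m - 1)))
        out += [
            LabeledSample(
                gene=s.gene,
                image=s.image[perm][:, perm],
                label=s.label,
            )
            for s in samples
        ]
    return out


def _median_heuristic_gamma(x: np.ndarray) -> float:
    """RBF inverse bandwidth 1/(2 sigma^2) with sigma the median pairwise distance."""
    if len(x) > 500:
        x = x[:500]
    d = pdist(x)
    med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
    return float(1.0 / (2.0 * med**2))


def _make_classical(kind: str, seed: int, x_train: np.ndarray):
    if kind == "svm_gaussian":
        return SVC(
            C=1.0,
            kernel="rbf",
            gamma=_median_heuristic_gamma(x_train),
            random_state=seed,
        )
    if kind == "svm_polynomial":
        return SVC(C=1.0, kernel="poly", degree=3, random_state=seed)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "extra_trees":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed)
    if kind == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown classifier kind {kind!r}")


def fit_score(
    kind: str,
    train_samples: Sequence[LabeledSample],
    test_samples: Sequence[LabeledSample],
    seed: int,
    cnn_kwargs: dict | None = None,
) -> tuple[TrainedClassifier, np.ndarray]:
    """Fit one classifier on the training samples and score the test samples."""
    y_train = np.array([s.label for s in train_samples])
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split must contain both classes")
    if kind == "cnn":
        x_train = np.stack([s.image for s in train_samples])
        model = SimpleCNN(seed=seed, **(cnn_kwargs or {}))
        model.fit(x_train, y_train)
        clf = TrainedClassifier(kind=kind, seed=seed, _model=model)
    elif kind in CLASSICAL_KINDS:
        x_train = np.stack([flatten(s) for s in train_samples])
        scaler = StandardScaler().fit(x_train)
        x_std = scaler.transform(x_train)
        model = _make_classical(kind, seed, x_std).fit(x_std, y_train)
        clf = TrainedClassifier(kind=kind, seed=seed, _model=model, _scaler=scaler)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return clf, clf.scores(test_samples)


def train(
    kind: str,
    samples: Sequence[LabeledSample],
    split: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    cnn_kwargs: dict | None = None,
) -> tuple[TrainedClassifier, pd.DataFrame]:
    """Stratified train/test split, fit, and held-out scoring.

    Returns the fitted classifier and a frame with columns
    ``gene``, ``label``, ``score`` for the held-out split.
    """
    if not np.isclose(sum(split), 1.0):
        raise ValueError("split fractions must sum to 1")
    labels = np.array([s.label for s in samples])
    idx_train, idx_test = train_test_split(
        np.arange(len(samples)),
        test_size=split[1],
        stratify=labels,
        random_state=seed,
    )
    train_s = [samples[i] for i in idx_train]
    test_s = [samples[i] for i in idx_test]
    if len({s.label for s in test_s}) < 2:
        raise ValueError("test split must contain both classes")
    clf, scores = fit_score(kind, train_s, test_s, seed, cnn_kwargs=cnn_kwargs)
    frame = pd.DataFrame(
        {
            "gene": [s.gene for s in test_s],
            "label": [s.label for s in test_s],
            "score": scores,
        }
    )
    return clf, frame


def cross_validate(
    kind: str,
    samples: Sequence[LabeledSample],
    n_folds: int = 5,
    seed: int = 0,
    cnn_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Out-of-fold scores from stratified K-fold cross-validation."""
    labels = np.array([s.label for s in samples])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (idx_train, idx_test) in enumerate(skf.split(labels, labels)):
        train_s = [samples[i] for i in idx_train]
        test_s = [samples[i] for i in idx_test]
        _, scores = fit_score(kind, train_s, test_s, seed, cnn_kwargs=cnn_kwargs)
        for s, score in zip(test_s, scores):
            rows.append({"fold": fold, "gene": s.gene, "label": s.label, "score": score})
    return pd.DataFrame(rows)
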