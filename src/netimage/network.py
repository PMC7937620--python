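"""Core domain types: gene networks and disease-class annotations."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["GeneNetwork", "DiseaseAnnotation"]


@dataclass
class GeneNetwork:
    """An undirected, weighted network over a named gene set.

    Parameters
    ----------
    name
        Label for this network view (e.g. ``"ppi"``).
    genes
        Ordered gene identifiers; row/column ``i`` of ``weights`` belongs to
        ``genes[i]``.
    weights
        Symmetric ``(n, n)`` non-negative matrix; ``0`` means "no edge".
    is_binary
        Whether the network carries only presence/absence information.
    """

    name: str
    genes: list[str]
    weights: np.ndarray
    is_binary: bool = False
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ValueError("duplicate gene identifiers in gene list")
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {self.weights.shape} does not match "
                f"{n} genes"
            )
        if n and not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if n and np.any(np.diagonal(self.weights) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if self.is_binary and not np.isin(self.weights, (0.0, 1.0)).all():
            raise ValueError("binary network contains weights outside {0, 1}")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in network {self.name!r}") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def degree(self) -> np.ndarray:
        """Number of incident edges per gene."""
        return (self.weights > 0).sum(axis=1)


@dataclass
class DiseaseAnnotation:
    """Per-gene disease-class tags (multi-tag) plus the identified target class.

    Class codes are integers in ``1..n_classes``; ``0`` is reserved for
    "unannotated". Genes absent from ``tags`` are unannotated.
    """

    tags: dict[str, frozenset[int]]
    n_classes: int
    target_class: int
    class_names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 1 <= self.target_class <= self.n_classes:
            raise ValueError(
                f"target_class {self.target_class} outside 1..{self.n_classes}"
            )
        clean: dict[str, frozenset[int]] = {}
        for gene, codes in self.tags.items():
            codes = frozenset(int(c) for c in codes)
            for c in codes:
                if not 1 <= c <= self.n_classes:
                    raise ValueError(
                        f"gene {gene!r} carries class code {c} outside "
                        f"1..{self.n_classes}"
                    )
            if codes:
                clean[gene] = codes
        self.tags = clean

    def tags_of(self, gene: str) -> frozenset[int]:
        return self.tags.get(gene, frozenset())

    def genes_with(self, code: int) -> list[str]:
        return [g for g, t in self.tags.items() if code in t]

    def annotated_genes(self) -> list[str]:
        return list(self.tags)

    def masked(self, genes: Iterable[str]) -> "DiseaseAnnotation":
        """Copy of this annotation with the given genes made unannotated."""
        hide = set(genes)
        return DiseaseAnnotation(
            tags={g: t for g, t in self.tags.items() if g not in hide},
            n_classes=self.n_classes,
            target_class=self.target_class,
            class_names=self.class_names,
        )
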