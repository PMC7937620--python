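"""Plain-text readers/writers for networks and annotations, plus
multi-view gene-universe harmonization.

Edge lists are whitespace/tab separated: ``gene_a  gene_b  [weight]``,
undirected, ``#`` starts a comment. A ``# genes: a,b,c`` comment (written by
:func:`write_edge_list`) pre-registers the gene universe so isolated genes
survive a round trip.

Annotations are ``gene<TAB>code[,code...]`` with integer class codes in
``1..K``; genes absent from the file are unannotated.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np

from .network import DiseaseAnnotation, GeneNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_annotations",
    "write_annotations",
    "harmonize",
]

_GENES_HEADER = "# genes:"


def read_edge_list(
    path: str | os.PathLike,
    default_weight: float = 1.0,
    name: str | None = None,
) -> GeneNetwork:
    """Read an undirected edge list into a :class:`GeneNetwork`.

    Duplicate edges keep the maximum weight; self-loops are dropped. A file
    with only two columns on every line yields a binary network with edge
    weight ``default_weight``.
    """
    genes: list[str] = []
    index: dict[str, int] = {}

    def gene_id(g: str) -> int:
        if g not in index:
            index[g] = len(genes)
            genes.append(g)
        return index[g]

    edges: list[tuple[int, int, float]] = []
    saw_weight_column = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith(_GENES_HEADER):
                for g in line[len(_GENES_HEADER):].strip().split(","):
                    if g:
                        gene_id(g)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, "
                    f"got {len(parts)}"
                )
            a, b = gene_id(parts[0]), gene_id(parts[1])
            if len(parts) == 3:
                saw_weight_column = True
                try:
                    w = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: bad weight {parts[2]!r}"
                    ) from None
            else:
                w = float(default_weight)
            if w < 0:
                raise ValueError(f"{path}: line {lineno}: negative weight {w}")
            if a == b:  # self-loop: register the gene, drop the edge
                continue
            edges.append((a, b, w))

    n = len(genes)
    weights = np.zeros((n, n))
    for a, b, w in edges:
        if w > weights[a, b]:
            weights[a, b] = weights[b, a] = w

    is_binary = not saw_weight_column and bool(
        np.isin(weights, (0.0, 1.0)).all()
    )
    return GeneNetwork(
        name=name or os.path.splitext(os.path.basename(os.fspath(path)))[0],
        genes=genes,
        weights=weights,
        is_binary=is_binary,
    )


def write_edge_list(network: GeneNetwork, path: str | os.PathLike) -> None:
    """Write a network as a TSV edge list (upper triangle only)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_GENES_HEADER + " " + ",".join(network.genes) + "\n")
        rows, cols = np.nonzero(np.triu(network.weights))
        for i, j in zip(rows.tolist(), cols.tolist()):
            w = network.weights[i, j]
            fh.write(f"{network.genes[i]}\t{network.genes[j]}\t{w:.12g}\n")


def read_annotations(
    path: str | os.PathLike,
    n_classes: int,
    target_class: int,
) -> DiseaseAnnotation:
    """Read ``gene<TAB>code[,code...]`` disease-class annotations."""
    tags: dict[str, set[int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'gene<TAB>codes'"
                )
            gene, codes_str = parts
            for tok in codes_str.split(","):
                try:
                    code = int(tok)
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: bad class code {tok!r}"
                    ) from None
                if code == 0:
                    raise ValueError(
                        f"{path}: line {lineno}: class code 0 is reserved "
                        "for 'no tag'"
                    )
                if not 1 <= code <= n_classes:
                    raise ValueError(
                        f"{path}: line {lineno}: class code {code} outside "
                        f"1..{n_classes}"
                    )
                tags.setdefault(gene, set()).add(code)
    return DiseaseAnnotation(
        tags={g: frozenset(t) for g, t in tags.items()},
        n_classes=n_classes,
        target_class=target_class,
    )


def write_annotations(
    annotation: DiseaseAnnotation, path: str | os.PathLike
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for gene in sorted(annotation.tags):
            codes = ",".join(str(c) for c in sorted(annotation.tags[gene]))
            fh.write(f"{gene}\t{codes}\n")


def harmonize(
    networks: Sequence[GeneNetwork], min_presence: int
) -> list[GeneNetwork]:
    """Restrict multiple network views to one shared, ordered gene universe.

    Keeps genes present in at least ``min_presence`` of the input views.
    Every output network uses the same (sorted) gene ordering; genes missing
    from a view become isolated (all-zero) rows/columns so that indices align
    across views.
    """
    if not networks:
        raise ValueError("need at least one network")
    if not 1 <= min_presence <= len(networks):
        raise ValueError(
            f"min_presence {min_presence} outside 1..{len(networks)}"
        )
    counts: dict[str, int] = {}
    for net in networks:
        for g in net.genes:
            counts[g] = counts.get(g, 0) + 1
    kept = sorted(g for g, c in counts.items() if c >= min_presence)
    if not kept:
        raise ValueError(
            f"no gene is present in >= {min_presence} of the "
            f"{len(networks)} views"
        )
    out: list[GeneNetwork] = []
    for net in networks:
        weights = np.zeros((len(kept), len(kept)))
        present = [(p, net.index_of(g)) for p, g in enumerate(kept) if g in net]
        if present:
            pos, src = map(np.array, zip(*present))
            weights[np.ix_(pos, pos)] = net.weights[np.ix_(src, src)]
        out.append(
            GeneNetwork(
                name=net.name,
                genes=list(kept),
                weights=weights,
                is_binary=net.is_binary,
            )
        )
    return out
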