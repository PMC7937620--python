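"""Vertex-to-image network representation.

Each vertex of a network is turned into a small ``m x m`` "image": the
adjacency block of a node-induced sub-network over the vertex and ``m - 1``
selected neighbors, plus a diagonal matrix carrying the neighbors'
disease-class values (the "environment"). Neighbors are drawn from a window
around the vertex in the leaf order of an agglomerative clustering of
row-vector similarities, so that hubs and leaves of a scale-free network
both receive information of comparable scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .network import DiseaseAnnotation, GeneNetwork

__all__ = [
    "SimilarityMatrix",
    "LeafOrder",
    "NeighborhoodField",
    "RepresentationImage",
    "RepresentationDataset",
    "compute_similarity",
    "leaf_order",
    "select_neighborhood",
    "build_sub_adjacency",
    "ClassCentroids",
    "class_centroid_distance",
    "assign_center_tag",
    "neighbor_class_value",
    "build_classification_matrix",
    "represent_vertex",
    "represent_all",
    "represent_baseline",
    "represent_all_baseline",
    "fuse_networks",
    "default_radius",
]

DEFAULT_CAP = 1e12

DistanceFn = Callable[[int, int], float]


@dataclass
class SimilarityMatrix:
    """Pairwise row-vector similarity: reciprocal sum of squared differences.

    ``cap`` replaces the (infinite) similarity of identical rows.
    """

    values: np.ndarray
    cap: float = DEFAULT_CAP


@dataclass
class LeafOrder:
    """Leaf sequence of the clustering dendrogram.

    ``order[p]`` is the vertex index at leaf position ``p``; ``position`` is
    the inverse permutation.
    """

    order: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.position = np.asarray(self.position, dtype=int)
        if not np.array_equal(self.position[self.order], np.arange(len(self.order))):
            raise ValueError("order and position are not inverse permutations")


@dataclass
class NeighborhoodField:
    """The center vertex plus its selected neighbors (in leaf-sequence order)."""

    center: int
    radius: int
    members: list[int]
    m: int

    def __post_init__(self) -> None:
        if len(self.members) != self.m - 1:
            raise ValueError("field must contain exactly m - 1 members")
        if self.center in self.members:
            raise ValueError("center cannot be one of its own neighbors")


@dataclass
class RepresentationImage:
    """``E = A + C`` for one center gene."""

    E: np.ndarray
    A: np.ndarray
    C: np.ndarray
    center: str
    t_center: int


@dataclass
class RepresentationDataset:
    """A stack of representation images with bookkeeping parameters."""

    images: np.ndarray  # (N, m, m)
    genes: list[str]
    t_centers: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.images.shape[1]

    def save(self, path: str | os.PathLike) -> None:
        """Write ``<path>.npz`` (arrays) and ``<path>.json`` (parameters)."""
        base = os.fspath(path)
        np.savez(
            base + ".npz",
            images=self.images,
            genes=np.array(self.genes),
            t_centers=self.t_centers,
        )
        with open(base + ".json", "wt", encoding="utf-8") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "RepresentationDataset":
        base = os.fspath(path)
        with np.load(base + ".npz") as data:
            images = data["images"]
            genes = [str(g) for g in data["genes"]]
            t_centers = data["t_centers"]
        params = {}
        if os.path.exists(base + ".json"):
            with open(base + ".json", "rt", encoding="utf-8") as fh:
                params = json.load(fh)
        return cls(images=images, genes=genes, t_centers=t_centers, params=params)


def default_radius(n: int, m: int) -> int:
    """Default receptive-field radius: ``min(n - 1, 3 m)`` (must satisfy m < k < n)."""
    k = min(n - 1, 3 * m)
    if not m < k < n:
        raise ValueError(f"cannot pick a radius with m={m} < k < n={n}")
    return k


def compute_similarity(
    network: GeneNetwork,
    cap: float = DEFAULT_CAP,
    use_sqrt: bool = False,
) -> SimilarityMatrix:
    """Similarity between vertices from their weight-matrix row vectors.

    ``S[i, j] = 1 / sum_k (a[i, k] - a[j, k])**2``; identical rows get ``cap``.
    With ``use_sqrt`` the root of the sum (Euclidean distance) is used instead
    of the sum itself.
    """
    if network.n < 2:
        raise ValueError("similarity needs at least two vertices")
    if cap <= 0:
        raise ValueError("cap must be positive")
    d2 = cdist(network.weights, network.weights, metric="sqeuclidean")
    if use_sqrt:
        d2 = np.sqrt(d2)
    with np.errstate(divide="ignore"):
        values = np.where(d2 > 0, 1.0 / np.where(d2 > 0, d2, 1.0), cap)
    return SimilarityMatrix(values=values, cap=cap)


def leaf_order(similarity: SimilarityMatrix) -> LeafOrder:
    """Leaf sequence of an average-linkage agglomerative clustering.

    The clustering distance is the reciprocal of the similarity (i.e. the
    squared-difference sum between row vectors). Merge ties break toward the
    smallest cluster indices. At each merge the child whose members have the
    smaller mean distance to all vertices is placed on the left, a purely
    geometric rule, so that relabeling a tie-free instance permutes the leaf
    sequence consistently.
    """
    S = np.asarray(similarity.values, dtype=float)
    n = S.shape[0]
    if n == 1:
        return LeafOrder(np.array([0]), np.array([0]))
    with np.errstate(divide="ignore"):
        D = 1.0 / S
    np.fill_diagonal(D, 0.0)

    # mean distance from each point to every other point; drives orientation
    pscore = D.sum(axis=1) / max(n - 1, 1)

    dist = D.copy()
    np.fill_diagonal(dist, np.inf)
    active = np.ones(n, dtype=bool)
    size = np.ones(n)
    members: list[list[int] | None] = [[i] for i in range(n)]

    for _ in range(n - 1):
        masked = np.where(active[:, None] & active[None, :], dist, np.inf)
        # argmin is row-major, so ties resolve to the smallest (i, j) pair
        i, j = divmod(int(np.argmin(masked)), n)
        if i > j:
            i, j = j, i
        mi, mj = members[i], members[j]
        assert mi is not None and mj is not None
        key_i = (pscore[mi].mean(), min(mi))
        key_j = (pscore[mj].mean(), min(mj))
        left, right = (mi, mj) if key_i <= key_j else (mj, mi)
        # average-linkage (Lance-Williams) update into slot i
        new_row = (size[i] * dist[i] + size[j] * dist[j]) / (size[i] + size[j])
        dist[i, :] = new_row
        dist[:, i] = new_row
        dist[i, i] = np.inf
        size[i] += size[j]
        members[i] = left + right
        members[j] = None
        active[j] = False

    order = np.array(members[int(np.flatnonzero(active)[0])], dtype=int)
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    return LeafOrder(order=order, position=position)


def _window_positions(pos: int, k: int, n: int) -> np.ndarray:
    """Positions of the 2k+1 window around ``pos``, truncation extended on
    the opposite side so the candidate pool keeps ``min(2k, n - 1)`` vertices."""
    lo, hi = pos - k, pos + k
    if lo < 0:
        hi += -lo
        lo = 0
    if hi > n - 1:
        lo -= hi - (n - 1)
        hi = n - 1
    lo = max(lo, 0)
    window = np.arange(lo, hi + 1)
    return window[window != pos]


def select_neighborhood(
    center: int,
    order: LeafOrder,
    similarity: SimilarityMatrix,
    k: int,
    m: int,
) -> NeighborhoodField:
    """Pick the ``m - 1`` window vertices most similar to the center.

    Candidates come from the ``2k + 1`` leaf-order window around the center.
    Ties break toward the smaller leaf position; members are reported in
    leaf-sequence order.
    """
    n = len(order.order)
    if not (2 <= m < k < n):
        raise ValueError(f"need 2 <= m < k < n, got m={m}, k={k}, n={n}")
    pos = int(order.position[center])
    candidates = _window_positions(pos, k, n)
    if len(candidates) < m - 1:
        raise ValueError(
            f"candidate pool of {len(candidates)} vertices cannot supply "
            f"{m - 1} neighbors"
        )
    sims = similarity.values[center, order.order[candidates]]
    ranking = np.lexsort((candidates, -sims))  # similarity desc, position asc
    chosen = np.sort(candidates[ranking[: m - 1]])
    members = [int(order.order[p]) for p in chosen]
    return NeighborhoodField(center=center, radius=k, members=members, m=m)


def build_sub_adjacency(
    network: GeneNetwork, field: NeighborhoodField
) -> np.ndarray:
    """Adjacency of the node-induced sub-network; row/column 0 is the center."""
    idx = np.array([field.center] + field.members)
    A = network.weights[np.ix_(idx, idx)].copy()
    np.fill_diagonal(A, 0.0)
    return A


class ClassCentroids:
    """Centroid-linkage distances between disease classes.

    The centroid of a class is the mean weight-matrix row vector of its
    member genes present in the network.
    """

    def __init__(self, network: GeneNetwork, annotation: DiseaseAnnotation):
        self._centroids: dict[int, np.ndarray] = {}
        for code in range(1, annotation.n_classes + 1):
            rows = [
                network.index_of(g)
                for g in annotation.genes_with(code)
                if g in network
            ]
            if rows:
                self._centroids[code] = network.weights[rows].mean(axis=0)

    def __call__(self, t_a: int, t_b: int) -> float:
        if t_a == t_b:
            return 0.0
        for t in (t_a, t_b):
            if t not in self._centroids:
                raise ValueError(f"class {t} has no member genes in the network")
        return float(np.linalg.norm(self._centroids[t_a] - self._centroids[t_b]))


def class_centroid_distance(
    t_a: int,
    t_b: int,
    network: GeneNetwork,
    annotation: DiseaseAnnotation,
) -> float:
    """Euclidean distance between the two classes' member-gene centroids."""
    for t in (t_a, t_b):
        if not 1 <= t <= annotation.n_classes:
            raise ValueError(f"class code {t} outside 1..{annotation.n_classes}")
    return ClassCentroids(network, annotation)(t_a, t_b)


def assign_center_tag(
    center: str,
    annotation: DiseaseAnnotation,
    dist: DistanceFn,
) -> int:
    """Resolve the center's multi-tag set to a single tag.

    The target class wins if present; otherwise the center's tag closest to
    the target (ties to the smallest code); unannotated centers get ``0``.
    """
    tags = annotation.tags_of(center)
    t_id = annotation.target_class
    if not tags:
        return 0
    if t_id in tags:
        return t_id
    return min(sorted(tags), key=lambda t: (dist(t, t_id), t))


def neighbor_class_value(
    neighbor: str,
    t_center: int,
    annotation: DiseaseAnnotation,
    dist: DistanceFn,
) -> float:
    """Diagonal class value for a neighbor: its most relevant tag over 4.

    If the center's resolved tag is in the neighbor's tag set, the value is
    ``t_center / 4``; otherwise the neighbor tag closest to the reference
    class is used (``t / 4``). For an unannotated center (``t_center == 0``)
    the reference class falls back to the target class. Unannotated
    neighbors contribute ``0``.
    """
    tags = annotation.tags_of(neighbor)
    if not tags:
        return 0.0
    if t_center != 0 and t_center in tags:
        return t_center / 4.0
    ref = t_center if t_center != 0 else annotation.target_class
    t = min(sorted(tags), key=lambda t: (dist(t, ref), t))
    return t / 4.0


def build_classification_matrix(
    field: NeighborhoodField, c_values: Sequence[float]
) -> np.ndarray:
    """Diagonal environment matrix; entry (0, 0) — the center — stays 0."""
    if len(c_values) != field.m - 1:
        raise ValueError(
            f"need {field.m - 1} class values, got {len(c_values)}"
        )
    C = np.zeros((field.m, field.m))
    C[np.arange(1, field.m), np.arange(1, field.m)] = np.asarray(
        c_values, dtype=float
    )
    return C


def _resolve_center(network: GeneNetwork, center: int | str) -> int:
    return network.index_of(center) if isinstance(center, str) else int(center)


def represent_vertex(
    network: GeneNetwork,
    annotation: DiseaseAnnotation,
    order: LeafOrder,
    similarity: SimilarityMatrix,
    center: int | str,
    k: int,
    m: int,
    dist: DistanceFn | None = None,
    mask_center: bool = False,
) -> RepresentationImage:
    """Build the ``m x m`` image ``E = A + C`` for one center vertex.

    With ``mask_center`` the center's own tags are hidden (its resolved tag
    becomes 0), which prevents label leakage when representing evaluation
    genes; neighbor tags remain visible.
    """
    ci = _resolve_center(network, center)
    gene = network.genes[ci]
    if dist is None:
        dist = ClassCentroids(network, annotation)
    field = select_neighborhood(ci, order, similarity, k, m)
    A = build_sub_adjacency(network, field)
    t_center = 0 if mask_center else assign_center_tag(gene, annotation, dist)
    c_values = [
        neighbor_class_value(network.genes[v], t_center, annotation, dist)
        for v in field.members
    ]
    C = build_classification_matrix(field, c_values)
    return RepresentationImage(E=A + C, A=A, C=C, center=gene, t_center=t_center)


def represent_all(
    network: GeneNetwork,
    annotation: DiseaseAnnotation,
    k: int | None = None,
    m: int = 21,
    genes: Sequence[str] | None = None,
    cap: float = DEFAULT_CAP,
    mask_centers: Iterable[str] = (),
    use_sqrt: bool = False,
) -> RepresentationDataset:
    """Represent every requested gene (default: all) of one network."""
    if k is None:
        k = default_radius(network.n, m)
    if not m < k < network.n:
        raise ValueError(f"need m < k < n, got m={m}, k={k}, n={network.n}")
    similarity = compute_similarity(network, cap=cap, use_sqrt=use_sqrt)
    order = leaf_order(similarity)
    dist = ClassCentroids(network, annotation)
    mask = set(mask_centers)
    targets = list(genes) if genes is not None else list(network.genes)
    images = np.empty((len(targets), m, m))
    t_centers = np.empty(len(targets), dtype=int)
    for i, gene in enumerate(targets):
        img = represent_vertex(
            network, annotation, order, similarity, gene, k, m,
            dist=dist, mask_center=gene in mask,
        )
        images[i] = img.E
        t_centers[i] = img.t_center
    return RepresentationDataset(
        images=images,
        genes=targets,
        t_centers=t_centers,
        params={
            "network": network.name, "m": m, "k": k, "cap": cap,
            "use_sqrt": use_sqrt, "representation": "environment",
        },
    )


def represent_baseline(
    network: GeneNetwork,
    order: LeafOrder,
    center: int | str,
    m: int,
) -> RepresentationImage:
    """No-environment baseline: neighbors are the ``m - 1`` consecutive
    leaf-order successors (wrapping at the end); ``E`` is the bare
    sub-adjacency."""
    ci = _resolve_center(network, center)
    n = network.n
    if m > n:
        raise ValueError(f"m={m} exceeds network size {n}")
    pos = int(order.position[ci])
    positions = [(pos + offset) % n for offset in range(1, m)]
    members = [int(order.order[p]) for p in positions]
    field = NeighborhoodField(center=ci, radius=m, members=members, m=m)
    A = build_sub_adjacency(network, field)
    return RepresentationImage(
        E=A.copy(), A=A, C=np.zeros((m, m)),
        center=network.genes[ci], t_center=0,
    )


def represent_all_baseline(
    network: GeneNetwork,
    m: int = 21,
    genes: Sequence[str] | None = None,
    cap: float = DEFAULT_CAP,
    use_sqrt: bool = False,
) -> RepresentationDataset:
    """Baseline dataset over the requested genes (leaf-order successors)."""
    similarity = compute_similarity(network, cap=cap, use_sqrt=use_sqrt)
    order = leaf_order(similarity)
    targets = list(genes) if genes is not None else list(network.genes)
    images = np.empty((len(targets), m, m))
    for i, gene in enumerate(targets):
        images[i] = represent_baseline(network, order, gene, m).E
    return RepresentationDataset(
        images=images,
        genes=targets,
        t_centers=np.zeros(len(targets), dtype=int),
        params={
            "network": network.name, "m": m, "cap": cap,
            "use_sqrt": use_sqrt, "representation": "baseline",
        },
    )


def _scaled_weights(view: GeneNetwork) -> np.ndarray:
    if view.is_binary:
        return view.weights
    lo, hi = view.weights.min(), view.weights.max()
    if hi <= lo:
        return np.zeros_like(view.weights)
    return (view.weights - lo) / (hi - lo)


def fuse_networks(
    views: Sequence[GeneNetwork],
    reference: GeneNetwork,
    annotation: DiseaseAnnotation,
    k: int | None = None,
    m: int = 21,
    genes: Sequence[str] | None = None,
    cap: float = DEFAULT_CAP,
    mask_centers: Iterable[str] = (),
) -> RepresentationDataset:
    """Average per-view images over multiple harmonized network views.

    The neighborhood field and the environment diagonal are computed once, on
    the reference view; each view then contributes the field's sub-adjacency
    from its own weights (binary views as 0/1, weighted views min-max scaled
    to [0, 1]) and the images are averaged elementwise.
    """
    if not any(v is reference or v.name == reference.name for v in views):
        raise ValueError("reference must be one of the views")
    for v in views:
        if v.genes != reference.genes:
            raise ValueError(
                f"view {v.name!r} gene ordering differs from the reference; "
                "run harmonize first"
            )
    if k is None:
        k = default_radius(reference.n, m)
    similarity = compute_similarity(reference, cap=cap)
    order = leaf_order(similarity)
    dist = ClassCentroids(reference, annotation)
    mask = set(mask_centers)
    targets = list(genes) if genes is not None else list(reference.genes)
    scaled = [
        GeneNetwork(
            name=v.name, genes=v.genes, weights=_scaled_weights(v),
            is_binary=v.is_binary,
        )
        for v in views
    ]
    images = np.empty((len(targets), m, m))
    t_centers = np.empty(len(targets), dtype=int)
    for i, gene in enumerate(targets):
        ci = reference.index_of(gene)
        field = select_neighborhood(ci, order, similarity, k, m)
        t_center = (
            0 if gene in mask else assign_center_tag(gene, annotation, dist)
        )
        c_values = [
            neighbor_class_value(reference.genes[v], t_center, annotation, dist)
            for v in field.members
        ]
        C = build_classification_matrix(field, c_values)
        stack = [build_sub_adjacency(sv, field) + C for sv in scaled]
        images[i] = np.mean(stack, axis=0)
        t_centers[i] = t_center
    return RepresentationDataset(
        images=images,
        genes=targets,
        t_centers=t_centers,
        params={
            "network": reference.name, "views": [v.name for v in views],
            "m": m, "k": k, "cap": cap, "representation": "fused",
        },
    )
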