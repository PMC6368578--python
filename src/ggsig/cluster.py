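"""Complete-linkage cladograms, PCA, k-means/elbow and the type partition check."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from ggsig.distance import DeltaMatrix

__all__ = [
    "Cladogram",
    "ElbowResult",
    "PCAResult",
    "PartitionReport",
    "WSSCurve",
    "complete_linkage",
    "elbow_suggest",
    "kmeans_fit",
    "kmeans_wss",
    "pca_project",
    "to_newick",
    "type_partition_check",
]


@dataclass(frozen=True)
class Cladogram:
    """Agglomeration result: merges of cluster ids with their heights.

    Leaves carry ids ``0..len(leaves)-1``; the i-th merge creates cluster
    ``len(leaves)+i``.  Complete linkage guarantees non-decreasing heights.
    """

    merges: tuple[tuple[int, int, float], ...]
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a binary tree needs exactly |leaves|-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


def complete_linkage(m: DeltaMatrix) -> Cladogram:
    """Farthest-neighbour agglomeration of a delta matrix.

    Ties on the minimal inter-cluster distance break deterministically by
    the lexicographically smallest pair of cluster representative labels
    (representative = minimal leaf label in the cluster).
    """
    k = len(m.labels)
    if k < 2:
        raise ValueError("need at least 2 leaves")
    # active clusters: id -> representative label; distances in a dict of dicts
    rep = {i: m.labels[i] for i in range(k)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            dist[(i, j)] = float(m.values[i, j])
    active = set(range(k))
    merges: list[tuple[int, int, float]] = []
    next_id = k
    while len(active) > 1:
        best: tuple[float, str, str, int, int] | None = None
        for (i, j), d in dist.items():
            lo, hi = sorted((rep[i], rep[j]))
            key = (d, lo, hi, i, j)
            if best is None or key < best:
                best = key
        d, _, _, i, j = best  # type: ignore[misc]
        merges.append((i, j, d))
        new = next_id
        next_id += 1
        active.discard(i)
        active.discard(j)
        new_dist = {}
        for other in active:
            dij = max(
                dist[tuple(sorted((i, other)))], dist[tuple(sorted((j, other)))]
            )
            new_dist[(other, new)] = dij
        dist = {
            p: d2 for p, d2 in dist.items() if i not in p and j not in p
        }
        dist.update(new_dist)
        rep[new] = min(rep[i], rep[j])
        active.add(new)
    return Cladogram(merges=tuple(merges), leaves=m.labels)


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]',;:]")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Cladogram) -> str:
    """Ultrametric Newick string; node depth = merge height / 2."""
    k = len(t.leaves)
    height = {i: 0.0 for i in range(k)}
    node = {i: _newick_label(t.leaves[i]) for i in range(k)}
    for idx, (a, b, h) in enumerate(t.merges):
        nid = k + idx
        half = h / 2.0
        la = half - height[a]
        lb = half - height[b]
        node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        height[nid] = half
    root = k + len(t.merges) - 1
    return node[root] + ";"


@dataclass(frozen=True)
class PCAResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray
    explained_variance: np.ndarray


def pca_project(vectors: Sequence, components: int = 2) -> PCAResult:
    """Project mean-centred (unscaled) vectors onto principal components.

    Sign convention: each component is flipped so that its largest-magnitude
    loading is positive, making projections deterministic.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    n = vectors[0].n
    if any(v.n != n for v in vectors):
        raise ValueError("all vectors must share the same n")
    x = np.vstack([np.asarray(v.values, dtype=float) for v in vectors])
    # rank bound from the data dimensions; numerically degenerate directions
    # (e.g. identical vectors) are allowed and project to the origin
    max_components = min(x.shape[0] - 1, x.shape[1])
    if components > max_components:
        raise ValueError(
            f"components={components} exceeds data rank bound {max_components}"
        )
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for c in range(components):
        i = int(np.argmax(np.abs(vt[c])))
        if vt[c, i] < 0:
            vt[c] = -vt[c]
            u[:, c] = -u[:, c]
    coords = u[:, :components] * s[:components]
    explained = s[:components] ** 2 / (x.shape[0] - 1)
    return PCAResult(
        labels=tuple(v.label for v in vectors),
        coordinates=coords,
        explained_variance=explained,
    )


@dataclass(frozen=True)
class WSSCurve:
    """Within-groups sum of squares per k, with the run metadata."""

    ks: tuple[int, ...]
    wss: tuple[float, ...]
    restarts: int
    max_iter: int
    seed: int


def _kmeans_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0])


def kmeans_fit(
    vectors: Sequence,
    k: int,
    restarts: int = 20,
    max_iter: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Best-of-`restarts` k-means on raw signature vectors (Euclidean WSS).

    Returns ``(labels, wss)``; bit-reproducible for a fixed seed, and the
    first `restarts` initializations are a prefix of any larger run, so
    increasing restarts never increases the best WSS.
    """
    x = np.vstack([np.asarray(v.values, dtype=float) for v in vectors])
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of vectors {x.shape[0]}")
    if k == 1:
        centre = x.mean(axis=0)
        return np.zeros(x.shape[0], dtype=int), float(((x - centre) ** 2).sum())
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        random_state=_kmeans_seed(seed, k),
        algorithm="lloyd",
    ).fit(x)
    return km.labels_.astype(int), float(km.inertia_)


def kmeans_wss(
    vectors: Sequence,
    k_min: int = 1,
    k_max: int = 15,
    restarts: int = 20,
    max_iter: int = 50,
    seed: int = 0,
) -> WSSCurve:
    """WSS curve over ``k_min..k_max`` for the elbow analysis."""
    if k_max > len(vectors):
        raise ValueError(f"k_max={k_max} exceeds number of vectors {len(vectors)}")
    if k_min < 1 or k_min > k_max:
        raise ValueError("need 1 <= k_min <= k_max")
    ks = tuple(range(k_min, k_max + 1))
    wss = tuple(
        kmeans_fit(vectors, k, restarts=restarts, max_iter=max_iter, seed=seed)[1]
        for k in ks
    )
    return WSSCurve(ks=ks, wss=wss, restarts=restarts, max_iter=max_iter, seed=seed)


@dataclass(frozen=True)
class ElbowResult:
    k: int
    clear: bool  # False when the WSS decline has no distinguished bend


def elbow_suggest(c: WSSCurve) -> ElbowResult:
    """k maximizing the discrete second difference of the WSS curve.

    Advisory only — the curve itself remains the primary output.  A constant
    second difference (e.g. a linear decline) returns the smallest interior
    k flagged as "no clear elbow".
    """
    if len(c.ks) < 3:
        raise ValueError("elbow detection needs at least 3 k values")
    w = np.asarray(c.wss)
    d2 = w[:-2] - 2 * w[1:-1] + w[2:]
    spread = float(d2.max() - d2.min())
    scale = max(abs(float(w[0])), 1e-300)
    if spread <= 1e-9 * scale:
        return ElbowResult(k=c.ks[1], clear=False)
    return ElbowResult(k=c.ks[1 + int(np.argmax(d2))], clear=True)


@dataclass(frozen=True)
class PartitionReport:
    """Naive same-type vs different-type separation of pairwise deltas."""

    max_same_type: float
    min_different_type: float
    violations: tuple[tuple[str, str, float, str], ...]  # (a, b, delta, kind)
    n_same_pairs: int
    n_different_pairs: int

    @property
    def perfect(self) -> bool:
        return not self.violations


def type_partition_check(m: DeltaMatrix, types: Mapping[str, str]) -> PartitionReport:
    """Check that same-type deltas all fall below different-type deltas.

    Violations are same-type pairs with delta >= the minimum different-type
    delta, and different-type pairs with delta <= the maximum same-type
    delta.  Perfect separation <=> no violations.
    """
    for label in m.labels:
        if label not in types:
            raise KeyError(f"label {label!r} has no type assignment")
    if len(set(types[l] for l in m.labels)) < 2:
        raise ValueError(">= 2 types required")
    same: list[tuple[str, str, float]] = []
    diff: list[tuple[str, str, float]] = []
    for i, a in enumerate(m.labels):
        for j in range(i + 1, len(m.labels)):
            b = m.labels[j]
            d = float(m.values[i, j])
            (same if types[a] == types[b] else diff).append((a, b, d))
    max_same = max(d for _, _, d in same) if same else float("nan")
    min_diff = min(d for _, _, d in diff)
    violations = []
    for a, b, d in same:
        if d >= min_diff:
            violations.append((a, b, d, "same-type-too-far"))
    for a, b, d in diff:
        if same and d <= max_same:
            violations.append((a, b, d, "different-type-too-close"))
    return PartitionReport(
        max_same_type=max_same,
        min_different_type=min_diff,
        violations=tuple(violations),
        n_same_pairs=len(same),
        n_different_pairs=len(diff),
    )
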