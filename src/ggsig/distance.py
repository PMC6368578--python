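"""Delta distance between signature vectors and rank-of-similarity analysis.

delta(g, h) = (1/w_n) * sum |rho_i(g) - rho_i(h)| over the w_n canonical word
classes — a scaled Manhattan metric.  Percent rank of similarity locates a
pair's delta among all pairwise deltas, oriented so 100% = most similar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DeltaMatrix",
    "delta_distance",
    "distance_matrix",
    "percent_rank_similarity",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_matrix_long_tsv",
]


def delta_distance(a, b) -> float:
    """Mean absolute difference of two signature vectors of equal n."""
    if a.n != b.n:
        raise ValueError(f"word-length mismatch: {a.n} != {b.n}")
    va, vb = np.asarray(a.values), np.asarray(b.values)
    if va.shape != vb.shape:
        raise ValueError(f"vector length mismatch: {va.shape} != {vb.shape}")
    return float(np.mean(np.abs(va - vb)))


@dataclass(frozen=True)
class DeltaMatrix:
    """Labeled symmetric matrix of pairwise delta distances."""

    labels: tuple[str, ...]
    n: int
    values: np.ndarray

    def __post_init__(self) -> None:
        m = self.values
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("matrix diagonal must be zero")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def distance_matrix(vectors: Sequence) -> DeltaMatrix:
    """All pairwise delta distances; label order is the input order."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    labels = tuple(v.label for v in vectors)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    n = vectors[0].n
    k = len(vectors)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = delta_distance(vectors[i], vectors[j])
    return DeltaMatrix(labels=labels, n=n, values=values)


def percent_rank_similarity(
    m: DeltaMatrix, pairs: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Percent rank of each queried pair among all unordered pairs.

    rank = 100 * #{pairs with delta >= this pair's delta} / #pairs, so the
    single most-similar pair scores 100% and ties share the most-similar
    (highest) percent.
    """
    all_deltas = m.condensed()
    total = all_deltas.size
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        if a == b:
            raise ValueError(f"pair ({a!r}, {b!r}) is not an unordered pair")
        d = m.get(a, b)
        out[(a, b)] = 100.0 * int(np.sum(all_deltas >= d)) / total
    return out


def write_matrix_tsv(m: DeltaMatrix, path: str | Path) -> None:
    """Square TSV with a label header row and column."""
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "\t" + "\t".join(format(x, ".10g") for x in row) + "\n")


def write_matrix_long_tsv(m: DeltaMatrix, path: str | Path) -> None:
    """3-column long format: label1, label2, delta (upper triangle)."""
    with open(path, "w") as fh:
        fh.write("label1\tlabel2\tdelta\n")
        for i, a in enumerate(m.labels):
            for j in range(i + 1, len(m.labels)):
                fh.write(f"{a}\t{m.labels[j]}\t{format(m.values[i, j], '.10g')}\n")


def read_matrix_tsv(path: str | Path, n: int = 0) -> DeltaMatrix:
    """Read a square TSV written by :func:`write_matrix_tsv`.

    The word length is not stored in the file; pass `n` if downstream code
    needs it (0 means unknown).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "label":
            raise ValueError(f"{path}: not a delta-matrix TSV")
        labels = tuple(header[1:])
        rows = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if fields[0] != labels[len(rows)]:
                raise ValueError(f"{path}: row/column label mismatch at {fields[0]!r}")
            rows.append([float(x) for x in fields[1:]])
    return DeltaMatrix(labels=labels, n=n, values=np.array(rows))
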