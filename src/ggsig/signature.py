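"""n-word counting, expected frequencies, odds ratios and signature vectors.

For a word s = N1..Nn the expected frequency is

    E(s) = f(N1..Nn-1) * f(N2..Nn) / f(N2..Nn-1)

with observed frequencies f taken from the strand-symmetrized sequence; for
n = 2 the middle term is the empty word with f == 1, so E reduces to the
classical dinucleotide form f(N1) * f(N2).  The odds ratio is
rho(s) = f(s) / E(s); the signature vector holds one rho per canonical
reverse-complement word class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ggsig.seqio import SymmetrizedSequence, reverse_complement

__all__ = [
    "BASES",
    "CanonicalWordSet",
    "GGSVector",
    "KmerFrequencyVector",
    "UndefinedExpectation",
    "WordCounts",
    "canonical_words",
    "count_words",
    "expected_frequency",
    "ggs_vector",
    "kmer_vector",
    "odds_ratio",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i


class UndefinedExpectation(ArithmeticError):
    """Raised when the middle-word count is zero and E(s) is undefined."""


def word_index(word: str) -> int:
    """Map an n-word to its index in base-4 lexicographic order."""
    idx = 0
    for ch in word:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def index_word(idx: int, n: int) -> str:
    out = []
    for _ in range(n):
        out.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class WordCounts:
    """Occurrence counts of all ``4**n`` words of length `n`.

    ``counts`` is indexed by :func:`word_index`; ``windows`` is the total
    number of counted length-`n` windows, so ``counts.sum() == windows``.
    """

    n: int
    counts: np.ndarray
    windows: int

    def count(self, word: str) -> int:
        if len(word) != self.n:
            raise ValueError(f"word length {len(word)} != n={self.n}")
        return int(self.counts[word_index(word)])

    def frequency(self, word: str) -> float:
        return self.count(word) / self.windows


def _encode_run(run: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(run.encode("ascii"), dtype=np.uint8)]


def _run_codes(arr: np.ndarray, n: int) -> np.ndarray:
    """Base-4 codes of all length-n windows of an encoded run."""
    m = arr.shape[0] - n + 1
    codes = np.zeros(m, dtype=np.int64)
    for j in range(n):
        codes = codes * 4 + arr[j : j + m]
    return codes


def count_words(sym: SymmetrizedSequence, n: int) -> WordCounts:
    """Count every length-`n` window inside each forward and reverse run."""
    if n < 1:
        raise ValueError("n must be >= 1")
    size = 4**n
    counts = np.zeros(size, dtype=np.int64)
    windows = 0
    for run in sym.runs:
        if len(run) < n:
            continue
        codes = _run_codes(_encode_run(run), n)
        counts += np.bincount(codes, minlength=size)
        windows += codes.shape[0]
    if windows == 0:
        raise ValueError(f"sequence too short for n={n}")
    return WordCounts(n=n, counts=counts, windows=windows)


@dataclass(frozen=True)
class CanonicalWordSet:
    """Representatives of the reverse-complement equivalence classes.

    The representative of {s, revcomp(s)} is the lexicographically smaller
    member; self-complementary words form singleton classes (class_size 1).
    Representatives are listed in lexicographic order.
    """

    n: int
    words: tuple[str, ...]
    class_size: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.words)

    def column_labels(self) -> tuple[str, ...]:
        """Header labels: ``AT`` for singletons, ``AA|TT`` for pairs."""
        return tuple(
            w if c == 1 else f"{w}|{reverse_complement(w)}"
            for w, c in zip(self.words, self.class_size)
        )


@lru_cache(maxsize=None)
def canonical_words(n: int) -> CanonicalWordSet:
    """Enumerate canonical reverse-complement word classes of length `n`.

    The number of classes is ``2**(2n-1)`` for odd n and
    ``2**(2n-1) + 2**(n-1)`` for even n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    words: list[str] = []
    sizes: list[int] = []
    for idx in range(4**n):
        w = index_word(idx, n)
        rc = reverse_complement(w)
        if w < rc:
            words.append(w)
            sizes.append(2)
        elif w == rc:
            words.append(w)
            sizes.append(1)
    return CanonicalWordSet(n=n, words=tuple(words), class_size=tuple(sizes))


def expected_frequency(
    word: str, counts_n1: WordCounts, counts_n2: WordCounts | None
) -> float:
    """E(word) = f(prefix) * f(suffix) / f(middle).

    ``counts_n1`` holds the (n-1)-word counts, ``counts_n2`` the (n-2)-word
    counts; for n = 2 pass ``counts_n2=None`` (empty middle word, f == 1).

    Raises
    ------
    UndefinedExpectation
        If the middle-word count is zero.
    """
    n = len(word)
    if n < 2:
        raise ValueError("expected frequency requires n >= 2")
    if counts_n1.n != n - 1:
        raise ValueError(f"counts_n1 has n={counts_n1.n}, expected {n - 1}")
    f_prefix = counts_n1.frequency(word[:-1])
    f_suffix = counts_n1.frequency(word[1:])
    if n == 2:
        f_middle = 1.0
    else:
        if counts_n2 is None or counts_n2.n != n - 2:
            raise ValueError(f"counts_n2 with n={n - 2} required")
        f_middle = counts_n2.frequency(word[1:-1])
    if f_middle == 0.0:
        raise UndefinedExpectation(f"middle word {word[1:-1]!r} has zero count")
    return f_prefix * f_suffix / f_middle


def odds_ratio(
    word: str,
    counts_n: WordCounts,
    counts_n1: WordCounts,
    counts_n2: WordCounts | None,
    zero_policy: str = "one",
) -> tuple[float, bool]:
    """rho(word) = f(word) / E(word), with the zero-denominator policy.

    Returns ``(rho, flagged)``.  When E(word) = 0 — any denominator count is
    zero — the default policy sets rho to 1 and flags the element ("no
    deviation measurable"); ``zero_policy="error"`` raises instead.  An
    observed zero with positive expectation is a genuine rho = 0, not a
    policy case.
    """
    if zero_policy not in ("one", "error"):
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    try:
        e = expected_frequency(word, counts_n1, counts_n2)
    except UndefinedExpectation:
        e = 0.0
    if e == 0.0:
        if zero_policy == "error":
            raise UndefinedExpectation(f"E({word}) = 0")
        return 1.0, True
    return counts_n.frequency(word) / e, False


@dataclass(frozen=True)
class GGSVector:
    """Odds ratios over the canonical word classes of one sequence at one n."""

    label: str
    n: int
    rho: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flags is None:
            object.__setattr__(self, "flags", np.zeros(len(self.rho), dtype=bool))
        if len(self.flags) != len(self.rho):
            raise ValueError("flags and rho must have equal length")

    @property
    def values(self) -> np.ndarray:
        return self.rho

    def __len__(self) -> int:
        return len(self.rho)


@dataclass(frozen=True)
class KmerFrequencyVector:
    """Observed relative class frequencies (supplementary k-mer mode)."""

    label: str
    n: int
    freq: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.freq

    def __len__(self) -> int:
        return len(self.freq)


def ggs_vector(
    sym: SymmetrizedSequence, n: int, label: str = "", zero_policy: str = "one"
) -> GGSVector:
    """Assemble the odds-ratio signature vector at word length `n`.

    Both members of a canonical pair have equal observed frequency on a
    symmetrized sequence, so the representative's rho is the class value.
    """
    if n < 2:
        raise ValueError("signature vectors require n >= 2")
    counts_n = count_words(sym, n)
    counts_n1 = count_words(sym, n - 1)
    counts_n2 = count_words(sym, n - 2) if n > 2 else None
    cws = canonical_words(n)
    rho = np.empty(len(cws))
    flags = np.zeros(len(cws), dtype=bool)
    for i, w in enumerate(cws.words):
        rho[i], flags[i] = odds_ratio(w, counts_n, counts_n1, counts_n2, zero_policy)
    return GGSVector(label=label, n=n, rho=rho, flags=flags)


def kmer_vector(sym: SymmetrizedSequence, n: int, label: str = "") -> KmerFrequencyVector:
    """Observed class frequencies: summed member counts / total windows."""
    counts = count_words(sym, n)
    cws = canonical_words(n)
    freq = np.empty(len(cws))
    for i, (w, size) in enumerate(zip(cws.words, cws.class_size)):
        total = counts.count(w)
        if size == 2:
            total += counts.count(reverse_complement(w))
        freq[i] = total / counts.windows
    return KmerFrequencyVector(label=label, n=n, freq=freq)


def write_vectors_tsv(
    vectors: list[GGSVector] | list[KmerFrequencyVector], path
) -> None:
    """Write signature vectors as TSV: label, n, one column per class.

    Pair-class columns are labelled ``AA|TT``; values use 10 significant
    digits so files are bit-reproducible across runs.
    """
    if not vectors:
        raise ValueError("no vectors to write")
    n = vectors[0].n
    if any(v.n != n for v in vectors):
        raise ValueError("all vectors must share the same n")
    cws = canonical_words(n)
    with open(path, "w") as fh:
        fh.write("label\tn\t" + "\t".join(cws.column_labels()) + "\n")
        for v in vectors:
            if len(v) != len(cws):
                raise ValueError(f"vector {v.label!r} has wrong length")
            row = "\t".join(format(x, ".10g") for x in v.values)
            fh.write(f"{v.label}\t{n}\t{row}\n")


def read_vectors_tsv(path, kind: str = "ggs") -> list[GGSVector] | list[KmerFrequencyVector]:
    """Read a vector TSV back; ``kind`` selects the container type.

    Zero-policy flags are not serialized and come back unset.
    """
    if kind not in ("ggs", "kmer"):
        raise ValueError(f"unknown vector kind {kind!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["label", "n"]:
            raise ValueError(f"{path}: not a signature vector TSV")
        out: list = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            label, n = fields[0], int(fields[1])
            values = np.array([float(x) for x in fields[2:]])
            if len(values) != len(canonical_words(n)):
                raise ValueError(f"{path}: row {label!r} has wrong length for n={n}")
            if kind == "ggs":
                out.append(GGSVector(label=label, n=n, rho=values))
            else:
                out.append(KmerFrequencyVector(label=label, n=n, freq=values))
    if not out:
        raise ValueError(f"{path}: no vectors found")
    return out
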