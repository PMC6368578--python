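"""Seeded Markov-chain sequence generators for synthetic test collections.

Generates (a) single "genomes" from order-m Markov models with controlled
neighbour-preference bias and (b) dataset concatenates of many short elements
together with matched-length surrogate concatenates from a background model.
All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ggsig.seqio import SequenceRecord, write_fasta
from ggsig.signature import BASES

__all__ = [
    "ClassSpec",
    "MarkovModel",
    "SyntheticCollection",
    "default_collection_spec",
    "make_dataset_and_surrogate",
    "make_test_collection",
    "random_markov_model",
    "simulate_sequence",
    "stationary_distribution",
]


@dataclass(frozen=True)
class MarkovModel:
    """Order-m nucleotide Markov model.

    ``transitions[c]`` is the distribution over A,C,G,T given context index
    ``c`` (base-4 encoding of the previous m bases); ``initial`` is the
    distribution over the 4**m contexts used to start a sequence.  Order 0
    has a single empty context, i.e. an i.i.d. composition model.
    """

    order: int
    initial: np.ndarray
    transitions: np.ndarray

    def __post_init__(self) -> None:
        m = 4**self.order
        if self.transitions.shape != (m, 4):
            raise ValueError(f"transitions must have shape ({m}, 4)")
        if self.initial.shape != (m,):
            raise ValueError(f"initial must have shape ({m},)")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


def stationary_distribution(transitions: np.ndarray, order: int, tol: float = 1e-12) -> np.ndarray:
    """Stationary distribution of the context chain, by power iteration."""
    m = 4**order
    if m == 1:
        return np.ones(1)
    # context c = (b1..bm) moves to ((b2..bm, b)) with prob transitions[c, b]
    pi = np.full(m, 1.0 / m)
    for _ in range(100000):
        nxt = np.zeros(m)
        for b in range(4):
            contrib = pi * transitions[:, b]
            dest = ((np.arange(m) * 4) % m) + b
            np.add.at(nxt, dest, contrib)
        if np.abs(nxt - pi).sum() < tol:
            return nxt / nxt.sum()
        pi = nxt
    raise RuntimeError("stationary distribution did not converge")


def _rc_word_index(idx: int, k: int) -> int:
    """Reverse-complement of a base-4 encoded k-word index."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (idx & 3))
        idx >>= 2
    return out


def _symmetrize_model(trans: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Make the chain's word distribution reverse-complement symmetric.

    The stationary (order+1)-word distribution q is averaged with its
    reverse complement and a new order-m chain is read off the averaged
    distribution.  Left and right m-word marginals of the averaged q agree,
    so the returned (transitions, stationary contexts) define a stationary
    chain with q(w) = q(revcomp(w)) at every word length.
    """
    m = 4**order
    pi = stationary_distribution(trans, order)
    q = (pi[:, None] * trans).ravel()  # index of word c+b is c*4+b
    k = order + 1
    rc = np.fromiter((_rc_word_index(i, k) for i in range(4**k)), dtype=np.int64)
    q = 0.5 * (q + q[rc])
    q = q.reshape(m, 4)
    context_marginal = q.sum(axis=1)
    trans_sym = q / context_marginal[:, None]
    return trans_sym, context_marginal


def random_markov_model(
    order: int,
    gc: float,
    bias_strength: float = 1.0,
    seed: int = 0,
    strand_symmetric: bool = True,
) -> MarkovModel:
    """Seeded random model with given GC content and neighbour bias.

    The baseline composition (A,C,G,T) = ((1-gc)/2, gc/2, gc/2, (1-gc)/2) is
    perturbed per context by multiplicative factors drawn log-uniformly in
    [1/bias_strength, bias_strength] and renormalized; ``bias_strength=1``
    yields the unbiased i.i.d. model exactly.  The initial distribution is
    the stationary distribution of the context chain, so expectations hold
    from the first window.

    By default the perturbed model's word distribution is made reverse-
    complement symmetric (a Chargaff-II-like property of real genomes).
    Without it, the symmetrized counts of a biased model mix two different
    chains and the maximal-order expectation formula is no longer exact at
    n = order + 2; set ``strand_symmetric=False`` to get that behaviour.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if bias_strength < 1.0:
        raise ValueError("bias_strength must be >= 1")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    m = 4**order
    if bias_strength == 1.0:
        trans = np.tile(base, (m, 1))
        initial = stationary_distribution(trans, order)
    else:
        factors = bias_strength ** rng.uniform(-1.0, 1.0, size=(m, 4))
        trans = base * factors
        trans /= trans.sum(axis=1, keepdims=True)
        if strand_symmetric:
            trans, initial = _symmetrize_model(trans, order)
        else:
            initial = stationary_distribution(trans, order)
    return MarkovModel(order=order, initial=initial, transitions=trans)


def _decode_context(ctx: int, order: int) -> str:
    out = []
    for _ in range(order):
        out.append(BASES[ctx & 3])
        ctx >>= 2
    return "".join(reversed(out))


def simulate_sequence(model: MarkovModel, length: int, seed: int, label: str = "sim") -> SequenceRecord:
    """Simulate a single unambiguous run of `length` bases from `model`."""
    if length <= model.order:
        raise ValueError(f"length must exceed model order {model.order}")
    rng = np.random.default_rng(seed)
    m = 4**model.order
    mask = m - 1 if m > 1 else 0
    ctx = int(rng.choice(m, p=model.initial)) if m > 1 else 0
    prefix = _decode_context(ctx, model.order)
    remaining = length - model.order
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, 3] = 1.0  # guard against accumulated rounding
    cum_rows = cum.tolist()
    u = rng.random(remaining).tolist()
    chars = [prefix]
    append = chars.append
    bases = BASES
    for r in u:
        row = cum_rows[ctx]
        if r < row[0]:
            b = 0
        elif r < row[1]:
            b = 1
        elif r < row[2]:
            b = 2
        else:
            b = 3
        append(bases[b])
        ctx = ((ctx << 2) | b) & mask
    return SequenceRecord(id=label, runs=("".join(chars),))


def make_dataset_and_surrogate(
    element_model: MarkovModel,
    background_model: MarkovModel,
    element_lengths: Sequence[int],
    seed: int,
    label: str = "dataset",
) -> tuple[SequenceRecord, SequenceRecord]:
    """Element concatenate plus a matched-length surrogate concatenate.

    The dataset is a concatenate of elements simulated from `element_model`;
    the surrogate concatenates segments of exactly the same lengths from
    `background_model`.  Element boundaries are preserved as runs, so no
    counting window spans two elements.
    """
    if any(l <= max(element_model.order, background_model.order) for l in element_lengths):
        raise ValueError("every element length must exceed the model orders")
    ss = np.random.SeedSequence(entropy=seed)
    seeds = ss.generate_state(2 * len(element_lengths))
    elem_runs = []
    surr_runs = []
    for i, length in enumerate(element_lengths):
        elem_runs.append(
            simulate_sequence(element_model, length, int(seeds[2 * i])).runs[0]
        )
        surr_runs.append(
            simulate_sequence(background_model, length, int(seeds[2 * i + 1])).runs[0]
        )
    return (
        SequenceRecord(id=label, runs=tuple(elem_runs)),
        SequenceRecord(id=f"{label}_surrogate", runs=tuple(surr_runs)),
    )


@dataclass(frozen=True)
class ClassSpec:
    """One generator class of a synthetic collection."""

    name: str
    model: MarkovModel
    count: int
    length: int
    model_params: dict = field(default_factory=dict)  # for the manifest


@dataclass(frozen=True)
class SyntheticCollection:
    records: tuple[SequenceRecord, ...]
    truth: dict[str, str]
    manifest: dict

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.truth:
                raise ValueError(f"record {rec.id!r} missing from truth table")


def default_collection_spec() -> list[ClassSpec]:
    """Three generator classes: strongly biased order-1 concatenate-like
    elements, order-2 biased exon-like elements, and an unbiased background.

    The class models are fixed constants — they define the classes — while
    the collection seed only drives sequence simulation.  Model seeds and
    bias strengths are chosen so the three class centroids at n=2 are nearly
    equidistant; wildly unbalanced separations would push the WSS elbow from
    the true k=3 to k=2.
    """
    params = [
        ("cne-like", dict(order=1, gc=0.38, bias_strength=1.8, seed=6)),
        ("exon-like", dict(order=2, gc=0.52, bias_strength=4.0, seed=4)),
        ("background", dict(order=0, gc=0.45, bias_strength=1.0, seed=0)),
    ]
    return [
        ClassSpec(
            name=name,
            model=random_markov_model(**p),
            count=6,
            length=500_000,
            model_params=p,
        )
        for name, p in params
    ]


def make_test_collection(
    class_specs: Sequence[ClassSpec] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticCollection:
    """Simulate a labeled multi-class collection (and optionally write it).

    With ``out_dir`` set, writes ``collection.fasta``, ``truth.tsv``
    (label, class) and ``manifest.json`` holding every parameter and seed
    needed to regenerate the collection bit-identically.
    """
    if class_specs is None:
        class_specs = default_collection_spec()
    if len(class_specs) < 2:
        raise ValueError(">= 2 classes required")
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    manifest_classes = []
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(2,))
    for spec, child in zip(class_specs, ss.spawn(len(class_specs))):
        member_seeds = [int(x) for x in child.generate_state(spec.count)]
        for i, mseed in enumerate(member_seeds):
            label = f"{spec.name}_{i}"
            records.append(
                simulate_sequence(spec.model, spec.length, mseed, label=label)
            )
            truth[label] = spec.name
        manifest_classes.append(
            {
                "name": spec.name,
                "count": spec.count,
                "length": spec.length,
                "model_params": spec.model_params,
                "member_seeds": member_seeds,
            }
        )
    manifest = {"seed": seed, "classes": manifest_classes}
    collection = SyntheticCollection(
        records=tuple(records), truth=truth, manifest=manifest
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(collection.records, out_dir / "collection.fasta")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("label\tclass\n")
            for rec in collection.records:
                fh.write(f"{rec.id}\t{truth[rec.id]}\n")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return collection
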