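"""End-to-end workflows: genome collection -> distances -> tree, and
dataset concatenates -> signatures -> PCA / k-means / partition check.

Every run writes a ``run_manifest.json`` recording input digests, parameters
and seeds; deterministic stages reproduce their outputs byte-identically
when re-run from the same manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import ggsig
from ggsig.cluster import (
    complete_linkage,
    elbow_suggest,
    kmeans_wss,
    pca_project,
    to_newick,
    type_partition_check,
)
from ggsig.distance import (
    distance_matrix,
    percent_rank_similarity,
    write_matrix_long_tsv,
    write_matrix_tsv,
)
from ggsig.seqio import read_fasta, symmetrize
from ggsig.signature import ggs_vector, kmer_vector, write_vectors_tsv

log = logging.getLogger("ggsig")

__all__ = ["RunConfig", "run_genome_workflow", "run_dataset_workflow"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one workflow run."""

    fasta: str
    out_dir: str
    n: int = 2
    mode: str = "ggs"  # or "kmer"
    seed: int = 0
    concat_records: bool = False
    hard_mask: bool = False
    types_tsv: str | None = None
    pairs_tsv: str | None = None
    k_min: int = 1
    k_max: int = 15
    restarts: int = 20
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("ggs", "kmer"):
            raise ValueError(f"mode must be 'ggs' or 'kmer', got {self.mode!r}")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, out_dir: Path, extra: dict) -> None:
    manifest = {
        "tool": "ggsig",
        "version": ggsig.__version__,
        "config": cfg.to_dict(),
        "inputs": {
            p: _sha256(p)
            for p in (cfg.fasta, cfg.types_tsv, cfg.pairs_tsv)
            if p is not None
        },
        **extra,
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _compute_vectors(cfg: RunConfig):
    records = read_fasta(cfg.fasta, concat_records=cfg.concat_records, hard_mask=cfg.hard_mask)
    log.info("loaded %d record(s) from %s", len(records), cfg.fasta)
    vectors = []
    for rec in records:
        sym = symmetrize(rec)
        if cfg.mode == "ggs":
            v = ggs_vector(sym, cfg.n, label=rec.id)
            fired = int(np.sum(v.flags))
            if fired:
                log.warning(
                    "zero-denominator policy fired for %d/%d classes of %s",
                    fired, len(v), rec.id,
                )
        else:
            v = kmer_vector(sym, cfg.n, label=rec.id)
        vectors.append(v)
    return vectors


def _read_two_column_tsv(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: {what} rows need 2 columns")
            rows.append((fields[0], fields[1]))
    if rows and rows[0] == ("label", "class"):
        rows = rows[1:]
    return rows


def run_genome_workflow(cfg: RunConfig) -> dict[str, Path]:
    """Signatures per sequence -> delta matrix -> cladogram (+ rank report)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vectors = _compute_vectors(cfg)
    if len(vectors) < 2:
        raise ValueError("genome workflow needs >= 2 input sequences")
    outputs: dict[str, Path] = {}

    outputs["vectors"] = out_dir / f"vectors_n{cfg.n}.tsv"
    write_vectors_tsv(vectors, outputs["vectors"])

    m = distance_matrix(vectors)
    outputs["matrix"] = out_dir / f"delta_n{cfg.n}.tsv"
    write_matrix_tsv(m, outputs["matrix"])
    outputs["matrix_long"] = out_dir / f"delta_n{cfg.n}_long.tsv"
    write_matrix_long_tsv(m, outputs["matrix_long"])

    tree = complete_linkage(m)
    outputs["tree"] = out_dir / f"tree_n{cfg.n}.nwk"
    outputs["tree"].write_text(to_newick(tree) + "\n")

    if cfg.pairs_tsv:
        pairs = _read_two_column_tsv(cfg.pairs_tsv, "pair")
        ranks = percent_rank_similarity(m, pairs)
        outputs["ranks"] = out_dir / f"ranks_n{cfg.n}.tsv"
        with open(outputs["ranks"], "w") as fh:
            fh.write("label1\tlabel2\tpercent_rank\n")
            for (a, b), r in ranks.items():
                fh.write(f"{a}\t{b}\t{format(r, '.10g')}\n")

    _write_manifest(cfg, out_dir, {"workflow": "genome"})
    log.info("genome workflow complete: %s", sorted(outputs))
    return outputs


def run_dataset_workflow(cfg: RunConfig) -> dict[str, Path]:
    """Signatures per dataset -> PCA(2) -> WSS curve + elbow -> partition check."""
    if not cfg.types_tsv:
        raise ValueError("dataset workflow requires a types table (label, type)")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vectors = _compute_vectors(cfg)
    if len(vectors) < 2:
        raise ValueError("dataset workflow needs >= 2 input datasets")
    types = dict(_read_two_column_tsv(cfg.types_tsv, "type"))
    outputs: dict[str, Path] = {}

    outputs["vectors"] = out_dir / f"vectors_n{cfg.n}.tsv"
    write_vectors_tsv(vectors, outputs["vectors"])

    pca = pca_project(vectors, components=2)
    outputs["pca"] = out_dir / f"pca_n{cfg.n}.tsv"
    with open(outputs["pca"], "w") as fh:
        fh.write("label\tpc1\tpc2\n")
        for label, (x, y) in zip(pca.labels, pca.coordinates):
            fh.write(f"{label}\t{format(x, '.10g')}\t{format(y, '.10g')}\n")

    k_max = min(cfg.k_max, len(vectors))
    curve = kmeans_wss(
        vectors,
        k_min=cfg.k_min,
        k_max=k_max,
        restarts=cfg.restarts,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    elbow = elbow_suggest(curve)
    outputs["wss"] = out_dir / f"wss_n{cfg.n}.tsv"
    with open(outputs["wss"], "w") as fh:
        fh.write(f"# elbow_k={elbow.k}\tclear={elbow.clear}\n")
        fh.write("k\twss\n")
        for k, w in zip(curve.ks, curve.wss):
            fh.write(f"{k}\t{format(w, '.10g')}\n")

    m = distance_matrix(vectors)
    report = type_partition_check(m, types)
    outputs["partition"] = out_dir / f"partition_n{cfg.n}.tsv"
    with open(outputs["partition"], "w") as fh:
        fh.write(f"# max_same_type={format(report.max_same_type, '.10g')}")
        fh.write(f"\tmin_different_type={format(report.min_different_type, '.10g')}")
        fh.write(f"\tperfect={report.perfect}\n")
        fh.write("label1\tlabel2\tdelta\tviolation\n")
        for a, b, d, kind in report.violations:
            fh.write(f"{a}\t{b}\t{format(d, '.10g')}\t{kind}\n")

    _write_manifest(cfg, out_dir, {"workflow": "dataset", "elbow_k": elbow.k})
    log.info("dataset workflow complete: %s", sorted(outputs))
    return outputs
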