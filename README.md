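# ggsig

Alignment-free DNA sequence comparison through strand-symmetric n-word
odds-ratio signatures.

For each sequence (conceptually concatenated with its reverse complement) and
each word length `n`, the package computes the odds ratio
`rho(s) = f(s) / E(s)` for every canonical reverse-complement word class,
where the expected frequency

```
E(s) = f(N1..Nn-1) * f(N2..Nn) / f(N2..Nn-1)
```

filters out all shorter-range compositional structure, leaving only
distance-`n` neighbour preferences (for `n = 2` this reduces to the classical
dinucleotide form `f(XY) / (f(X) f(Y))`).  Signature vectors have
10 / 32 / 136 / 512 elements for `n = 2..5`.  The distance between two
signatures is the scaled Manhattan metric
`delta(g, h) = (1/w_n) * sum |rho_i(g) - rho_i(h)|`.

Built on top of these primitives:

- pairwise delta-distance matrices and percent *rank of similarity*
  (100% = most similar pair),
- complete-linkage cladograms with Newick export,
- PCA projection of signature vectors,
- k-means with the within-groups-sum-of-squares elbow heuristic,
- a naive same-type / different-type partition check,
- a supplementary raw k-mer-frequency vector mode,
- a seeded Markov-chain simulator producing genomes, element concatenates,
  matched surrogate concatenates and labeled multi-class test collections.

## Command-line usage

```sh
# synthetic 3-class collection (FASTA + truth table + manifest)
ggsig simulate --out-dir sim --seed 1

# signature vectors (one row per FASTA record; --concat merges records
# into one dataset concatenate, --mode kmer for raw class frequencies)
ggsig compute --fasta sim/collection.fasta --n 2 --out vectors.tsv

# distances, tree, PCA, k-means/elbow, ranks, partition report
ggsig dist --vectors vectors.tsv --out delta.tsv --long-out delta_long.tsv
ggsig tree --matrix delta.tsv --out tree.nwk
ggsig pca --vectors vectors.tsv --out pca.tsv
ggsig kmeans --vectors vectors.tsv --k-min 1 --k-max 15 --seed 1 --out wss.tsv
ggsig ranksim --matrix delta.tsv --pairs pairs.tsv --out ranks.tsv
ggsig partition --matrix delta.tsv --types sim/truth.tsv --out partition.tsv
```

Two end-to-end workflows bundle the steps and write a `run_manifest.json`
with input digests, parameters and seeds:

```sh
ggsig run-genome  --fasta genomes.fasta --n 2 --out-dir out/   # vectors, matrix, tree, ranks
ggsig run-dataset --fasta sets.fasta --types types.tsv --out-dir out/  # vectors, PCA, WSS+elbow, partition
```

All flags can be supplied from a `key=value` config file via
`ggsig --config run.cfg <command>`.  Exit codes: 0 success, 2 input error,
3 numerical/degenerate-input error.

## Conventions

- Ambiguous bases split sequences into runs; no counting window spans an
  ambiguous base, a record boundary, or the strand junction.  Lowercase
  bases are upcased unless `--hard-mask` is given.
- Canonical class representatives are the lexicographically smaller member
  of each `{s, revcomp(s)}` pair, listed in lexicographic order; pair-class
  TSV columns are labelled e.g. `AA|TT`.
- When `E(s) = 0` the odds ratio defaults to 1 and the element is flagged
  (logged by the workflows); an observed zero with positive expectation is a
  genuine `rho = 0`.

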