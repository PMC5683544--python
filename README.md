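# mitocmp

Comparative analysis of circular plant mitochondrial genomes, built around
the kind of question raised by cotton (*Gossypium*): closely related
mitogenomes whose genes barely diverge in sequence, yet whose genome
*structures* — repeat content, segment presence/absence, gene order — evolve
rapidly, and whose DNA keeps leaking into the nuclear genome as NUMTs.

The package is a library first (import `mitocmp`), with short narrative
scripts under `examples/` and a thin `mitocmp` command-line wrapper.

## What it computes

- **Repeat catalogue** — all *maximal exact repeats* within a circular
  genome (forward and reverse-complement, origin-aware), clustered into
  families and classified as large (≥ 1 kb), medium (100–999 bp) or small
  (< 100 bp). Large dispersed repeats are the substrate of the homologous
  recombination that reshuffles plant mitogenomes.
- **Homology coverage and unique segments** — pairwise maximal exact
  matches ≥ 30 bp act as homology anchors (the sensitivity floor of a
  relaxed blastn search between genomes that differ by < 1%); the
  uncovered complement of a genome, filtered at ≥ 100 bp, is its set of
  *unique segments*. The **complexity-absence matrix** reports, for every
  ordered genome pair, the percentage of the column genome that the row
  genome lacks:
  `M[r][c] = 100 · (unique bases of c relative to r) / length(c)`.
- **Gene-order rearrangement** — gene orders are decomposed into shared
  syntenic blocks (maximal runs of genes contiguous and co-oriented in
  every genome); each genome becomes a signed permutation of block ids,
  and an exhaustive breadth-first search returns a *provably minimal*
  scenario of inversions and translocations (unit cost each, circular
  permutations compared up to rotation).
- **p-distances and NUMT dating** — p = differing/compared sites
  (pairwise or complete gap deletion), and insertion ages under the
  two-rate model

  `T = p / (r_nu + r_mt)`,  with defaults `r_nu = 6.5e-9`,
  `r_mt = 2e-10` substitutions·site⁻¹·yr⁻¹.

- **NUMT scanning** — maximal exact matches ≥ 100 bp between a nuclear
  chromosome and the mitogenome, chained into insertion blocks when
  consecutive matches are co-oriented and closer than 500 bp on both axes;
  per block identity, p-distance and age.
- **Synthetic evolution** — ancestors of arbitrary length and GC, planted
  repeat families, inversions/translocations/indels/substitution epochs,
  and NUMT chromosomes of known age, all with emitted ground truth. The
  defaults emulate a diploid-cotton-like mitogenome: 644,395 bp at 44.9%
  GC, six large repeats (12,921 … 7,317 bp), eight unique insertions of
  108–7,888 bp totalling 18,194 bp.

## Worked example

```python
from mitocmp import find_maximal_repeats, classify_and_count
from mitocmp.simulate import indel_trio_scenario

res = indel_trio_scenario(seed=1).run()
fams = find_maximal_repeats(res.ancestor, min_len=1000)
print(classify_and_count(fams)["large"])
print(sorted((f.unit_length for f in fams), reverse=True))
```

prints

```
6
[12921, 12669, 10632, 9121, 8544, 7317]
```

— six large repeat families, recovered at exactly the planted unit
lengths: the repeat profile of a diploid-type cotton mitogenome. Running
`python examples/04_numt_dating.py` detects a simulated 100 kb NUMT and
dates it at 0.32 MYA against a true age of 0.33 MYA (binomial noise on
~100,000 compared sites). The other examples cover unique-segment calling
(`02`) and certified-minimal rearrangement scenarios (`03`).

## Command line

```sh
mitocmp generate --scenario scenario.json --out-dir sim/
mitocmp repeats --fasta genomes.fasta --min-len 1000 --out repeats.tsv
mitocmp compare --fasta genomes.fasta --out-matrix m.tsv --out-segments u.bed
mitocmp order --annotations genes.tsv --out-blocks b.tsv --out-distance d.tsv
mitocmp numt --nuclear chr.fa --mito mito.fa --out numts.tsv
mitocmp date --p 0.0009
mitocmp all --fasta genomes.fasta --out-dir report/
```

All outputs are plain TSV/BED with a parameter-echo header line, so any
run can be repeated exactly from its own outputs.

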