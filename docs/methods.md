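# Methods

## Scope and data model

`mitocmp` treats a mitochondrial genome as a single circular DNA molecule
over {A, C, G, T, N}. All coordinates are 0-based half-open; a feature
spanning the origin is stored with `end > length` and interpreted modulo
the genome length, splitting into at most two linear parts only at I/O or
interval-arithmetic boundaries. Downstream string algorithms see circular
context through a doubled-sequence view (`seq + seq`), never through
special-cased wrap logic inside the scanners. `N` is permitted but never
matches anything in repeat or homology search — a deliberately
conservative treatment of ambiguity.

The annotation table is TSV (`genome_id gene start end strand`) with the
coordinate convention declared in a `# coords:` comment or by the caller,
defaulting to 0-based half-open; conversion happens at the I/O boundary
only, because deposited organelle annotations do not reliably state their
convention.

## Maximal exact matching

The shared primitive behind repeat detection, homology anchoring and NUMT
scanning is the maximal exact match. Every k-mer window
(k = min(min_len, 31)) is packed exactly into a 64-bit integer — 2 bits
per base, windows containing N invalidated — so seeding is collision-free
by construction. Equal windows of the two (doubled) sequences are joined
and sorted by diagonal; because a match of length m contains exactly
m − k + 1 consecutive window positions, runs of consecutive seed hits on
one diagonal are in one-to-one correspondence with exact matches ≥ k. Two
O(1) post-filters finish the job: a one-base extension check discards
candidates truncated at doubled-view edges (their untruncated twin is
always generated elsewhere), and coordinates taken modulo the genome
length collapse the up-to-four doubled-view placements of each circular
match into one canonical record. Runs that wrap the full circle
(possible only in self-comparison or between equal-length circles) are
capped at the genome length and anchored canonically; between circles of
different lengths an over-length run is a genuine maximal match whose
footprint wraps past the smaller circle and is kept whole.

Self-comparison excludes identity diagonals, reports each unordered copy
pair once, and drops exact palindromic self-pairs (an interval matching
its own reverse complement is not two copies). Overlapping *distinct*
copies — tandem-style repeats — are reported; the worked micro-example is
`ATCGATCGA`, whose two copies at 0 and 4 extend maximally to the
overlapping unit `ATCGA`.

The test suite certifies the scanner against an independent brute-force
oracle (per-diagonal and per-anti-diagonal equality runs) with exact set
equality on hundreds of random circular and linear sequences.

## Repeat families and size classes

Pairwise maximal matches are clustered into families by shared copy
intervals (identical start and length, union-find); relative orientations
propagate along match edges from the leftmost copy. In exact mode every
copy of a family has the same unit length, and the family's size class is
a pure function of it: large ≥ 1000 bp, medium 100–999 bp, small
< 100 bp. Exact repeats are the deliberate core contract — published
repeat tables for organelle genomes derive from maximal exact matching —
and near-identical merging is left out of the default path. Families with
different maximal extents against different partners stay separate
families; this matches the pairwise-maximal semantics of the repeat
tables the output is modelled on.

## Homology, unique segments, complexity absence

The homology primitive is the maximal exact match ≥ `min_anchor`
(default 30 bp) rather than an E-value local aligner: between genomes
that diverge by well under 1%, exact 30-mers recover essentially the same
homologous footprint a permissive blastn would, deterministically and
with no external dependency. Isolated substitutions cost only the
mismatched column (flanking anchors re-cover the rest), so spurious
"unique" gaps stay far below the 100 bp reporting floor.

Coverage of target by query is the merged union of anchor footprints on
the target; unique segments are the complement, filtered to
≥ `min_missing` (default 100 bp — smaller gaps are noise or trivial
indels, not missing genome complexity). A gap crossing the origin is
reported once, as a single wrapping segment. Called segment edges can
each be off by up to one anchor length (a < min_anchor sliver of true
homology adjacent to an insertion cannot be anchored); the planted-indel
recovery test asserts exactly this ± min_anchor tolerance per edge.

The complexity-absence matrix is row-reads-column: `M[r][c]` is the
percentage of genome *c* (denominator: its full length) lying in unique
segments relative to genome *r* — "what share of c has r lost". The
direction convention is fixed this way because the asymmetry it produces
(a small genome missing little of a large one, the large one missing more
of the small one's content) is the biologically meaningful reading; the
matrix is generally asymmetric with a zero diagonal. Using plain genome
length rather than a non-redundant "complexity" denominator is the
simplest defensible choice; with ≤ 2% of these genomes in large repeats
the difference is second-order.

## Gene order and rearrangement distance

Shared syntenic blocks are maximal runs of genes contiguous with
consistent relative orientation in *every* genome, computed from signed
gene adjacencies (an adjacency survives if each genome contains it
forward or reverse-complemented, including the wrap adjacency on circular
genomes). Genes missing from any genome, or annotated in multiple copies,
are dropped with a warning — a signed permutation needs single-copy
markers. The reference genome maps to the identity permutation.

The rearrangement distance is computed by exhaustive breadth-first search
over signed permutations, applying every single inversion
(reverse+negate a contiguous run, circularly) and every translocation
(move a contiguous run elsewhere, optionally inverted), each at unit
cost — the uniform "changes" count used when describing organelle
rearrangements. Circular permutations are canonicalized by minimal
rotation; rotation is free, but a whole-molecule flip is not treated as
identity, so every single inversion is at distance exactly 1. The search
is bidirectional with raw-state witnesses, so the returned scenario
replays from source to target and the count is a certified minimum. The
exact search refuses beyond `max_blocks` (default 10; the state space is
n!·2ⁿ) — enough for the ~8 syntenic blocks typical of these comparisons.
Tests compare against an independent uni-directional BFS on all signed
permutations of up to 5 blocks, linear and circular.

## Distances and dating

p-distance is differing/compared sites. `pairwise_deletion` (default, the
common default of standard distance software — the source analyses do not
state their option) excludes a column only when the pair at hand has a
gap or N there; `complete_deletion` also excludes columns gapped anywhere
in the alignment. Zero comparable sites is an error, not a zero.

NUMT ages use `T = p / (r_nu + r_mt)` with homogeneous rates since
divergence, defaults `r_nu = 6.5e-9` and `r_mt = 2e-10`
substitutions·site⁻¹·yr⁻¹ (angiosperm nuclear and mitochondrial rate
estimates). Reported ages are rounded to two decimals in MYA, matching
the precision at which such estimates are meaningful. The formula is
linear in p, so per-segment and concatenated datings interconvert by
weighted averaging.

## NUMT scanning

Anchors (maximal exact matches ≥ `min_match`, default 100 bp — the
standard whole-genome-alignment setting for this task) are chained into
blocks when consecutive anchors are co-oriented, separated by less than
`chain_gap` (default 500 bp) on the nuclear axis, and consistent in order
and orientation on the (circular) mitochondrial axis; small overlaps up
to one anchor length are tolerated because substitutions inside repeats
can split anchors unevenly. Identity and p-distance are computed
columnwise over anchor-covered positions plus inter-anchor spans of equal
length on both axes; unequal-length (indel) spans contribute no sites.
This avoids full affine-gap alignment while matching the "percent
identical" semantics of dot-matrix comparisons; it slightly undercounts
compared sites when an inter-anchor span contains both substitutions and
an indel, which is negligible at the < 1% divergences involved. The
nuclear side is treated as linear, the mitochondrial side circularly.

## Synthetic evolution and what it does (not) show

The generator's defaults emulate the study system: a 644,395 bp circular
ancestor at 44.9% GC; six planted large-repeat families with unit lengths
12,921 / 12,669 / 10,632 / 9,121 / 8,544 / 7,317 bp (two copies each,
alternating orientations); eight unique insertions of
108 / 300 / 600 / 900 / 1,500 / 2,898 / 4,000 / 7,888 bp — bounds and
18,194 bp total fixed by the reported unique-segment burden, interior
sizes chosen once to fill that total — plus one 80 bp insertion that must
*not* be called; substitution epochs at organelle-like rates; and NUMT
chromosomes whose nuclear and mitochondrial copies diverge independently
at the two model rates. Planted repeats pin their flanking bases to
distinct letters per copy so the maximal repeat length equals the planted
size exactly; insertions are i.i.d. random DNA, so they share no homology
with the background.

Substitutions are i.i.d. across sites and uniform over the three
alternative bases: no rate heterogeneity, no transition bias, no indel
polymerase model, no selection. Passing tests therefore certify the
*algorithms* (exact recovery of planted structure, unbiased age
estimation under the stated model) — they do not certify robustness to
rate heterogeneity, nested/partially overlapping biological repeats, or
alignment ambiguity in real data.

Structural events operate on non-wrapping coordinates (rotate first to
edit across the origin), and ground-truth segment coordinates are remapped
through every subsequent indel so the truth tables always refer to the
final emitted sequences; deterministic under a single integer seed.

## Problem sizes and numerical choices

Tests and examples run at the full 644 kb mitogenome scale for repeat
and unique-segment recovery (a few seconds each with the seed-run
scanner), a 200 kb mitogenome with 100 kb inserted segments for NUMT age
recovery (21 replicates across three true ages; per-replicate binomial
noise on ~10⁵ compared sites is ~0.014 MYA at the youngest age), and
≤ 5 blocks for exhaustive rearrangement cross-validation. Age-recovery
assertions use three standard errors of the group mean. Tie-breaks are
leftmost-start canonicalization throughout; degenerate inputs (empty
sequences, no comparable sites, overlong events) raise typed errors
rather than returning sentinel values.

## Known limitations

- Exact-match homology underestimates coverage for divergences well above
  ~1–2%, inflating unique segments; the anchor floor should be lowered or
  an aligner substituted beyond that regime.
- Identity within NUMT blocks ignores unequal-gap spans rather than
  aligning them.
- The rearrangement search certifies minimality only up to `max_blocks`;
  no DCJ-style closed form is provided.
- Repeat families are exact; a diverged repeat copy (> 0 mismatches)
  splits into shorter families instead of joining at < 100% identity.
- The dating model inherits its rate calibrations; ages scale inversely
  with `r_nu + r_mt` and are only as good as those constants.
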