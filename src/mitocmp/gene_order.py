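"""Syntenic-block extraction from gene orders and exact minimum
inversion+translocation scenarios between genomes.

Blocks are maximal runs of genes that stay contiguous with consistent
relative orientation in every genome (gene adjacency conservation); each
genome is then a signed permutation of block ids. The rearrangement
distance is certified minimal by breadth-first search over the permutation
space, applying every single inversion (reverse and negate a contiguous
run) and translocation (move a contiguous run elsewhere, optionally
inverted), each at unit cost. Circular permutations are compared up to
rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import DecompositionError, SearchSpaceError


@dataclass(frozen=True)
class BlockPermutation:
    """Signed ordering of shared syntenic blocks for one genome."""

    genome: str
    blocks: tuple[int, ...]
    circular: bool = True

    def __post_init__(self):
        ids = sorted(abs(b) for b in self.blocks)
        if ids != list(range(1, len(self.blocks) + 1)):
            raise DecompositionError(
                f"blocks of {self.genome!r} are not a signed permutation of 1..n"
            )


@dataclass
class RearrangementScenario:
    """A witness sequence of operations transforming source into target."""

    op_count: int
    ops: list[dict] = field(default_factory=list)


@dataclass
class BlockDecomposition:
    """Shared syntenic blocks and the per-genome signed permutations."""

    blocks: list[list[str]]  # gene names per block, in reference orientation
    permutations: dict[str, BlockPermutation]
    reference: str


def gene_orders_from_annotations(annotations) -> dict[str, list[tuple[str, str]]]:
    """Group a flat annotation list into per-genome (gene, strand) orders."""
    by_genome: dict[str, list] = {}
    for a in annotations:
        by_genome.setdefault(a.genome_id, []).append(a)
    return {
        gid: [(a.gene, a.strand) for a in sorted(rows, key=lambda a: a.start)]
        for gid, rows in by_genome.items()
    }


def shared_blocks(
    orders: dict[str, list[tuple[str, str]]],
    circular: bool = True,
    reference: str | None = None,
) -> BlockDecomposition:
    """Decompose gene orders into maximal conserved syntenic blocks.

    ``orders`` maps genome id to its gene order as (gene, strand) tuples.
    Genes missing from any genome, and genes annotated more than once in a
    genome, are dropped with a warning. The reference genome (first by
    default) maps to the identity permutation (+1, ..., +m).
    """
    if reference is None:
        reference = next(iter(orders))
    if reference not in orders:
        raise DecompositionError(f"reference genome {reference!r} not in input")

    # genes present exactly once in every genome
    counts_per_genome = {
        gid: {g: [x[0] for x in order].count(g) for g, _ in order}
        for gid, order in orders.items()
    }
    common = None
    for gid, counts in counts_per_genome.items():
        once = {g for g, c in counts.items() if c == 1}
        common = once if common is None else common & once
    dropped = {
        g for order in orders.values() for g, _ in order if g not in common
    }
    if dropped:
        warnings.warn(
            f"dropping genes absent or multicopy in some genome: {sorted(dropped)}"
        )
    if len(common) < 2:
        raise DecompositionError("fewer than 2 genes shared by all genomes")

    filt = {
        gid: [(g, s) for g, s in order if g in common]
        for gid, order in orders.items()
    }
    ref_order = filt[reference]
    gene_idx = {g: i + 1 for i, (g, _) in enumerate(ref_order)}
    ref_strand = {g: s for g, s in ref_order}
    n = len(ref_order)

    signed = {}
    for gid, order in filt.items():
        signed[gid] = [
            gene_idx[g] if s == ref_strand[g] else -gene_idx[g] for g, s in order
        ]

    def adjacency_set(seq):
        pairs = list(zip(seq, seq[1:]))
        if circular and len(seq) > 1:
            pairs.append((seq[-1], seq[0]))
        out = set()
        for u, v in pairs:
            out.add((u, v))
            out.add((-v, -u))
        return out

    adjsets = {gid: adjacency_set(seq) for gid, seq in signed.items()}

    def conserved(x, y):
        return all((x, y) in s for s in adjsets.values())

    breaks = [i for i in range(n - 1) if not conserved(i + 1, i + 2)]
    wrap_conserved = circular and conserved(n, 1)
    if circular and not wrap_conserved:
        breaks.append(n - 1)

    if not breaks:  # circular, fully conserved cycle (or linear single run)
        if circular:
            blocks_idx = [list(range(1, n + 1))]
        else:
            blocks_idx = [list(range(1, n + 1))]
    else:
        bounds = sorted(breaks)
        runs = []
        start = 0
        for b in bounds:
            runs.append(list(range(start + 1, b + 2)))
            start = b + 1
        if start < n:
            runs.append(list(range(start + 1, n + 1)))
        if circular and wrap_conserved and len(runs) > 1:
            runs[0] = runs[-1] + runs[0]  # block spanning the origin
            runs.pop()
        blocks_idx = runs

    # lookup from the signed element that starts a block (in either reading
    # direction) to (block_index, direction)
    lookup = {}
    for bi, blk in enumerate(blocks_idx):
        lookup[blk[0]] = (bi, "+")
        lookup.setdefault(-blk[-1], (bi, "-"))

    def scan(seq):
        m = len(seq)
        if circular:
            p0 = next((p for p in range(m) if seq[p] in lookup), None)
            if p0 is None:
                raise DecompositionError("gene order inconsistent with blocks")
            seq = seq[p0:] + seq[:p0]
        out = []
        i = 0
        while i < m:
            u = seq[i]
            if u not in lookup:
                raise DecompositionError("gene order inconsistent with blocks")
            bi, dirn = lookup[u]
            blk = blocks_idx[bi]
            expect = blk if dirn == "+" else [-x for x in reversed(blk)]
            if seq[i : i + len(blk)] != expect:
                raise DecompositionError("gene order inconsistent with blocks")
            out.append((bi, dirn))
            i += len(blk)
        return out

    # number blocks 1..m by their order in the reference scan
    ref_scan = scan(signed[reference])
    number = {bi: j + 1 for j, (bi, _) in enumerate(ref_scan)}

    perms = {}
    for gid, seq in signed.items():
        s = scan(seq)
        perms[gid] = BlockPermutation(
            genome=gid,
            blocks=tuple(
                number[bi] if dirn == "+" else -number[bi] for bi, dirn in s
            ),
            circular=circular,
        )

    idx_to_gene = {i: g for g, i in gene_idx.items()}
    named = [None] * len(blocks_idx)
    for bi, blk in enumerate(blocks_idx):
        named[number[bi] - 1] = [idx_to_gene[i] for i in blk]
    return BlockDecomposition(blocks=named, permutations=perms, reference=reference)


# ---------------------------------------------------------------------------
# rearrangement distance


def canonical(state: tuple[int, ...], circular: bool) -> tuple[int, ...]:
    """Rotation-minimal representative of a circular signed permutation."""
    if not circular:
        return state
    n = len(state)
    return min(tuple(state[i:] + state[:i]) for i in range(n))


def apply_op(state: tuple[int, ...], op: dict, circular: bool) -> tuple[int, ...]:
    """Apply one inversion or translocation to a raw signed permutation."""
    n = len(state)
    if op["type"] == "inversion":
        s, l = op["start"], op["length"]
        st = list(state)
        idxs = [(s + i) % n for i in range(l)] if circular else list(range(s, s + l))
        vals = [st[i] for i in idxs][::-1]
        for i, v in zip(idxs, vals):
            st[i] = -v
        return tuple(st)
    if op["type"] == "translocation":
        s, l, p = op["start"], op["length"], op["insert_at"]
        idxs = [(s + i) % n for i in range(l)] if circular else list(range(s, s + l))
        picked = set(idxs)
        seg = [state[i] for i in idxs]
        rest = [state[i] for i in range(n) if i not in picked]
        if op.get("inverted", False):
            seg = [-x for x in reversed(seg)]
        return tuple(rest[:p] + seg + rest[p:])
    raise ValueError(f"unknown op type {op['type']!r}")


def _neighbor_ops(n: int, circular: bool):
    ops = []
    max_s = n if circular else n
    for l in range(1, n + 1):
        for s in range(n if circular else n - l + 1):
            ops.append({"type": "inversion", "start": s, "length": l})
    for l in range(1, n):
        rest = n - l
        for s in range(n if circular else n - l + 1):
            last_p = rest if not circular else rest  # gap indices 0..rest-1 (+end for linear)
            for p in range(rest + (0 if circular else 1)):
                for inv in (False, True):
                    ops.append(
                        {
                            "type": "translocation",
                            "start": s,
                            "length": l,
                            "insert_at": p,
                            "inverted": inv,
                        }
                    )
    return ops


def min_rearrangement(
    source: BlockPermutation,
    target: BlockPermutation,
    max_blocks: int = 10,
) -> RearrangementScenario:
    """Provably minimal inversion+translocation scenario (exhaustive BFS).

    Both operation types cost 1. Raises :class:`SearchSpaceError` above
    ``max_blocks`` blocks. The returned scenario replays from ``source.blocks``
    to a permutation equal to ``target.blocks`` (up to rotation when
    circular).
    """
    if sorted(abs(b) for b in source.blocks) != sorted(abs(b) for b in target.blocks):
        raise DecompositionError("source and target must share the same block set")
    if source.circular != target.circular:
        raise DecompositionError("source and target disagree on circularity")
    n = len(source.blocks)
    if n > max_blocks:
        raise SearchSpaceError(
            f"{n} blocks exceeds max_blocks={max_blocks}; exact search refused"
        )
    circular = source.circular
    src = tuple(source.blocks)
    tgt = tuple(target.blocks)
    if canonical(src, circular) == canonical(tgt, circular):
        return RearrangementScenario(op_count=0, ops=[])

    ops = _neighbor_ops(n, circular)

    # bidirectional BFS on canonical states; raw representatives kept so that
    # the witness replays exactly
    dist_f = {canonical(src, circular): 0}
    dist_b = {canonical(tgt, circular): 0}
    parent_f = {canonical(src, circular): None}  # canon -> (parent_raw, op, raw)
    raw_f = {canonical(src, circular): src}
    raw_b = {canonical(tgt, circular): tgt}
    frontier_f = [src]
    frontier_b = [tgt]
    meet = None

    while meet is None:
        if not frontier_f and not frontier_b:
            raise SearchSpaceError("search exhausted without meeting")  # unreachable
        expand_forward = len(frontier_f) <= len(frontier_b)
        frontier = frontier_f if expand_forward else frontier_b
        dist_here = dist_f if expand_forward else dist_b
        dist_other = dist_b if expand_forward else dist_f
        new_frontier = []
        for raw in frontier:
            c0 = canonical(raw, circular)
            d0 = dist_here[c0]
            for op in ops:
                nxt = apply_op(raw, op, circular)
                c = canonical(nxt, circular)
                if c in dist_here:
                    continue
                dist_here[c] = d0 + 1
                if expand_forward:
                    parent_f[c] = (raw, op, nxt)
                    raw_f[c] = nxt
                else:
                    raw_b[c] = nxt
                new_frontier.append(nxt)
                if c in dist_other:
                    meet = c
                    break
            if meet is not None:
                break
        if expand_forward:
            frontier_f = new_frontier
        else:
            frontier_b = new_frontier
        if meet is None and not new_frontier:
            raise SearchSpaceError("state space exhausted")  # unreachable

    # forward half: source -> meet
    fwd_ops = []
    c = meet
    while parent_f.get(c) is not None:
        raw_parent, op, _ = parent_f[c]
        fwd_ops.append(op)
        c = canonical(raw_parent, circular)
    fwd_ops.reverse()

    # backward half: walk meet -> target greedily down dist_b
    ops_out = list(fwd_ops)
    cur = raw_f.get(meet, None)
    if cur is None:
        cur = src
        for op in ops_out:
            cur = apply_op(cur, op, circular)
    d = dist_b[meet]
    while d > 0:
        for op in ops:
            nxt = apply_op(cur, op, circular)
            c = canonical(nxt, circular)
            if dist_b.get(c, 99) == d - 1:
                ops_out.append(op)
                cur = nxt
                d -= 1
                break
        else:
            raise SearchSpaceError("witness reconstruction failed")  # unreachable
    return RearrangementScenario(op_count=len(ops_out), ops=ops_out)


def rearrangement_distance(
    source: BlockPermutation, target: BlockPermutation, max_blocks: int = 10
) -> int:
    """Minimum number of inversions+translocations between two genomes."""
    return min_rearrangement(source, target, max_blocks).op_count
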