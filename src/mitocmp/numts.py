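"""NUMT detection: anchor matching between nuclear and mitochondrial
sequences, chaining into insertion blocks, identity/p-distance and dating.

Anchors are maximal exact matches of length >= min_match (default 100 bp)
between a linear nuclear sequence and the circular mitogenome. Consecutive
anchors are chained into one NUMT block when they are co-oriented, closer
than ``chain_gap`` (default 500 bp) on the nuclear axis, and consistent in
order and orientation on the mitochondrial axis. Within a block, identity
and p-distance are computed columnwise over anchor-covered positions plus
inter-anchor spans of equal length on both axes; unequal-length (indel)
spans are excluded from the site counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .distances import R_MT_DEFAULT, R_NU_DEFAULT, DatingResult, numt_age
from .errors import ParameterError
from .genome import CircularGenome, Interval, merge_intervals
from .match import genome_matches


@dataclass
class NumtBlock:
    """A chained nuclear insertion of mitochondrial origin."""

    nuclear_id: str
    nuclear_interval: Interval
    mito_intervals: list[Interval]
    strand: str
    aligned_identity: float
    p_distance: float
    compared_sites: int
    differing_sites: int
    age: DatingResult
    n_anchors: int


def _signed_circular_gap(prev_end: int, next_start: int, L: int) -> int:
    """Signed shortest gap from prev_end forward to next_start on a circle."""
    gap = (next_start - prev_end) % L
    if gap > L // 2:
        gap -= L
    return gap


def scan_numts(
    nuclear: CircularGenome,
    mito: CircularGenome,
    min_match: int = 100,
    chain_gap: int = 500,
    r_nu: float = R_NU_DEFAULT,
    r_mt: float = R_MT_DEFAULT,
    min_block_len: int = 0,
) -> list[NumtBlock]:
    """Detect, chain and date NUMT blocks on one nuclear sequence.

    The nuclear record is treated as linear regardless of its flag; the
    mitochondrial side is circular-aware. ``min_block_len`` filters the
    returned blocks by nuclear footprint length (0 keeps everything).
    """
    if min_match < 20:
        raise ParameterError("min_match must be >= 20")
    if chain_gap < 0:
        raise ParameterError("chain_gap must be >= 0")
    nuc = CircularGenome(nuclear.id, nuclear.seq, is_circular=False)
    matches = genome_matches(nuc, mito, min_match, include_reverse=True)
    matches.sort(key=lambda m: (m.a_start, m.a_end()))
    Lm = mito.length

    chains: list[list] = []
    for m in matches:
        placed = False
        if chains:
            last = chains[-1][-1]
            nuc_gap = m.a_start - last.a_end()
            if m.strand == last.strand and -min_match < nuc_gap < chain_gap:
                if m.strand == "+":
                    mito_gap = _signed_circular_gap(last.b_end() % Lm,
                                                    m.b_start % Lm, Lm)
                else:
                    # '-' strand: mito coordinates run backwards along nucleus
                    mito_gap = _signed_circular_gap(m.b_end() % Lm,
                                                    last.b_start % Lm, Lm)
                if -min_match < mito_gap < chain_gap:
                    chains[-1].append(m)
                    placed = True
        if not placed:
            chains.append([m])

    blocks = []
    for chain in chains:
        block = _finish_block(chain, nuc, mito, r_nu, r_mt)
        if block.nuclear_interval.length >= min_block_len:
            blocks.append(block)
    return blocks


def _finish_block(chain, nuc: CircularGenome, mito: CircularGenome,
                  r_nu: float, r_mt: float) -> NumtBlock:
    Lm = mito.length
    compared = differing = 0
    for m in chain:
        compared += m.length  # anchors are exact matches
    for prev, nxt in zip(chain, chain[1:]):
        nuc_span = (prev.a_end(), nxt.a_start)
        if prev.strand == "+":
            mstart, mend = prev.b_end() % Lm, nxt.b_start % Lm
        else:
            mstart, mend = nxt.b_end() % Lm, prev.b_start % Lm
        mlen = (mend - mstart) % Lm
        nlen = nuc_span[1] - nuc_span[0]
        if nlen <= 0 or mlen != nlen:
            continue  # indel span: excluded from site counts
        nseq = nuc.seq[nuc_span[0] : nuc_span[1]]
        mseq = mito.fetch(Interval(mstart, mstart + mlen))
        if prev.strand == "-":
            from .genome import revcomp

            mseq = revcomp(mseq)
        for x, y in zip(nseq, mseq):
            if x == "N" or y == "N":
                continue
            compared += 1
            if x != y:
                differing += 1
    p = differing / compared if compared else 0.0
    return NumtBlock(
        nuclear_id=nuc.id,
        nuclear_interval=Interval(chain[0].a_start, chain[-1].a_end()),
        mito_intervals=[Interval(m.b_start, m.b_end(), m.strand) for m in chain],
        strand=chain[0].strand,
        aligned_identity=1.0 - p,
        p_distance=p,
        compared_sites=compared,
        differing_sites=differing,
        age=numt_age(p, r_nu, r_mt),
        n_anchors=len(chain),
    )


def numt_coverage_summary(blocks: list[NumtBlock], mito: CircularGenome) -> float:
    """Percent of the mitogenome represented among the blocks' anchors."""
    ivs = [iv for b in blocks for iv in b.mito_intervals]
    merged = merge_intervals(ivs, mito.length)
    return 100.0 * sum(iv.length for iv in merged) / mito.length


def numt_table(blocks: list[NumtBlock]) -> pd.DataFrame:
    """Per-block report; ages in MYA rounded to two decimals."""
    rows = [
        {
            "nuclear_id": b.nuclear_id,
            "nuc_start": b.nuclear_interval.start,
            "nuc_end": b.nuclear_interval.end,
            "strand": b.strand,
            "n_anchors": b.n_anchors,
            "compared_sites": b.compared_sites,
            "p_distance": round(b.p_distance, 6),
            "identity_pct": round(100.0 * b.aligned_identity, 2),
            "age_mya": round(b.age.t_mya, 2),
        }
        for b in blocks
    ]
    return pd.DataFrame(
        rows,
        columns=["nuclear_id", "nuc_start", "nuc_end", "strand", "n_anchors",
                 "compared_sites", "p_distance", "identity_pct", "age_mya"],
    )
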