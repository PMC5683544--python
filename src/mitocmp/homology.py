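"""Pairwise homology coverage, unique-segment calling, and the
genome-complexity-absence matrix.

The homology primitive is the maximal exact match of length >= ``min_anchor``
(default 30 bp, the sensitivity floor of a relaxed blastn search between
closely related mitogenomes). Coverage of a target genome by a query is the
merged union of anchor footprints on the target; unique segments are the
complement, filtered to a minimum length (default 100 bp: smaller gaps are
treated as noise, not as missing sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .genome import (
    CircularGenome,
    Interval,
    complement_intervals,
    merge_intervals,
)
from .match import genome_matches


@dataclass(frozen=True)
class MatchAnchor:
    """A maximal exact match between genome A and genome B."""

    a_interval: Interval
    b_interval: Interval
    strand: str
    length: int


@dataclass
class CoverageMap:
    """Merged homologous footprint of ``query_genome`` on ``target_genome``."""

    target_genome: str
    query_genome: str
    covered: list[Interval]
    covered_bases: int
    target_length: int


@dataclass
class UniqueSegment:
    """A target interval with no homolog of >= min_anchor in any query."""

    genome: str
    interval: Interval
    length: int
    absent_in: list[str]
    wraps_origin: bool = False


def find_anchors(
    a: CircularGenome, b: CircularGenome, min_anchor: int = 30
) -> list[MatchAnchor]:
    """All maximal exact matches >= min_anchor between two genomes.

    Both strands, circular-aware. Anchors whose footprints on both genomes
    are contained in another anchor of the same strand are deduplicated.
    """
    if min_anchor < 20:
        raise ParameterError("min_anchor must be >= 20")
    matches = genome_matches(a, b, min_anchor, include_reverse=True)
    anchors = [
        MatchAnchor(
            a_interval=Interval(m.a_start, m.a_end()),
            b_interval=Interval(m.b_start, m.b_end(), m.strand),
            strand=m.strand,
            length=m.length,
        )
        for m in matches
    ]
    return _drop_contained(anchors)


def _drop_contained(anchors: list[MatchAnchor]) -> list[MatchAnchor]:
    anchors = sorted(anchors, key=lambda x: (x.a_interval.start, -x.length))
    kept: list[MatchAnchor] = []
    for an in anchors:
        contained = False
        for other in kept:
            if (
                other.strand == an.strand
                and other.a_interval.start <= an.a_interval.start
                and an.a_interval.end <= other.a_interval.end
                and other.b_interval.start <= an.b_interval.start
                and an.b_interval.end <= other.b_interval.end
            ):
                contained = True
                break
        if not contained:
            kept.append(an)
    return kept


def coverage_of(
    target: CircularGenome, query: CircularGenome, min_anchor: int = 30
) -> CoverageMap:
    """Merged disjoint target intervals hit by any anchor against ``query``."""
    anchors = find_anchors(target, query, min_anchor)
    covered = merge_intervals((a.a_interval for a in anchors), target.length)
    return CoverageMap(
        target_genome=target.id,
        query_genome=query.id,
        covered=covered,
        covered_bases=sum(iv.length for iv in covered),
        target_length=target.length,
    )


def unique_segments(
    target: CircularGenome,
    queries: list[CircularGenome],
    min_anchor: int = 30,
    min_missing: int = 100,
) -> list[UniqueSegment]:
    """Target segments absent (no >= min_anchor exact homolog) from every query.

    The complement of the union coverage over all queries, filtered to
    length >= min_missing. A gap spanning the origin of a circular target
    is reported once, as a single wrapping segment.
    """
    if min_missing < 1:
        raise ParameterError("min_missing must be >= 1")
    all_cov = []
    for q in queries:
        all_cov.extend(coverage_of(target, q, min_anchor).covered)
    covered = merge_intervals(all_cov, target.length)
    gaps = complement_intervals(covered, target.length, circular=target.is_circular)
    out = []
    for gap in gaps:
        if gap.length < min_missing:
            continue
        out.append(
            UniqueSegment(
                genome=target.id,
                interval=gap,
                length=gap.length,
                absent_in=[q.id for q in queries],
                wraps_origin=gap.end > target.length,
            )
        )
    return out


def complexity_absence_matrix(
    genomes: list[CircularGenome],
    min_anchor: int = 30,
    min_missing: int = 100,
) -> pd.DataFrame:
    """Percentage of each genome's complexity that is absent in another.

    Entry ``M.loc[r, c]`` is 100 x (bases of genome ``c`` lying in unique
    segments relative to genome ``r``, after the min_missing filter) divided
    by the length of genome ``c``: the share of column genome ``c`` that row
    genome ``r`` has "lost". The diagonal is 0 and the matrix is generally
    asymmetric.
    """
    if len(genomes) < 2:
        raise ParameterError("need at least two genomes")
    ids = [g.id for g in genomes]
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for r in genomes:
        for c in genomes:
            if r.id == c.id:
                continue
            segs = unique_segments(c, [r], min_anchor, min_missing)
            missing = sum(s.length for s in segs)
            mat.loc[r.id, c.id] = 100.0 * missing / c.length
    return mat


def segments_bed(segments: list[UniqueSegment]) -> pd.DataFrame:
    """BED-like frame (0-based half-open); wrapping segments keep end > length."""
    rows = [
        {
            "genome": s.genome,
            "start": s.interval.start,
            "end": s.interval.end,
            "length": s.length,
            "wraps_origin": int(s.wraps_origin),
            "absent_in": ",".join(s.absent_in),
        }
        for s in segments
    ]
    return pd.DataFrame(
        rows, columns=["genome", "start", "end", "length", "wraps_origin", "absent_in"]
    )
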