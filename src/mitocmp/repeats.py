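"""Dispersed repeat detection and size classification within one mitogenome.

The primitive is the maximal exact repeat: a pair of distinct genome
intervals carrying identical sequence (forward or reverse-complement) that
cannot be extended on both sides simultaneously. Pairwise matches sharing a
copy interval are clustered into repeat families; large plant mitochondrial
repeats (>= 1 kb) are the recombination substrate of interest, so families
are classified into large / medium / small size classes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .genome import CircularGenome, Interval
from .match import PairMatch, self_matches

SIZE_LARGE = "large"    # unit_length >= 1000 bp
SIZE_MEDIUM = "medium"  # 100..999 bp
SIZE_SMALL = "small"    # < 100 bp


def size_class(unit_length: int) -> str:
    if unit_length >= 1000:
        return SIZE_LARGE
    if unit_length >= 100:
        return SIZE_MEDIUM
    return SIZE_SMALL


@dataclass
class RepeatFamily:
    """A set of >= 2 identical genome intervals (exact-repeat mode).

    ``copies`` hold canonical forward-coordinate intervals; a copy's strand
    is its orientation relative to the first (leftmost) copy. ``identity``
    is 1.0 in exact mode.
    """

    copies: list[Interval]
    unit_length: int
    identity: float = 1.0

    @property
    def size_class(self) -> str:
        return size_class(self.unit_length)

    @property
    def n_copies(self) -> int:
        return len(self.copies)


def maximal_repeat_matches(
    g: CircularGenome, min_len: int, include_reverse: bool = True
) -> list[PairMatch]:
    """All maximal exact repeat pairs within ``g`` (low-level interface).

    Exposed separately from :func:`find_maximal_repeats` so that the raw
    pairwise match set can be compared against independent oracles.
    """
    if min_len < 8:
        raise ParameterError("min_len must be >= 8")
    return self_matches(g, min_len, include_reverse)


def find_maximal_repeats(
    g: CircularGenome, min_len: int = 1000, include_reverse: bool = True
) -> list[RepeatFamily]:
    """Detect maximal exact repeat families of unit length >= min_len.

    Pairwise maximal matches are clustered into families by shared copy
    intervals (identical start and length); all copies of a family
    therefore have the same unit length. Families are reported with copies
    in leftmost-start order, families sorted by descending unit length then
    leftmost copy.
    """
    matches = maximal_repeat_matches(g, min_len, include_reverse)
    # union-find over copy nodes (start, length); edges labelled by relative
    # orientation so each copy gets a strand w.r.t. its family's first copy
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    edges = []
    for m in matches:
        na = (m.a_start, m.length)
        nb = (m.b_start, m.length)
        union(na, nb)
        edges.append((na, nb, m.strand))

    adj = defaultdict(list)
    for na, nb, strand in edges:
        adj[na].append((nb, strand))
        adj[nb].append((na, strand))

    groups = defaultdict(list)
    for node in parent:
        groups[find(node)].append(node)

    families = []
    for nodes in groups.values():
        nodes.sort()
        # orient copies relative to the leftmost copy by BFS over match edges
        orient = {nodes[0]: "+"}
        stack = [nodes[0]]
        while stack:
            cur = stack.pop()
            for nxt, strand in adj[cur]:
                rel = orient[cur] if strand == "+" else ("-" if orient[cur] == "+" else "+")
                if nxt not in orient:
                    orient[nxt] = rel
                    stack.append(nxt)
        copies = [Interval(s, s + ln, orient[(s, ln)]) for s, ln in nodes]
        families.append(RepeatFamily(copies=copies, unit_length=nodes[0][1]))
    families.sort(key=lambda f: (-f.unit_length, f.copies[0].start))
    return families


def classify_and_count(families: list[RepeatFamily]) -> dict[str, int]:
    """Counts of repeat families per size class (large / medium / small)."""
    counts = {SIZE_LARGE: 0, SIZE_MEDIUM: 0, SIZE_SMALL: 0}
    for f in families:
        counts[f.size_class] += 1
    return counts


def repeat_table(
    genomes: list[CircularGenome], min_len: int = 1000, include_reverse: bool = True
) -> pd.DataFrame:
    """Per-genome large-repeat unit lengths, sorted descending.

    One row per repeat family with columns genome, rank, unit_length,
    n_copies, size_class.
    """
    if not genomes:
        raise ParameterError("repeat_table needs at least one genome")
    rows = []
    for g in genomes:
        fams = find_maximal_repeats(g, min_len, include_reverse)
        for rank, f in enumerate(sorted(fams, key=lambda f: -f.unit_length), 1):
            rows.append(
                {
                    "genome": g.id,
                    "rank": rank,
                    "unit_length": f.unit_length,
                    "n_copies": f.n_copies,
                    "size_class": f.size_class,
                }
            )
    return pd.DataFrame(rows, columns=["genome", "rank", "unit_length", "n_copies", "size_class"])


def family_tsv(genome_id: str, families: list[RepeatFamily]) -> pd.DataFrame:
    """Long-format copy table: genome, family_id, copy coordinates, strand."""
    rows = []
    for fid, f in enumerate(families, 1):
        for c in f.copies:
            rows.append(
                {
                    "genome": genome_id,
                    "family_id": fid,
                    "copy_start": c.start,
                    "copy_end": c.end,
                    "strand": c.strand,
                    "unit_length": f.unit_length,
                    "size_class": f.size_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genome", "family_id", "copy_start", "copy_end", "strand",
                 "unit_length", "size_class"],
    )
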