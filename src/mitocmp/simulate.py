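"""Synthetic genome evolution with known ground truth.

Generates ancestral circular mitogenomes (i.i.d. composition at a target
GC), plants dispersed repeat families, evolves derived genomes through
inversions, translocations, insertions, deletions and substitution epochs,
and builds nuclear chromosomes carrying mitochondrial insertions (NUMTs)
diverged for a known time under the two-rate model. Every event's ground
truth is recorded so pipeline stages can be validated without any external
data.

Structural events operate on non-wrapping coordinates (rotate the genome
first if an event must cross the origin). Substitutions are i.i.d. across
sites, uniform over the three alternative bases, with no rate
heterogeneity or indel model, matching the homogeneous-rate assumption of
the dating formula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distances import R_MT_DEFAULT, R_NU_DEFAULT
from .errors import ParameterError, PlacementError
from .genome import CircularGenome, GeneAnnotation, Interval, revcomp
from .repeats import RepeatFamily

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_dna(length: int, gc: float, rng) -> str:
    """i.i.d. DNA with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    if length <= 0:
        raise ParameterError("length must be positive")
    if not 0 < gc < 1:
        raise ParameterError("gc must be in (0, 1)")
    rng = _rng(rng)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    draws = rng.choice(4, size=length, p=probs)
    return _BASES[draws].tobytes().decode("ascii")


def generate_ancestor(
    length: int, gc: float = 0.449, seed=0, genome_id: str = "ancestor"
) -> CircularGenome:
    """Random circular ancestor; reproducible under ``seed``."""
    return CircularGenome(genome_id, random_dna(length, gc, _rng(seed)))


def plant_repeat(
    g: CircularGenome,
    size: int,
    positions: list[int],
    orientations: list[str] | None = None,
    rng=0,
    gc: float | None = None,
) -> tuple[CircularGenome, RepeatFamily]:
    """Overwrite identical copies of a random unit at the given positions.

    Copies (with a one-base margin used to pin down maximality of the
    planted unit) must not overlap each other or run off the molecule.
    Returns the modified genome and the ground-truth repeat family.
    """
    if size <= 0:
        raise PlacementError("repeat size must be positive")
    if len(positions) < 2:
        raise PlacementError("a repeat family needs at least two copies")
    if len(positions) > 4:
        raise PlacementError("at most four copies per planted family "
                             "(distinct flanking letters pin maximality)")
    orientations = orientations or ["+"] * len(positions)
    if len(orientations) != len(positions):
        raise PlacementError("positions and orientations must align")
    rng = _rng(rng)
    L = g.length
    spans = sorted((p - 1, p + size + 1) for p in positions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise PlacementError("planted repeat copies overlap")
    if spans[0][0] < 0 or spans[-1][1] > L:
        raise PlacementError("repeat copy (plus margin) outside the genome")

    unit = random_dna(size, gc if gc is not None else g.gc_content, rng)
    seq = list(g.seq)
    for pos, orient in zip(positions, orientations):
        copy = unit if orient == "+" else revcomp(unit)
        seq[pos : pos + size] = copy
    # pin maximal extension to exactly `size`: give each copy distinct
    # flanking bases (left flanks mutually distinct, right flanks too,
    # respecting orientation so extension fails on every copy pair)
    letters = "ACGT"
    for k, (pos, orient) in enumerate(zip(positions, orientations)):
        lpos, rpos = pos - 1, pos + size
        if orient == "+":
            seq[lpos] = letters[k]
            seq[rpos] = letters[k]
        else:
            seq[lpos] = revcomp(letters[k])
            seq[rpos] = revcomp(letters[k])
    out = CircularGenome(g.id, "".join(seq), g.is_circular, list(g.annotations))
    order = sorted(range(len(positions)), key=lambda i: positions[i])
    copies = [
        Interval(positions[i], positions[i] + size, orientations[i]) for i in order
    ]
    # express orientations relative to the leftmost copy
    ref = copies[0].strand
    copies = [
        Interval(c.start, c.end, "+" if c.strand == ref else "-") for c in copies
    ]
    return out, RepeatFamily(copies=copies, unit_length=size)


def _shift_annotations(anns, pivot: int, delta: int, drop_span=None):
    out = []
    for a in anns:
        if drop_span and not (a.end <= drop_span[0] or a.start >= drop_span[1]):
            continue  # feature destroyed by the deletion
        if a.start >= pivot:
            out.append(replace(a, start=a.start + delta, end=a.end + delta))
        else:
            out.append(a)
    return out


def insert_segment(
    g: CircularGenome, pos: int, seq: str
) -> CircularGenome:
    """Insert novel sequence at ``pos`` (0..length), shifting annotations."""
    if not 0 <= pos <= g.length:
        raise PlacementError(f"insertion position {pos} out of range")
    new_seq = g.seq[:pos] + seq.upper() + g.seq[pos:]
    anns = _shift_annotations(g.annotations, pos, len(seq))
    return CircularGenome(g.id, new_seq, g.is_circular, anns)


def delete_segment(g: CircularGenome, start: int, end: int) -> CircularGenome:
    """Delete [start, end); annotations inside are dropped, later ones shift."""
    if not (0 <= start < end <= g.length):
        raise PlacementError(f"deletion ({start}, {end}) out of range")
    new_seq = g.seq[:start] + g.seq[end:]
    anns = _shift_annotations(g.annotations, end, start - end, drop_span=(start, end))
    return CircularGenome(g.id, new_seq, g.is_circular, anns)


def invert_segment(g: CircularGenome, start: int, end: int) -> CircularGenome:
    """Reverse-complement [start, end); contained annotations are remapped,
    annotations straddling a boundary raise :class:`PlacementError`."""
    if not (0 <= start < end <= g.length):
        raise PlacementError(f"inversion ({start}, {end}) out of range")
    new_seq = g.seq[:start] + revcomp(g.seq[start:end]) + g.seq[end:]
    anns = []
    for a in g.annotations:
        if a.end <= start or a.start >= end:
            anns.append(a)
        elif start <= a.start and a.end <= end:
            ns = start + (end - a.end)
            anns.append(
                replace(a, start=ns, end=ns + a.length,
                        strand="-" if a.strand == "+" else "+")
            )
        else:
            raise PlacementError(f"gene {a.gene} straddles the inversion boundary")
    return CircularGenome(g.id, new_seq, g.is_circular, anns)


def translocate_segment(
    g: CircularGenome, start: int, end: int, dest: int, inverted: bool = False
) -> CircularGenome:
    """Move [start, end) so it starts at ``dest`` (post-removal coordinates)."""
    if not (0 <= start < end <= g.length):
        raise PlacementError(f"translocation source ({start}, {end}) out of range")
    seg = g.seq[start:end]
    rest = g.seq[:start] + g.seq[end:]
    if not 0 <= dest <= len(rest):
        raise PlacementError(f"translocation destination {dest} out of range")
    if inverted:
        seg = revcomp(seg)
    new_seq = rest[:dest] + seg + rest[dest:]
    seg_len = end - start
    anns = []
    for a in g.annotations:
        if start <= a.start and a.end <= end:  # rides along
            off = a.start - start
            if inverted:
                ns = dest + (seg_len - (a.end - start))
                anns.append(replace(a, start=ns, end=ns + a.length,
                                    strand="-" if a.strand == "+" else "+"))
            else:
                anns.append(replace(a, start=dest + off, end=dest + off + a.length))
        elif a.end <= start or a.start >= end:
            pos = a.start if a.start < start else a.start - seg_len
            pos = pos if pos < dest else pos + seg_len
            anns.append(replace(a, start=pos, end=pos + a.length))
        else:
            raise PlacementError(f"gene {a.gene} straddles the translocation")
    return CircularGenome(g.id, new_seq, g.is_circular, anns)


def substitution_epoch(
    g: CircularGenome, rate: float, years: float, rng=0
) -> tuple[CircularGenome, int]:
    """Apply i.i.d. substitutions at per-site probability ``rate * years``.

    Each hit site switches uniformly to one of the three other bases (N
    sites are left untouched). Returns the mutated genome and the number
    of substituted sites.
    """
    p = rate * years
    if p < 0 or p >= 1:
        raise ParameterError(f"per-site substitution probability {p} out of [0, 1)")
    rng = _rng(rng)
    arr = np.frombuffer(g.seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero((rng.random(g.length) < p) & (arr != ord("N")))
    code = {65: 0, 67: 1, 71: 2, 84: 3}
    for i in hit:
        cur = code[arr[i]]
        arr[i] = _BASES[(cur + rng.integers(1, 4)) % 4]
    return CircularGenome(g.id, arr.tobytes().decode("ascii"),
                          g.is_circular, list(g.annotations)), len(hit)


def plant_genes(
    g: CircularGenome, n_genes: int, gene_length: int | None = None,
    prefix: str = "g",
) -> CircularGenome:
    """Attach ``n_genes`` evenly spaced annotations with alternating strands."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    spacing = g.length // n_genes
    glen = gene_length or max(1, min(900, spacing // 2))
    anns = []
    for i in range(n_genes):
        start = i * spacing
        anns.append(
            GeneAnnotation(
                gene=f"{prefix}{i + 1:02d}",
                start=start,
                end=start + glen,
                strand="+" if i % 2 == 0 else "-",
                genome_id=g.id,
            )
        )
    return CircularGenome(g.id, g.seq, g.is_circular, anns)


def apply_event(g: CircularGenome, event: dict, rng=0):
    """Dispatch one evolution event; returns (genome, truth record).

    Event kinds: ``insertion`` (pos, length | seq), ``deletion`` (start,
    end), ``inversion`` (start, end), ``translocation`` (start, end, dest,
    inverted), ``substitution_epoch`` (rate, years).
    """
    rng = _rng(rng)
    kind = event["kind"]
    if kind == "insertion":
        seq = event.get("seq") or random_dna(event["length"], 0.449, rng)
        out = insert_segment(g, event["pos"], seq)
        truth = {"kind": "insertion", "start": event["pos"],
                 "end": event["pos"] + len(seq), "length": len(seq)}
    elif kind == "deletion":
        out = delete_segment(g, event["start"], event["end"])
        truth = {"kind": "deletion", "start": event["start"],
                 "end": event["end"], "length": event["end"] - event["start"]}
    elif kind == "inversion":
        out = invert_segment(g, event["start"], event["end"])
        truth = {"kind": "inversion", "start": event["start"], "end": event["end"],
                 "length": event["end"] - event["start"]}
    elif kind == "translocation":
        out = translocate_segment(g, event["start"], event["end"],
                                  event["dest"], event.get("inverted", False))
        truth = {"kind": "translocation", "start": event["start"],
                 "end": event["end"], "length": event["end"] - event["start"]}
    elif kind == "substitution_epoch":
        out, n = substitution_epoch(g, event["rate"], event["years"], rng)
        truth = {"kind": "substitution_epoch", "start": -1, "end": -1, "length": n}
    else:
        raise ParameterError(f"unknown event kind {kind!r}")
    return out, truth


def _remap_truth(truth_rows: list[dict], event_truth: dict):
    """Shift previously planted segment coordinates through a new indel."""
    kind = event_truth["kind"]
    if kind == "insertion":
        pos, ln = event_truth["start"], event_truth["length"]
        for t in truth_rows:
            if t["start"] == -1:
                continue
            if t["start"] >= pos:
                t["start"] += ln
                t["end"] += ln
            elif t["start"] < pos < t["end"]:
                t["end"] += ln  # novel DNA inside a novel segment stays unique
    elif kind == "deletion":
        s, e = event_truth["start"], event_truth["end"]
        ln = e - s

        def remap(x):  # map a coordinate through the deletion
            if x <= s:
                return x
            if x >= e:
                return x - ln
            return s
        for t in truth_rows:
            if t["start"] == -1:
                continue
            t["start"], t["end"] = remap(t["start"]), remap(t["end"])
            t["length"] = t["end"] - t["start"]


@dataclass
class NumtSimulation:
    """A nuclear chromosome with one dated mitochondrial insertion."""

    nuclear: CircularGenome          # linear record
    mito_evolved: CircularGenome     # the extant mitogenome after t_years
    insert_interval: Interval        # footprint on the nuclear chromosome
    mito_interval: Interval          # source segment on the mitogenome
    t_years: float
    expected_p: float
    n_subs_nuclear: int
    n_subs_mito: int


def make_numt_chromosome(
    mito: CircularGenome,
    segment: Interval,
    t_years: float,
    r_nu: float = R_NU_DEFAULT,
    r_mt: float = R_MT_DEFAULT,
    flank_length: int = 10000,
    seed=0,
    nuclear_id: str = "chr_sim",
) -> NumtSimulation:
    """Simulate a NUMT insertion of known age.

    The nuclear copy of ``segment`` accumulates substitutions at ``r_nu``
    and the retained mitogenome at ``r_mt``, independently, for
    ``t_years``; expected pairwise p-distance is about
    ``t_years * (r_nu + r_mt)``. Random flanks surround the insert.
    """
    if t_years < 0:
        raise ParameterError("t_years must be >= 0")
    rng = _rng(seed)
    seg_seq = mito.fetch(segment)
    numt = CircularGenome("numt", seg_seq, is_circular=False)
    numt, n_nu = substitution_epoch(numt, r_nu, t_years, rng)
    mito_evolved, n_mt = substitution_epoch(mito, r_mt, t_years, rng)
    gc = mito.gc_content
    left = random_dna(flank_length, gc, rng) if flank_length else ""
    right = random_dna(flank_length, gc, rng) if flank_length else ""
    nuclear = CircularGenome(nuclear_id, left + numt.seq + right, is_circular=False)
    return NumtSimulation(
        nuclear=nuclear,
        mito_evolved=mito_evolved,
        insert_interval=Interval(len(left), len(left) + len(seg_seq)),
        mito_interval=segment,
        t_years=t_years,
        expected_p=t_years * (r_nu + r_mt),
        n_subs_nuclear=n_nu,
        n_subs_mito=n_mt,
    )


# ---------------------------------------------------------------------------
# scenario orchestration

#: Large-repeat unit lengths emulating a diploid-type cotton mitogenome
D_GROUP_REPEAT_SIZES = (12921, 12669, 10632, 9121, 8544, 7317)

#: Planted unique-insertion sizes: eight segments, 108-7888 bp, 18,194 bp total
D_GROUP_UNIQUE_SIZES = (108, 300, 600, 900, 1500, 2898, 4000, 7888)


@dataclass
class EvolutionScenario:
    """A reproducible ancestral genome plus derived-genome event programs."""

    seed: int = 0
    ancestor_length: int = 644395
    gc: float = 0.449
    planted_repeats: tuple = tuple((s, 2, "+-"[i % 2]) for i, s in
                                   enumerate(D_GROUP_REPEAT_SIZES))
    n_genes: int = 36
    derived: dict = field(default_factory=dict)  # id -> list of event dicts
    numt_events: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "ancestor_length": self.ancestor_length,
                "gc": self.gc,
                "planted_repeats": [list(r) for r in self.planted_repeats],
                "n_genes": self.n_genes,
                "derived": self.derived,
                "numt_events": self.numt_events,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvolutionScenario":
        d = json.loads(text)
        d["planted_repeats"] = tuple(tuple(r) for r in d.get("planted_repeats", []))
        return cls(**d)

    def run(self) -> "SimulationResult":
        rng = _rng(self.seed)
        anc = generate_ancestor(self.ancestor_length, self.gc, rng, "ancestor")
        anc = plant_genes(anc, self.n_genes)
        repeat_truth = []
        cursor = self.ancestor_length // 50
        for size, n_copies, orient in self.planted_repeats:
            positions = []
            for c in range(n_copies):
                positions.append(cursor)
                cursor += size + max(2000, size // 4)
            if cursor >= self.ancestor_length:
                raise PlacementError("scenario too crowded for planted repeats")
            orients = ["+"] + [orient] * (n_copies - 1)
            anc, fam = plant_repeat(anc, size, positions, orients, rng, self.gc)
            repeat_truth.append(fam)

        genomes = {"ancestor": anc}
        unique_truth: dict[str, list[dict]] = {}
        for gid, events in self.derived.items():
            g = CircularGenome(gid, anc.seq, True,
                              [replace(a, genome_id=gid) for a in anc.annotations])
            rows: list[dict] = []
            for ev in events:
                g, truth = apply_event(g, ev, rng)
                _remap_truth(rows, truth)
                if truth["kind"] in ("insertion", "deletion"):
                    rows.append(dict(truth, genome=gid))
            genomes[gid] = g
            unique_truth[gid] = rows

        numts = []
        for ev in self.numt_events:
            seg = Interval(ev["mito_start"], ev["mito_end"])
            numts.append(
                make_numt_chromosome(
                    anc, seg, ev["t_years"],
                    ev.get("r_nu", R_NU_DEFAULT), ev.get("r_mt", R_MT_DEFAULT),
                    ev.get("flank_length", 10000), rng,
                    ev.get("nuclear_id", f"chr_sim{len(numts) + 1}"),
                )
            )
        return SimulationResult(
            scenario=self,
            ancestor=anc,
            genomes=genomes,
            repeat_truth=repeat_truth,
            unique_truth=unique_truth,
            numts=numts,
        )


@dataclass
class SimulationResult:
    scenario: EvolutionScenario
    ancestor: CircularGenome
    genomes: dict[str, CircularGenome]
    repeat_truth: list[RepeatFamily]
    unique_truth: dict[str, list[dict]]
    numts: list[NumtSimulation]

    def unique_truth_table(self) -> pd.DataFrame:
        rows = [r for rows in self.unique_truth.values() for r in rows]
        return pd.DataFrame(
            rows, columns=["kind", "start", "end", "length", "genome"]
        )


def indel_trio_scenario(
    seed: int = 0,
    ancestor_length: int = 644395,
    insert_sizes: tuple = D_GROUP_UNIQUE_SIZES,
    small_insert: int = 80,
    divergence_p: float = 0.0004,
) -> EvolutionScenario:
    """Three-genome scenario for unique-segment recovery tests.

    ``derived_a`` carries novel insertions of ``insert_sizes`` (the
    diploid-type unique-segment size profile) plus one sub-threshold
    ``small_insert``; ``derived_b`` differs from the ancestor only by point
    substitutions at organelle-like divergence. Unique segments of
    ``derived_a`` against the other two should recover exactly the planted
    insertions of >= 100 bp.
    """
    sizes = list(insert_sizes) + [small_insert]
    n = len(sizes)
    events = []
    # spread insertion points over the ring, away from the repeat zone tail
    for i, size in enumerate(sizes):
        pos = ancestor_length // 2 + (i * ancestor_length // (4 * n))
        events.append({"kind": "insertion", "pos": pos, "length": size})
    events.append({"kind": "substitution_epoch", "rate": R_MT_DEFAULT,
                   "years": divergence_p / R_MT_DEFAULT / 2})
    return EvolutionScenario(
        seed=seed,
        ancestor_length=ancestor_length,
        derived={
            "derived_a": events,
            "derived_b": [
                {"kind": "substitution_epoch", "rate": R_MT_DEFAULT,
                 "years": divergence_p / R_MT_DEFAULT / 2}
            ],
        },
    )
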