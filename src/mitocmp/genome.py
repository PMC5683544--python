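"""Circular genome data model and flat-file I/O.

Coordinates are 0-based half-open everywhere inside the package. A feature
that spans the origin of a circular molecule is stored with ``end > length``
and interpreted modulo the genome length; :meth:`Interval.parts` splits such
an interval into at most two linear pieces for interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, FormatError

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a genome; ``end`` may exceed the genome length
    to encode an origin-spanning (wrapping) feature on a circular molecule."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise CoordinateError(f"empty or inverted interval ({self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise CoordinateError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def parts(self, genome_length: int) -> list["Interval"]:
        """Split into at most two non-wrapping linear intervals."""
        if self.length > genome_length:
            raise CoordinateError("interval longer than the genome")
        if not self.wraps(genome_length):
            return [self]
        out = [Interval(self.start, genome_length, self.strand)]
        if self.end - genome_length > 0:
            out.append(Interval(0, self.end - genome_length, self.strand))
        return out


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene feature on one genome (0-based half-open; wrap via end > length)."""

    gene: str
    start: int
    end: int
    strand: str
    genome_id: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> Interval:
        return Interval(self.start, self.end, self.strand)


@dataclass
class CircularGenome:
    """A named DNA molecule, circular by default.

    The sequence is stored uppercased over the alphabet {A, C, G, T, N}.
    """

    id: str
    seq: str
    is_circular: bool = True
    annotations: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"genome {self.id!r} has an empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc_content(self) -> float:
        """GC fraction computed over unambiguous (A/C/G/T) positions only."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        if acgt == 0:
            raise FormatError(f"genome {self.id!r} has no unambiguous bases")
        gc = self.seq.count("G") + self.seq.count("C")
        return gc / acgt

    def fetch(self, interval: Interval) -> str:
        """Sequence under an interval, following the wrap convention."""
        s = "".join(
            self.seq[p.start : p.end] for p in interval.parts(self.length)
        )
        if interval.strand == "-":
            s = revcomp(s)
        return s


def read_fasta(path, is_circular: bool = True) -> list[CircularGenome]:
    """Read a (multi-)FASTA file into :class:`CircularGenome` records.

    Sequences are uppercased; characters outside A/C/G/T/N raise
    :class:`FormatError`, as does an empty file.
    """
    genomes = [
        CircularGenome(id=rec.id, seq=str(rec.seq), is_circular=is_circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not genomes:
        raise FormatError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes: list[CircularGenome], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_annotation_table(
    path,
    one_based: bool | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> list[GeneAnnotation]:
    """Read a tab-separated annotation table.

    Required header columns: ``genome_id  gene  start  end  strand``.
    The file's coordinate convention is declared either by ``one_based``
    or by a comment line ``# coords: 1-based-inclusive`` /
    ``# coords: 0-based-half-open`` before the header; the default is
    0-based half-open. Rows with ``end <= start`` (after conversion) are
    interpreted as origin-spanning and stored with ``end`` shifted by the
    genome length, which requires ``genome_lengths``.
    """
    declared = None
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                token = line.lstrip("#").strip().lower()
                if token.startswith("coords:"):
                    conv = token.split(":", 1)[1].strip()
                    if conv.startswith("1"):
                        declared = True
                    elif conv.startswith("0"):
                        declared = False
                    else:
                        raise FormatError(f"unknown coordinate declaration {conv!r}")
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                continue
            rows.append(fields)
    if header is None:
        raise FormatError(f"no header line found in {path}")
    required = ["genome_id", "gene", "start", "end", "strand"]
    try:
        idx = {c: header.index(c) for c in required}
    except ValueError as e:
        raise FormatError(f"annotation table missing a required column: {e}") from e
    if one_based is None:
        one_based = bool(declared) if declared is not None else False

    out = []
    for fields in rows:
        genome_id = fields[idx["genome_id"]].strip()
        gene = fields[idx["gene"]].strip()
        start = int(fields[idx["start"]])
        end = int(fields[idx["end"]])
        strand = fields[idx["strand"]].strip()
        if one_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        length = genome_lengths.get(genome_id) if genome_lengths else None
        if length is not None and not (0 <= start < length):
            raise CoordinateError(
                f"{gene}: start {start} outside genome {genome_id} (length {length})"
            )
        if end <= start:
            if length is None:
                raise CoordinateError(
                    f"{gene}: end <= start needs genome_lengths to resolve the wrap"
                )
            end += length
        out.append(GeneAnnotation(gene, start, end, strand, genome_id))
    return out


def write_annotation_table(annotations: list[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("# coords: 0-based-half-open\n")
        fh.write("genome_id\tgene\tstart\tend\tstrand\n")
        for a in annotations:
            fh.write(f"{a.genome_id}\t{a.gene}\t{a.start}\t{a.end}\t{a.strand}\n")


def rotate_genome(g: CircularGenome, offset: int) -> CircularGenome:
    """Rotate a circular genome so that former position ``offset`` becomes 0.

    Annotations are shifted modulo the length; rotation by 0 is the identity.
    """
    if not g.is_circular:
        raise CoordinateError("cannot rotate a linear sequence")
    if not (0 <= offset < g.length):
        raise CoordinateError(f"offset {offset} out of range [0, {g.length})")
    if offset == 0:
        return replace(g, annotations=list(g.annotations))
    seq = g.seq[offset:] + g.seq[:offset]
    shifted = []
    for a in g.annotations:
        start = (a.start - offset) % g.length
        shifted.append(replace(a, start=start, end=start + a.length))
    return CircularGenome(id=g.id, seq=seq, is_circular=True, annotations=shifted)


def merge_intervals(intervals, genome_length: int) -> list[Interval]:
    """Merge intervals (wrap-aware) into sorted disjoint non-wrapping pieces.

    Output intervals are strand-less ('+'), sorted, disjoint, non-adjacent,
    and clipped to [0, genome_length).
    """
    parts = []
    for iv in intervals:
        ln = min(iv.length, genome_length)  # footprint of an over-wrapping match
        for p in Interval(iv.start % genome_length,
                          iv.start % genome_length + ln).parts(genome_length):
            parts.append((p.start, p.end))
    if not parts:
        return []
    parts.sort()
    merged = [list(parts[0])]
    for s, e in parts[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval(s, e) for s, e in merged]


def complement_intervals(covered: list[Interval], genome_length: int,
                         circular: bool = True) -> list[Interval]:
    """Complement of a merged, disjoint, sorted interval set.

    On a circular genome a complement gap that crosses the origin is returned
    as a single wrapping interval (end > genome_length).
    """
    if not covered:
        return [Interval(0, genome_length)]
    gaps = []
    for prev, nxt in zip(covered, covered[1:]):
        if nxt.start > prev.end:
            gaps.append(Interval(prev.end, nxt.start))
    head_open = covered[0].start > 0
    tail_open = covered[-1].end < genome_length
    if circular:
        if head_open or tail_open:
            start = covered[-1].end
            end = covered[0].start if head_open else 0
            if tail_open and head_open:
                gaps.append(Interval(start, end + genome_length))  # wraps
            elif tail_open:
                gaps.append(Interval(start, genome_length))
            else:
                gaps.insert(0, Interval(0, covered[0].start))
    else:
        if head_open:
            gaps.insert(0, Interval(0, covered[0].start))
        if tail_open:
            gaps.append(Interval(covered[-1].end, genome_length))
    return gaps
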