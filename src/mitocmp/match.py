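"""Maximal exact match engine.

Finds all maximal exact matches of length >= min_len between two DNA
sequences (or within one sequence), on both strands, with circular
molecules handled by scanning a doubled-sequence view. This is the shared
primitive behind repeat detection, pairwise homology anchoring and NUMT
scanning.

Method: every window of k = min(min_len, 31) bases is packed exactly into
a 64-bit integer (2 bits per base; windows containing N are invalidated,
so N never matches anything). Equal windows of the two sequences are
joined, and runs of seed hits that are consecutive along a diagonal
correspond one-to-one to exact matches of length >= k: a match of length
m contains exactly m - k + 1 consecutive seed positions. Candidates that
can still be extended by one base on either side (possible at doubled-view
truncation edges, where the untruncated twin of the match is found
elsewhere) are discarded by an O(1) maximality check, and duplicates
arising from the doubled view are removed by canonicalizing coordinates
modulo the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, ParameterError
from .genome import CircularGenome

MAX_SEED = 31  # 2 bits/base -> 62 bits, exact (collision-free) packing

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
_LUT[ord("N")] = 4
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as uint8 codes (A,C,G,T -> 0..3, N -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        raise FormatError("sequence contains characters outside A/C/G/T/N")
    return codes


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_CODE[codes][::-1]


@dataclass(frozen=True)
class PairMatch:
    """One maximal exact match.

    ``a_start``/``b_start`` are canonical 0-based starts on the forward
    strand of each molecule (intervals may wrap: start + length can exceed
    the molecule length on a circular genome). ``strand`` is the relative
    orientation: '-' means the a-segment equals the reverse complement of
    the b-segment.
    """

    a_start: int
    b_start: int
    length: int
    strand: str

    def a_end(self) -> int:
        return self.a_start + self.length

    def b_end(self) -> int:
        return self.b_start + self.length


def _window_keys(codes: np.ndarray, k: int):
    """Exact 2-bit packed keys for every k-window, plus validity (no N)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    c = codes.astype(np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        keys = (keys << np.uint64(2)) | c[i : i + n]
    bad = np.concatenate([[0], np.cumsum((codes >= 4).astype(np.int64))])
    valid = (bad[k:] - bad[:-k]) == 0
    return keys, valid


def _join_seeds(akeys, avalid, bkeys, bvalid, max_pairs=80_000_000):
    """All (a_pos, b_pos) pairs with equal valid window keys."""
    apos = np.flatnonzero(avalid)
    bpos = np.flatnonzero(bvalid)
    if len(apos) == 0 or len(bpos) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ak = akeys[apos]
    order = np.argsort(bkeys[bpos], kind="stable")
    bk_sorted = bkeys[bpos][order]
    bpos_sorted = bpos[order]
    left = np.searchsorted(bk_sorted, ak, side="left")
    right = np.searchsorted(bk_sorted, ak, side="right")
    cnt = right - left
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    if total > max_pairs:
        raise ParameterError(
            f"seed join would produce {total} pairs; raise min_len or mask "
            "low-complexity sequence"
        )
    arep = np.repeat(apos, cnt)
    run_starts = np.repeat(np.concatenate([[0], np.cumsum(cnt)[:-1]]), cnt)
    offsets = np.arange(total, dtype=np.int64) - run_starts
    brep = bpos_sorted[np.repeat(left, cnt) + offsets]
    return arep.astype(np.int64), brep.astype(np.int64)


def _diagonal_runs(arep, brep, k):
    """Collapse seed pairs into (a_start, b_start, length) diagonal runs."""
    if len(arep) == 0:
        return []
    d = brep - arep
    order = np.lexsort((arep, d))
    a = arep[order]
    dd = d[order]
    brk = np.flatnonzero((np.diff(dd) != 0) | (np.diff(a) != 1))
    starts = np.concatenate([[0], brk + 1])
    ends = np.concatenate([brk, [len(a) - 1]])
    return [
        (int(a[s]), int(a[s] + dd[s]), int(a[e] - a[s] + k))
        for s, e in zip(starts, ends)
    ]


def _char(codes: np.ndarray, L: int, i: int, circular: bool) -> int:
    """Code at position i with modular access; -1 if off a linear end."""
    if circular:
        return int(codes[i % L])
    if i < 0 or i >= L:
        return -1
    return int(codes[i])


def _collect(a_codes, b_codes, a_circ, b_circ, min_len, k, strand,
             self_mode, seen, out, max_pairs):
    """Run the seed pipeline for one strand and append maximal matches."""
    La, Lb = len(a_codes), len(b_codes)
    ad = np.concatenate([a_codes, a_codes]) if a_circ else a_codes
    bd = np.concatenate([b_codes, b_codes]) if b_circ else b_codes
    akeys, avalid = _window_keys(ad, k)
    bkeys, bvalid = _window_keys(bd, k)
    arep, brep = _join_seeds(akeys, avalid, bkeys, bvalid, max_pairs)
    if self_mode and strand == "+":
        keep = (brep - arep) % La != 0
        arep, brep = arep[keep], brep[keep]
    # A run can only saturate (wrap the full circle periodically) in
    # self-comparison or between equal-length circles; between circles of
    # different lengths an over-length run is a genuine maximal match whose
    # footprint wraps past the smaller circle, and is kept whole.
    cap = La if (self_mode or (a_circ and b_circ and La == Lb)) else None
    for a0, b0, ln in _diagonal_runs(arep, brep, k):
        saturated = False
        if cap is not None and ln > cap:
            ln = cap
            saturated = True
        if ln < min_len:
            continue
        if saturated:
            # full-circle match: canonical anchoring
            if self_mode:
                a0, b0 = 0, (b0 - a0) % La
            else:
                a0, b0 = (a0 - (b0 % Lb)) % La, 0
        else:
            a0 = a0 % La if a_circ else a0
            b0 = b0 % Lb if b_circ else b0
        if not saturated:
            ca = _char(a_codes, La, a0 - 1, a_circ)
            cb = _char(b_codes, Lb, b0 - 1, b_circ)
            if 0 <= ca < 4 and ca == cb:
                continue  # truncated duplicate; full match found elsewhere
            ca = _char(a_codes, La, a0 + ln, a_circ)
            cb = _char(b_codes, Lb, b0 + ln, b_circ)
            if 0 <= ca < 4 and ca == cb:
                continue
        key = (a0, b0, ln)
        if key in seen:
            continue
        seen.add(key)
        out.append((a0, b0, ln))


def maximal_matches(
    a_codes: np.ndarray,
    b_codes: np.ndarray | None,
    min_len: int,
    a_circular: bool,
    b_circular: bool,
    include_reverse: bool = True,
    max_pairs: int = 80_000_000,
) -> list[PairMatch]:
    """All maximal exact matches >= min_len between two encoded sequences.

    Pass ``b_codes=None`` for self-comparison (repeat search): identity
    diagonals are excluded, pairs are reported once with the leftmost copy
    first, and palindromic self-pairs (the same interval matching its own
    reverse complement) are dropped.
    """
    if min_len < 2:
        raise ParameterError("min_len must be >= 2")
    self_mode = b_codes is None
    if self_mode:
        b_codes = a_codes
        b_circular = a_circular
    La, Lb = len(a_codes), len(b_codes)
    k = min(min_len, MAX_SEED)
    if La < k or Lb < k:
        return []

    fwd: list[tuple] = []
    _collect(a_codes, b_codes, a_circular, b_circular, min_len, k, "+",
             self_mode, set(), fwd, max_pairs)
    matches = []
    seen_pairs = set()
    for a0, b0, ln in fwd:
        if self_mode:
            i, j = sorted((a0, b0))
            key = (i, j, ln, "+")
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            matches.append(PairMatch(i, j, ln, "+"))
        else:
            matches.append(PairMatch(a0, b0, ln, "+"))

    if include_reverse:
        rcb = revcomp_codes(b_codes)
        rev: list[tuple] = []
        _collect(a_codes, rcb, a_circular, b_circular, min_len, k, "-",
                 False, set(), rev, max_pairs)
        for a0, r0, ln in rev:
            b_start = (Lb - (r0 % Lb) - ln) % Lb if b_circular else Lb - r0 - ln
            if self_mode:
                if a0 == b_start:
                    continue  # exact palindrome: copy coincides with itself
                i, j = sorted((a0, b_start))
                key = (i, j, ln, "-")
                if key in seen_pairs:
                    continue
                seen_pairs.add(key)
                matches.append(PairMatch(i, j, ln, "-"))
            else:
                matches.append(PairMatch(a0, b_start, ln, "-"))
    return matches


def genome_matches(
    a: CircularGenome,
    b: CircularGenome,
    min_len: int,
    include_reverse: bool = True,
) -> list[PairMatch]:
    """Maximal exact matches between two genomes (circular-aware)."""
    return maximal_matches(
        encode(a.seq), encode(b.seq), min_len,
        a.is_circular, b.is_circular, include_reverse,
    )


def self_matches(
    g: CircularGenome, min_len: int, include_reverse: bool = True
) -> list[PairMatch]:
    """Maximal exact repeats (pairwise matches) within one genome."""
    return maximal_matches(
        encode(g.seq), None, min_len, g.is_circular, g.is_circular,
        include_reverse,
    )
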