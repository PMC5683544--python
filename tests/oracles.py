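"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use different algorithmic structure from the package:
repeat/homology oracles scan every diagonal (and anti-diagonal) of the
comparison matrix and read off maximal runs of equality; the rearrangement
oracle is a plain uni-directional BFS over raw signed permutations.
"""

from __future__ import annotations

import numpy as np

_CODE = {c: i for i, c in enumerate("ACGT")}
_CODE["N"] = 4
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


def _runs_from_bool(eq: np.ndarray, circular: bool):
    """Maximal runs of True; circular runs may wrap. Returns list or 'full'."""
    L = len(eq)
    if eq.all():
        return "full" if circular else [(0, L)]
    if not eq.any():
        return []
    if circular:
        starts = np.flatnonzero(eq & ~np.roll(eq, 1))
        out = []
        for s in starts:
            ln = 0
            while eq[(s + ln) % L]:
                ln += 1
            out.append((int(s), ln))
        return out
    d = np.diff(eq.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if eq[0]:
        starts.insert(0, 0)
    if eq[-1]:
        ends.append(L)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def oracle_self_matches(seq: str, min_len: int, circular: bool = True,
                        include_reverse: bool = True) -> set[tuple]:
    """All maximal exact repeat pairs as (start_a, start_b, length, strand),
    with start_a <= start_b, palindromic self-pairs excluded."""
    arr = _enc(seq)
    L = len(arr)
    valid = arr != 4
    out: set[tuple] = set()
    for d in range(1, L):
        if circular:
            other = np.roll(arr, -d)
            eq = (arr == other) & valid & (np.roll(valid, -d))
            rs = _runs_from_bool(eq, True)
            if rs == "full":
                out.add((0, d, L, "+"))
                continue
        else:
            eq = (arr[: L - d] == arr[d:]) & valid[: L - d] & valid[d:]
            rs = _runs_from_bool(eq, False)
        for s, ln in rs:
            if ln >= min_len:
                i, j = s, (s + d) % L if circular else s + d
                a, b = sorted((i, j))
                out.add((a, b, min(ln, L), "+"))
    if include_reverse:
        comp = _COMP[arr]
        compvalid = comp != 4
        crange = range(L) if circular else range(2 * L - 1)
        for c in crange:
            if circular:
                mirror = np.roll(comp[::-1], (c + 1) % L)
                mvalid = np.roll(compvalid[::-1], (c + 1) % L)
                eq = (arr == mirror) & valid & mvalid
                rs = _runs_from_bool(eq, True)
                if rs == "full":
                    rs = [(0, L)]
            else:
                xs = list(range(max(0, c - L + 1), min(L, c + 1)))
                flags = np.array(
                    [arr[x] == comp[c - x] and valid[x] and compvalid[c - x]
                     for x in xs], dtype=bool,
                )
                rs = [(xs[s], ln) for s, ln in _runs_from_bool(flags, False)]
            for s, ln in rs:
                if ln >= min_len:
                    i = s
                    j = (c - s - ln + 1) % L if circular else c - s - ln + 1
                    if i == j:
                        continue
                    a, b = sorted((i, j))
                    out.add((a, b, ln, "-"))
    return out


def oracle_cross_matches(seq_a: str, seq_b: str, min_len: int,
                         circular: bool = True) -> set[tuple]:
    """Maximal exact matches between two circular sequences, forward strand
    only, as (a_start, b_start, length); full-circle saturation follows the
    package's anchoring convention (b anchored at 0)."""
    a, b = _enc(seq_a), _enc(seq_b)
    La, Lb = len(a), len(b)
    assert circular, "oracle implemented for circular comparison"
    out: set[tuple] = set()
    ad = np.concatenate([a, a])
    bd = np.concatenate([b, b])
    n = min(2 * La, 2 * Lb)
    seen_diag_cells = set()
    for d in range(-(2 * La) + 1, 2 * Lb):
        lo_a, hi_a = max(0, -d), min(2 * La, 2 * Lb - d)
        if hi_a - lo_a < min_len:
            continue
        sl_a = ad[lo_a:hi_a]
        sl_b = bd[lo_a + d : hi_a + d]
        eq = (sl_a == sl_b) & (sl_a != 4) & (sl_b != 4)
        for s, ln in _runs_from_bool(eq, False):
            if ln < min_len:
                continue
            a0, b0 = lo_a + s, lo_a + s + d
            cap = La if La == Lb else None
            if cap is not None and ln > cap:
                out.add((int((a0 - (b0 % Lb)) % La), 0, cap))
                continue
            # drop truncated duplicates: extendable at either end
            if a[(a0 - 1) % La] == b[(b0 - 1) % Lb] and a[(a0 - 1) % La] != 4:
                continue
            if a[(a0 + ln) % La] == b[(b0 + ln) % Lb] and a[(a0 + ln) % La] != 4:
                continue
            out.add((a0 % La, b0 % Lb, ln))
    return out


# ---------------------------------------------------------------------------
# rearrangement oracle


def oracle_neighbors(state: tuple[int, ...], circular: bool):
    """All states one inversion or translocation away (raw, no canonicalization)."""
    n = len(state)
    out = set()
    for s in range(n):
        for l in range(1, n + 1):
            if not circular and s + l > n:
                continue
            idxs = [(s + i) % n for i in range(l)]
            st = list(state)
            vals = [st[i] for i in idxs][::-1]
            for i, v in zip(idxs, vals):
                st[i] = -v
            out.add(tuple(st))
    for s in range(n):
        for l in range(1, n):
            if not circular and s + l > n:
                continue
            idxs = [(s + i) % n for i in range(l)]
            picked = set(idxs)
            seg = [state[i] for i in idxs]
            rest = [state[i] for i in range(n) if i not in picked]
            for p in range(len(rest) + 1):
                out.add(tuple(rest[:p] + seg + rest[p:]))
                inv = [-x for x in reversed(seg)]
                out.add(tuple(rest[:p] + inv + rest[p:]))
    out.discard(state)
    return out


def oracle_distance_map(start: tuple[int, ...], circular: bool,
                        max_depth: int = 10) -> dict:
    """BFS distances from ``start`` to every reachable raw permutation."""
    from collections import deque

    dist = {start: 0}
    q = deque([start])
    while q:
        cur = q.popleft()
        if dist[cur] >= max_depth:
            continue
        for nxt in oracle_neighbors(cur, circular):
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                q.append(nxt)
    return dist
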