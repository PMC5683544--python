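"""Syntenic blocks and minimum inversion+translocation scenarios."""

import itertools

import pytest

from mitocmp import (
    BlockPermutation,
    GeneAnnotation,
    apply_op,
    gene_orders_from_annotations,
    min_rearrangement,
    rearrangement_distance,
    shared_blocks,
)
from mitocmp.errors import DecompositionError, SearchSpaceError
from mitocmp.gene_order import canonical

from oracles import oracle_distance_map, oracle_neighbors


def _perm(blocks, circular=True, name="p"):
    return BlockPermutation(name, tuple(blocks), circular=circular)


class TestSharedBlocks:
    def test_identical_orders_single_block(self):
        order = [(f"g{i}", "+") for i in range(10)]
        dec = shared_blocks({"a": order, "b": list(order)}, circular=True)
        assert len(dec.blocks) == 1
        assert dec.permutations["a"].blocks == (1,)

    def test_internal_inversion_three_blocks(self):
        ref = [("A", "+"), ("B", "+"), ("C", "+"), ("D", "+"), ("E", "+")]
        inv = [("A", "+"), ("B", "+"), ("D", "-"), ("C", "-"), ("E", "+")]
        dec = shared_blocks({"r": ref, "q": inv}, circular=False)
        assert dec.blocks == [["A", "B"], ["C", "D"], ["E"]]
        assert dec.permutations["r"].blocks == (1, 2, 3)
        assert dec.permutations["q"].blocks == (1, -2, 3)

    def test_missing_genes_dropped_with_warning(self):
        ref = [("A", "+"), ("B", "+"), ("C", "+")]
        other = [("A", "+"), ("C", "+")]
        with pytest.warns(UserWarning):
            dec = shared_blocks({"r": ref, "q": other}, circular=False)
        assert all("B" not in blk for blk in dec.blocks)

    def test_too_few_shared_genes(self):
        with pytest.raises(DecompositionError):
            shared_blocks({"r": [("A", "+")], "q": [("A", "+")]})

    def test_from_annotations_orders_by_start(self):
        anns = [
            GeneAnnotation("x", 500, 600, "+", "g1"),
            GeneAnnotation("y", 100, 200, "-", "g1"),
            GeneAnnotation("x", 10, 110, "+", "g2"),
            GeneAnnotation("y", 300, 400, "-", "g2"),
        ]
        orders = gene_orders_from_annotations(anns)
        assert orders["g1"] == [("y", "-"), ("x", "+")]
        assert orders["g2"] == [("x", "+"), ("y", "-")]

    def test_planted_blocks_recovered(self):
        # build a derived order from 8 blocks: invert two, move one
        blocks = [[f"b{b}g{i}" for i in range(3)] for b in range(8)]
        ref = [(g, "+") for blk in blocks for g in blk]
        # arrangement breaking every reference adjacency between blocks
        derived_blocks = [0, 2, 4, 6, 1, 7, 3, 5]
        derived = []
        for bi in derived_blocks:
            if bi in (2, 5):
                derived.extend((g, "-") for g in reversed(blocks[bi]))
            else:
                derived.extend((g, "+") for g in blocks[bi])
        dec = shared_blocks({"ref": ref, "der": derived}, circular=True)
        assert len(dec.blocks) == 8
        assert dec.permutations["ref"].blocks == tuple(range(1, 9))


class TestMinRearrangement:
    def test_identity_zero_ops(self):
        p = _perm([1, 2, 3, 4])
        assert rearrangement_distance(p, _perm([1, 2, 3, 4])) == 0

    def test_rotation_is_free_for_circular(self):
        p = _perm([1, 2, 3, 4, 5])
        q = _perm([3, 4, 5, 1, 2])
        assert rearrangement_distance(p, q) == 0

    @pytest.mark.parametrize("circular", [True, False])
    def test_every_single_inversion_is_distance_one(self, circular):
        n = 5
        identity = tuple(range(1, n + 1))
        p = _perm(identity, circular)
        seen = set()
        for s in range(n):
            for l in range(1, n + 1):
                if not circular and s + l > n:
                    continue
                op = {"type": "inversion", "start": s, "length": l}
                q = apply_op(identity, op, circular)
                key = canonical(q, circular)
                if key in seen or key == canonical(identity, circular):
                    continue
                seen.add(key)
                assert rearrangement_distance(p, _perm(q, circular)) == 1

    @pytest.mark.parametrize("circular", [True, False])
    def test_every_single_translocation_is_distance_one(self, circular):
        n = 5
        identity = tuple(range(1, n + 1))
        p = _perm(identity, circular)
        seen = set()
        for s in range(n):
            for l in range(1, n):
                if not circular and s + l > n:
                    continue
                for pp in range(n - l + (0 if circular else 1)):
                    for inv in (False, True):
                        op = {"type": "translocation", "start": s, "length": l,
                              "insert_at": pp, "inverted": inv}
                        q = apply_op(identity, op, circular)
                        key = canonical(q, circular)
                        if key in seen or key == canonical(identity, circular):
                            continue
                        seen.add(key)
                        assert rearrangement_distance(p, _perm(q, circular)) == 1

    def test_two_random_ops_at_most_two(self, rng):
        identity = tuple(range(1, 7))
        for trial in range(10):
            cur = identity
            for _ in range(2):
                s = int(rng.integers(0, 6))
                l = int(rng.integers(1, 6))
                cur = apply_op(cur, {"type": "inversion", "start": s, "length": l},
                               True)
            d = rearrangement_distance(_perm(identity), _perm(cur))
            assert d <= 2

    def test_witness_replays_to_target(self, rng):
        identity = tuple(range(1, 6))
        for trial in range(8):
            cur = identity
            for _ in range(int(rng.integers(1, 4))):
                s, l = int(rng.integers(0, 5)), int(rng.integers(1, 5))
                if trial % 2:
                    cur = apply_op(cur, {"type": "inversion", "start": s,
                                         "length": l}, True)
                else:
                    cur = apply_op(cur, {"type": "translocation", "start": s,
                                         "length": min(l, 4), "insert_at": 0,
                                         "inverted": bool(trial % 3)}, True)
            sc = min_rearrangement(_perm(identity), _perm(cur))
            replay = identity
            for op in sc.ops:
                replay = apply_op(replay, op, True)
            assert canonical(replay, True) == canonical(cur, True)
            assert sc.op_count == len(sc.ops)

    def test_symmetry(self, rng):
        a = _perm([1, -3, 2, 4])
        b = _perm([4, 2, -1, 3])
        assert rearrangement_distance(a, b) == rearrangement_distance(b, a)

    def test_triangle_inequality_sampled(self, rng):
        perms = []
        base = list(range(1, 5))
        for _ in range(4):
            vals = [int(v) * (1 if rng.random() < 0.5 else -1)
                    for v in rng.permutation(base)]
            perms.append(_perm(vals))
        for x, y, z in itertools.permutations(perms, 3):
            assert rearrangement_distance(x, z) <= (
                rearrangement_distance(x, y) + rearrangement_distance(y, z)
            )

    def test_search_space_guard(self):
        n = 12
        p = _perm(list(range(1, n + 1)))
        q = _perm(list(range(n, 0, -1)))
        with pytest.raises(SearchSpaceError):
            min_rearrangement(p, q)

    def test_block_set_mismatch(self):
        with pytest.raises(DecompositionError):
            min_rearrangement(_perm([1, 2, 3]), _perm([1, 2, -4, 3][:3]))


class TestOracleAgreement:
    @pytest.mark.parametrize("circular", [False, True])
    def test_all_signed_permutations_of_four(self, circular):
        identity = (1, 2, 3, 4)
        dist = oracle_distance_map(identity, circular, max_depth=4)
        src = _perm(identity, circular)
        for vals in itertools.permutations(range(1, 5)):
            for signs in itertools.product((1, -1), repeat=4):
                tgt = tuple(v * s for v, s in zip(vals, signs))
                oracle = min(
                    (dist[t] for t in dist
                     if canonical(t, circular) == canonical(tgt, circular)),
                    default=None,
                )
                assert oracle is not None
                got = rearrangement_distance(src, _perm(tgt, circular))
                assert got == oracle, (tgt, got, oracle)
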