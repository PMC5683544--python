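"""Synthetic-evolution generator: determinism, composition, ground truth."""

import numpy as np
import pytest

from mitocmp import (
    CircularGenome,
    GeneAnnotation,
    find_maximal_repeats,
    generate_ancestor,
    plant_genes,
    plant_repeat,
    unique_segments,
)
from mitocmp.errors import ParameterError, PlacementError
from mitocmp.simulate import (
    EvolutionScenario,
    apply_event,
    delete_segment,
    indel_trio_scenario,
    insert_segment,
    invert_segment,
    make_numt_chromosome,
    random_dna,
    substitution_epoch,
    translocate_segment,
)
from mitocmp.genome import Interval


class TestAncestor:
    def test_deterministic_under_seed(self):
        a = generate_ancestor(1000, 0.5, seed=42)
        b = generate_ancestor(1000, 0.5, seed=42)
        assert a.seq == b.seq
        assert generate_ancestor(1000, 0.5, seed=43).seq != a.seq

    def test_gc_within_binomial_bound(self):
        g = generate_ancestor(100_000, 0.449, seed=7)
        sd = np.sqrt(0.449 * 0.551 / 100_000)
        assert abs(g.gc_content - 0.449) < 3 * sd

    def test_exact_length(self):
        assert generate_ancestor(644_395, seed=1).length == 644_395

    def test_validation(self):
        with pytest.raises(ParameterError):
            random_dna(0, 0.5, 1)
        with pytest.raises(ParameterError):
            random_dna(10, 1.5, 1)


class TestPlantRepeat:
    def test_planted_unit_recovered_exactly(self, rng):
        g0 = CircularGenome("g", random_dna(30_000, 0.449, rng))
        g, fam = plant_repeat(g0, 10_246, [2000, 15_000], rng=rng)
        found = [f for f in find_maximal_repeats(g, 1000)
                 if f.unit_length == 10_246]
        assert len(found) == 1
        assert {c.start for c in found[0].copies} == {2000, 15_000}

    def test_inverted_copy_truth(self, rng):
        g0 = CircularGenome("g", random_dna(5000, 0.449, rng))
        g, fam = plant_repeat(g0, 500, [1000, 3000], ["+", "-"], rng=rng)
        assert [c.strand for c in fam.copies] == ["+", "-"]
        found = [f for f in find_maximal_repeats(g, 400)
                 if f.unit_length == 500]
        assert [c.strand for c in found[0].copies] == ["+", "-"]

    def test_zero_size_rejected(self, small_genome):
        with pytest.raises(PlacementError):
            plant_repeat(small_genome, 0, [10, 100])

    def test_overlap_rejected(self, small_genome):
        with pytest.raises(PlacementError):
            plant_repeat(small_genome, 500, [100, 300])


class TestEvents:
    def _annotated(self, rng, L=4000, n=8):
        return plant_genes(CircularGenome("g", random_dna(L, 0.45, rng)), n)

    def test_insertion_shifts_annotations(self, rng):
        g = self._annotated(rng)
        g2 = insert_segment(g, 600, "A" * 50)
        assert g2.length == g.length + 50
        before = [a for a in g.annotations if a.start < 600]
        after = [a for a in g.annotations if a.start >= 600]
        assert [a.start for a in g2.annotations][: len(before)] == [
            a.start for a in before
        ]
        assert [a.start + 50 for a in after] == [
            a.start for a in g2.annotations[len(before):]
        ]

    def test_deletion_drops_contained_genes(self, rng):
        g = self._annotated(rng)
        span = (g.annotations[2].start - 5, g.annotations[2].end + 5)
        g2 = delete_segment(g, *span)
        assert len(g2.annotations) == len(g.annotations) - 1
        assert g2.length == g.length - (span[1] - span[0])

    def test_inversion_flips_contained_gene(self, rng):
        g = self._annotated(rng)
        a = g.annotations[3]
        g2 = invert_segment(g, a.start - 10, a.end + 10)
        flipped = [x for x in g2.annotations if x.gene == a.gene][0]
        assert flipped.strand != a.strand
        assert g2.fetch(flipped.interval()) == g.fetch(a.interval())

    def test_inversion_straddle_rejected(self, rng):
        g = self._annotated(rng)
        a = g.annotations[3]
        with pytest.raises(PlacementError):
            invert_segment(g, a.start + 1, a.end + 50)

    def test_translocation_preserves_gene_sequence(self, rng):
        g = self._annotated(rng)
        a = g.annotations[5]
        g2 = translocate_segment(g, a.start - 5, a.end + 5, 100, inverted=True)
        moved = [x for x in g2.annotations if x.gene == a.gene][0]
        assert g2.fetch(moved.interval()) == g.fetch(a.interval())
        assert g2.length == g.length

    def test_substitution_epoch_rate(self, rng):
        g = CircularGenome("g", random_dna(100_000, 0.45, rng))
        p = 2e-10 * 1e6  # rate x years = 2e-4
        g2, n = substitution_epoch(g, 2e-10, 1e6, rng)
        sd = np.sqrt(p * (1 - p) * g.length)
        assert abs(n - p * g.length) < 4 * sd
        diffs = sum(x != y for x, y in zip(g.seq, g2.seq))
        assert diffs == n

    def test_apply_event_dispatch_unknown(self, small_genome):
        with pytest.raises(ParameterError):
            apply_event(small_genome, {"kind": "duplication"})


class TestNumtSimulation:
    def test_zero_age_identical_insert(self):
        mito = generate_ancestor(20_000, 0.449, seed=9, genome_id="m")
        sim = make_numt_chromosome(mito, Interval(500, 5500), 0.0, seed=1,
                                   flank_length=1000)
        assert sim.nuclear.seq[1000:6000] == mito.seq[500:5500]
        assert sim.expected_p == 0.0

    def test_expected_p_scales_with_age(self):
        mito = generate_ancestor(50_000, 0.449, seed=9, genome_id="m")
        sim = make_numt_chromosome(mito, Interval(0, 40_000), 1.03e6, seed=1)
        assert sim.expected_p == pytest.approx(0.0069, abs=1e-4)
        # realised divergence close to expectation
        from mitocmp.distances import p_distance

        numt = sim.nuclear.seq[10_000:50_000]
        native = sim.mito_evolved.seq[:40_000]
        p_obs = p_distance(numt, native)
        sd = np.sqrt(0.0069 * (1 - 0.0069) / 40_000)
        assert abs(p_obs - sim.expected_p) < 4 * sd


class TestScenario:
    def test_full_determinism(self):
        sc1 = indel_trio_scenario(seed=5, ancestor_length=60_000,
                                  insert_sizes=(150, 400), small_insert=80)
        sc1.planted_repeats = ((2000, 2, "+"),)
        sc2 = indel_trio_scenario(seed=5, ancestor_length=60_000,
                                  insert_sizes=(150, 400), small_insert=80)
        sc2.planted_repeats = ((2000, 2, "+"),)
        r1, r2 = sc1.run(), sc2.run()
        assert all(r1.genomes[k].seq == r2.genomes[k].seq for k in r1.genomes)

    def test_truth_consistent_with_emitted_sequences(self):
        sc = indel_trio_scenario(seed=11, ancestor_length=80_000,
                                 insert_sizes=(120, 700, 2500), small_insert=80)
        sc.planted_repeats = ((3000, 2, "+"), (1500, 2, "-"))
        res = sc.run()
        tgt = res.genomes["derived_a"]
        queries = [res.genomes["ancestor"], res.genomes["derived_b"]]
        called = unique_segments(tgt, queries)
        truth = [r for r in res.unique_truth["derived_a"]
                 if r["kind"] == "insertion" and r["length"] >= 100]
        assert len(called) == len(truth)
        for t in truth:
            hit = [s for s in called
                   if s.interval.start < t["end"] and t["start"] < s.interval.end]
            assert len(hit) == 1
            assert abs(hit[0].interval.start - t["start"]) <= 30
            assert abs(hit[0].interval.end - t["end"]) <= 30

    def test_scenario_json_roundtrip(self):
        sc = indel_trio_scenario(seed=3, ancestor_length=50_000,
                                 insert_sizes=(200,), small_insert=60)
        sc2 = EvolutionScenario.from_json(sc.to_json())
        assert sc2 == sc
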