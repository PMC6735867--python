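from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_hit, make_segment
from oracles import interval_union_footprints, pairwise_join_chains
from tnfoot.footprints import (Footprint, JoinCriteria, TransposaseUnit,
                               annotate_genome, assign_transposases,
                               build_footprints, filter_hits,
                               fraction_of_transposase, join_fragments,
                               segments_joinable)
from tnfoot.io import GenomeRecord, TransposaseProtein
from tnfoot.simulate import PlantSpec, ideal_hits, simulate_genome


class TestFilterHits:
    @pytest.mark.parametrize("evalue,kept", [
        (1e-5, True), (1e-3, False), (1e-4, True), (0.0, True),
    ])
    def test_threshold_is_inclusive(self, evalue, kept):
        hits = [make_hit(evalue=evalue)]
        assert (len(filter_hits(hits)) == 1) is kept

    def test_matches_brute_force_on_random_hits(self, rng):
        hits = [make_hit(evalue=float(10.0 ** rng.uniform(-8, 0)))
                for _ in range(100)]
        expected = [h for h in hits if h.evalue <= 1e-4]
        assert filter_hits(hits) == expected


class TestBuildFootprints:
    def test_overlapping_hits_merge(self):
        fps = build_footprints([make_hit(qstart=100, qend=400),
                                make_hit(qstart=350, qend=700)])
        assert [(f.start, f.end) for f in fps] == [(100, 700)]
        assert len(fps[0].hits) == 2

    def test_adjacent_hits_stay_separate(self):
        fps = build_footprints([make_hit(qstart=100, qend=400),
                                make_hit(qstart=401, qend=700)])
        assert [(f.start, f.end) for f in fps] == [(100, 400), (401, 700)]

    def test_no_hits_no_footprints(self):
        assert build_footprints([]) == []

    @given(st.lists(st.tuples(st.integers(1, 2000), st.integers(1, 300)),
                    min_size=0, max_size=60))
    def test_equals_interval_union_oracle(self, raw):
        hits = [make_hit(qstart=lo, qend=lo + span) for lo, span in raw]
        got = [(f.start, f.end) for f in build_footprints(hits)]
        assert got == interval_union_footprints(
            [(h.qstart, h.qend) for h in hits])

    def test_every_hit_inside_exactly_one_footprint(self, rng):
        hits = [make_hit(qstart=int(s), qend=int(s) + int(l))
                for s, l in zip(rng.integers(1, 3000, 80),
                                rng.integers(0, 400, 80))]
        fps = build_footprints(hits)
        for h in hits:
            owners = [f for f in fps if f.start <= h.qstart and h.qend <= f.end]
            assert len(owners) == 1
        # pairwise disjoint
        for a, b in zip(fps, fps[1:]):
            assert a.end < b.start or a.contig_id != b.contig_id


class TestAssignTransposases:
    def test_single_hit_covers_footprint(self):
        h = make_hit(qstart=100, qend=700, send=200)
        fp = build_footprints([h])[0]
        (seg,) = assign_transposases(fp)
        assert (seg.start, seg.end) == (100, 700)
        assert (seg.sstart, seg.send) == (1, 200)

    def test_greedy_cover_clips_second_best(self):
        a = make_hit(qstart=100, qend=500, bitscore=200.0, protein="A",
                     sstart=1, send=134)
        b = make_hit(qstart=450, qend=900, bitscore=150.0, protein="B",
                     sstart=1, send=150)
        fp = build_footprints([a, b])[0]
        segs = assign_transposases(fp)
        assert [(s.start, s.end, s.protein_id) for s in segs] == \
            [(100, 500, "A"), (501, 900, "B")]
        # clipped B lost 51 nt = 17 full codons off its 5' end
        assert segs[1].sstart == 1 + 17

    def test_tie_breaks_on_lexicographic_protein(self):
        a = make_hit(qstart=100, qend=500, bitscore=200.0, protein="Z")
        b = make_hit(qstart=100, qend=500, bitscore=200.0, protein="B")
        fp = build_footprints([a, b])[0]
        (seg,) = assign_transposases(fp)
        assert seg.protein_id == "B"

    def test_short_remainders_left_unassigned(self):
        a = make_hit(qstart=100, qend=500, bitscore=200.0)
        b = make_hit(qstart=480, qend=520, bitscore=50.0)
        fp = build_footprints([a, b])[0]
        segs = assign_transposases(fp, min_remainder=30)
        # remainder [501, 520] is 20 nt < 30: stays unassigned
        assert [(s.start, s.end) for s in segs] == [(100, 500)]

    def test_segments_never_overlap_nor_leave_footprint(self, rng):
        hits = [make_hit(qstart=int(s), qend=int(s) + int(l),
                         bitscore=float(b), protein=f"P{i % 7}")
                for i, (s, l, b) in enumerate(zip(
                    rng.integers(1, 2000, 60), rng.integers(30, 500, 60),
                    rng.integers(40, 400, 60)))]
        for fp in build_footprints(hits):
            segs = assign_transposases(fp)
            assert segs, "footprint with hits must receive >= 1 segment"
            for s in segs:
                assert fp.start <= s.start <= s.end <= fp.end
            for x, y in zip(segs, segs[1:]):
                assert x.end < y.start


class TestJoinFragments:
    def test_consecutive_plus_fragments_join(self):
        a = make_segment(start=1000, end=1449, sstart=1, send=150)
        b = make_segment(start=1950, end=2369, sstart=161, send=300)
        (unit,) = join_fragments([a, b])
        assert unit.joined and len(unit.fragments) == 2

    def test_opposite_strands_do_not_join(self):
        a = make_segment(start=1000, end=1449, sstart=1, send=150)
        b = make_segment(start=1460, end=1900, strand="-", sstart=151, send=300)
        units = join_fragments([a, b])
        assert [u.joined for u in units] == [False, False]

    def test_gap_over_1kb_does_not_join(self):
        a = make_segment(start=1000, end=1449, sstart=1, send=150)
        b = make_segment(start=2951, end=3400, sstart=151, send=300)
        assert len(join_fragments([a, b])) == 2

    def test_minus_strand_subject_order_reversed(self):
        # genomic left fragment carries the C-terminal part on '-'
        a = make_segment(start=1000, end=1449, strand="-", sstart=151, send=300)
        b = make_segment(start=1500, end=1949, strand="-", sstart=1, send=150)
        (unit,) = join_fragments([a, b])
        assert unit.joined

    def test_overlapping_segments_rejected(self):
        a = make_segment(start=1000, end=1500)
        b = make_segment(start=1400, end=1900)
        with pytest.raises(ValueError, match="overlapping"):
            join_fragments([a, b])

    def test_output_invariant_to_input_order(self, rng):
        segs = []
        pos = 100
        for i in range(20):
            length = int(rng.integers(60, 400))
            segs.append(make_segment(
                start=pos, end=pos + length,
                strand="+" if rng.integers(2) else "-",
                sstart=int(rng.integers(1, 200)),
                send=int(rng.integers(200, 400))))
            pos += length + int(rng.integers(1, 1500))
        perm = [segs[i] for i in rng.permutation(len(segs))]
        u1 = join_fragments(segs)
        u2 = join_fragments(perm)
        assert [(u.start, u.end, len(u.fragments)) for u in u1] == \
               [(u.start, u.end, len(u.fragments)) for u in u2]

    def test_chains_match_pairwise_oracle(self, rng):
        for _ in range(20):
            segs = []
            pos = 100
            for i in range(int(rng.integers(2, 15))):
                length = int(rng.integers(60, 500))
                strand = "+" if rng.integers(2) else "-"
                sstart = int(rng.integers(1, 300))
                segs.append(make_segment(
                    start=pos, end=pos + length, strand=strand,
                    sstart=sstart, send=sstart + length // 3))
                pos += length + int(rng.integers(1, 2000))
            got = [[(f.start, f.end) for f in u.fragments]
                   for u in join_fragments(segs)]
            exp = [[(f.start, f.end) for f in chain]
                   for chain in pairwise_join_chains(segs)]
            assert got == exp


class TestFraction:
    P300 = {"P": TransposaseProtein("P", "M" * 300)}

    def test_full_coverage_is_one(self):
        u = TransposaseUnit([make_segment(start=101, end=1000, protein="P")], 0)
        assert fraction_of_transposase(u, self.P300) == pytest.approx(1.0)

    def test_half_coverage(self):
        u = TransposaseUnit([make_segment(start=101, end=550, protein="P")], 0)
        assert fraction_of_transposase(u, self.P300) == pytest.approx(0.5)

    def test_joined_uses_shortest_originating_protein(self):
        prots = {"A": TransposaseProtein("A", "M" * 250),
                 "B": TransposaseProtein("B", "M" * 200)}
        u = TransposaseUnit([
            make_segment(start=101, end=400, protein="A", sstart=1, send=100),
            make_segment(start=600, end=839, protein="B", sstart=101, send=180),
        ], 0)
        assert fraction_of_transposase(u, prots) == pytest.approx((300 + 240) / 600)

    def test_unknown_protein_is_an_error(self):
        u = TransposaseUnit([make_segment(protein="nope")], 0)
        with pytest.raises(KeyError):
            fraction_of_transposase(u, self.P300)

    def test_monotone_in_coverage(self):
        fracs = [fraction_of_transposase(
            TransposaseUnit([make_segment(start=101, end=101 + n, protein="P")], 0),
            self.P300) for n in range(50, 900, 100)]
        assert fracs == sorted(fracs)

    def test_fraction_above_one_reported_not_clamped(self):
        prots = {"A": TransposaseProtein("A", "M" * 100),
                 "B": TransposaseProtein("B", "M" * 400)}
        u = TransposaseUnit([
            make_segment(start=101, end=400, protein="A", sstart=1, send=100),
            make_segment(start=600, end=1400, protein="B", sstart=90, send=356),
        ], 0)
        assert fraction_of_transposase(u, prots) > 1.0


class TestAnnotateGenome:
    def _one_plant(self, proteins, **kw):
        spec = PlantSpec("TNP_004", "c1", 3000, **kw)
        genome, truths, hits = simulate_genome(
            "g", {"c1": [spec]}, {"c1": 9000}, proteins, seed=11)
        return genome, truths, hits

    def test_full_length_plant_gives_one_full_unit(self, proteins):
        genome, _, hits = self._one_plant(proteins)
        units = annotate_genome(genome, hits, proteins)
        assert len(units) == 1
        assert 0.95 <= units[0].fraction <= 1.05

    def test_split_plant_within_1kb_joins(self, proteins):
        genome, _, hits = self._one_plant(
            proteins, planted_fraction=0.8, n_fragments=2, fragment_gaps=(400,))
        units = annotate_genome(genome, hits, proteins)
        assert len(units) == 1 and units[0].joined

    def test_split_plant_beyond_1kb_stays_two_units(self, proteins):
        genome, _, hits = self._one_plant(
            proteins, planted_fraction=0.8, n_fragments=2, fragment_gaps=(2000,))
        units = annotate_genome(genome, hits, proteins)
        assert len(units) == 2
        assert not any(u.joined for u in units)

    def test_hits_on_unknown_contig_rejected(self, proteins):
        genome = GenomeRecord("g", {"c1": "ACGT" * 100})
        with pytest.raises(ValueError, match="unknown contigs"):
            annotate_genome(genome, [make_hit(contig="cX")], proteins)
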