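from __future__ import annotations

import numpy as np
import pytest

from tnfoot.footprints import annotate_genome
from tnfoot.repeats import find_inverted_repeats
from tnfoot.search import six_frame_translate
from tnfoot.simulate import (CTAG_IR, PlantSpec, bundled_transposase_proteins,
                             generate_background, ideal_hits, plant_elements,
                             reverse_translate, simulate_genome, truth_table)


class TestBackground:
    def test_gc_concentrates_at_target(self):
        s = generate_background(10_000, 0.69, 42)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.69) <= 0.02

    def test_deterministic_for_fixed_seed(self):
        assert generate_background(500, 0.69, 7) == generate_background(500, 0.69, 7)

    def test_mean_gc_over_replicates(self):
        gcs = [(lambda s: (s.count("G") + s.count("C")) / len(s))(
            generate_background(2000, 0.5, seed)) for seed in range(30)]
        assert abs(np.mean(gcs) - 0.5) <= 0.01

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0, 0.5)
        with pytest.raises(ValueError):
            generate_background(10, 1.5)


class TestReverseTranslate:
    def test_unique_codon(self):
        assert reverse_translate("M", 0) == "ATG"

    def test_round_trip_on_random_proteins(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for i in range(20):
            prot = "".join(rng.choice(list(aas), size=int(rng.integers(2, 80))))
            nt = reverse_translate(prot, i)
            aa, _ = six_frame_translate(nt + "AAA")[1]
            assert aa[:len(prot)] == prot

    def test_bundled_proteins_round_trip(self, proteins):
        for i, p in enumerate(proteins.values()):
            nt = reverse_translate(p, i)
            aa, _ = six_frame_translate(nt)[1]
            assert aa == p.sequence


class TestPlantElements:
    def test_full_length_plant_coordinates(self, proteins):
        p = proteins["TNP_001"]
        bg = generate_background(5000, 0.69, 1)
        spec = PlantSpec("TNP_001", "c1", 2000)
        contig, (truth,) = plant_elements(bg, [spec], proteins, 1)
        assert len(truth.fragments) == 1
        start, end, sa, sb = truth.fragments[0]
        assert end - start + 1 == p.nt_length
        assert (sa, sb) == (1, p.aa_length)
        assert len(contig) == 5000 + p.nt_length
        # planted piece translates back to the protein
        aa, _ = six_frame_translate(contig[start - 1:end])[1]
        assert aa == p.sequence

    def test_fragmented_plant_lengths(self, proteins):
        p = proteins["TNP_006"]
        bg = generate_background(6000, 0.69, 2)
        spec = PlantSpec("TNP_006", "c1", 3000, planted_fraction=0.5,
                         n_fragments=2, fragment_gaps=(400,))
        _, (truth,) = plant_elements(bg, [spec], proteins, 2)
        total = sum(e - s + 1 for s, e, _, _ in truth.fragments)
        assert abs(total - 0.5 * p.nt_length) <= 3
        (s1, e1, *_), (s2, e2, *_) = truth.fragments
        assert s2 - e1 - 1 == 400

    def test_minus_strand_fragment_order(self, proteins):
        bg = generate_background(6000, 0.69, 3)
        spec = PlantSpec("TNP_006", "c1", 3000, strand="-", planted_fraction=0.8,
                         n_fragments=2, fragment_gaps=(300,))
        _, (truth,) = plant_elements(bg, [spec], proteins, 3)
        (s1, e1, sa1, sb1), (s2, e2, sa2, sb2) = truth.fragments
        assert s1 < s2
        assert sa1 > sb2  # genomic left fragment carries the C-terminal part

    def test_ir_flanks_bracket_the_insert(self, proteins):
        bg = generate_background(4000, 0.69, 4)
        spec = PlantSpec("TNP_003", "c1", 1500, flank_with_ir=True)
        contig, (truth,) = plant_elements(bg, [spec], proteins, 4)
        start = truth.fragments[0][0]
        end = truth.fragments[-1][1]
        assert contig[start - 13:start - 1] == CTAG_IR
        assert contig[end:end + 12] == CTAG_IR
        pairs = find_inverted_repeats(contig)
        bracketing = [p for p in pairs
                      if p.arm1_end < start and p.arm2_start > end]
        assert bracketing, "flanking motif pair must be detectable"

    def test_overlapping_positions_rejected(self, proteins):
        bg = generate_background(4000, 0.69, 5)
        specs = [PlantSpec("TNP_001", "c1", 2000),
                 PlantSpec("TNP_002", "c1", 2000)]
        with pytest.raises(ValueError, match="strictly increasing"):
            plant_elements(bg, specs, proteins, 5)


class TestIdealHits:
    def test_full_length_hit_spans_protein(self, proteins):
        genome, truths, hits = simulate_genome(
            "g", {"c1": [PlantSpec("TNP_004", "c1", 2000)]}, {"c1": 7000},
            proteins, seed=6)
        (h,) = hits
        assert (h.sstart, h.send) == (1, proteins["TNP_004"].aa_length)
        assert h.evalue < 1e-4

    def test_fragment_hits_have_consecutive_subjects(self, proteins):
        _, truths, hits = simulate_genome(
            "g", {"c1": [PlantSpec("TNP_008", "c1", 2000, planted_fraction=0.9,
                                   n_fragments=3, fragment_gaps=(200, 500))]},
            {"c1": 9000}, proteins, seed=7)
        assert len(hits) == 3
        assert hits[0].send + 1 == hits[1].sstart
        assert hits[1].send + 1 == hits[2].sstart

    def test_truth_table_flattens_fragments(self, proteins):
        _, truths, _ = simulate_genome(
            "g", {"c1": [PlantSpec("TNP_008", "c1", 2000, planted_fraction=0.9,
                                   n_fragments=2, fragment_gaps=(200,))]},
            {"c1": 8000}, proteins, seed=8)
        df = truth_table(truths)
        assert len(df) == 2
        assert df.fragment_index.tolist() == [0, 1]


class TestEndToEnd:
    def test_generation_is_bit_reproducible(self, proteins):
        kw = dict(
            specs_by_contig={"c1": [PlantSpec("TNP_002", "c1", 2500,
                                              strand="-")]},
            contig_lengths={"c1": 8000}, proteins=proteins, seed=99)
        g1, t1, h1 = simulate_genome("g", **kw)
        g2, t2, h2 = simulate_genome("g", **kw)
        assert g1.contigs == g2.contigs
        assert [t.fragments for t in t1] == [t.fragments for t in t2]
        assert [(h.qstart, h.qend) for h in h1] == [(h.qstart, h.qend) for h in h2]

    def test_spaced_plants_recovered_one_unit_each(self, proteins):
        specs = [
            PlantSpec("TNP_001", "c1", 2000, planted_fraction=1.0),
            PlantSpec("TNP_004", "c1", 6000, strand="-", planted_fraction=0.6),
            PlantSpec("TNP_007", "c1", 10_000, planted_fraction=0.4,
                      n_fragments=2, fragment_gaps=(600,)),
        ]
        genome, truths, hits = simulate_genome(
            "g", {"c1": specs}, {"c1": 16_000}, proteins, seed=10)
        units = annotate_genome(genome, hits, proteins)
        assert len(units) == len(specs)
        for unit, spec in zip(units, specs):
            assert abs(unit.fraction - spec.planted_fraction) <= 0.05

    def test_wide_gaps_split_into_fragment_units(self, proteins):
        specs = [PlantSpec("TNP_009", "c1", 3000, planted_fraction=0.9,
                           n_fragments=3, fragment_gaps=(1500, 1500))]
        genome, _, hits = simulate_genome("g", {"c1": specs}, {"c1": 12_000},
                                          proteins, seed=11)
        units = annotate_genome(genome, hits, proteins)
        assert len(units) == 3
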