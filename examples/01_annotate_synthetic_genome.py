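"""Annotate a synthetic genome with planted transposase copies.

Builds one high-GC contig carrying a full-length copy, a 50% truncation on
the minus strand and a fragmented copy, derives the ideal hit table from
the planted truth, and runs the full annotation (filter -> footprints ->
assignment -> joining -> fractions).
"""

from tnfoot import annotate_genome
from tnfoot.simulate import PlantSpec, bundled_transposase_proteins, simulate_genome

proteins = bundled_transposase_proteins()
specs = [
    PlantSpec("TNP_002", "c1", 2000),                       # full length, +
    PlantSpec("TNP_005", "c1", 6000, strand="-",
              planted_fraction=0.5),                        # truncated, -
    PlantSpec("TNP_008", "c1", 10_000, planted_fraction=0.8,
              n_fragments=2, fragment_gaps=(400,)),         # fragmented
]
genome, truths, hits = simulate_genome(
    "demo", {"c1": specs}, {"c1": 16_000}, proteins, seed=42)

units = annotate_genome(genome, hits, proteins)
print(f"{len(units)} transposase units on {genome.total_length} bp:")
for u in units:
    print(f"  {u.contig_id}:{u.start}-{u.end} ({u.strand}) "
          f"protein={'|'.join(u.protein_ids)} joined={u.joined} "
          f"fraction={u.fraction:.3f}")

# Each planted element comes back as exactly one counted transposase ORF;
# the fraction estimates how complete the element is (1.0 = potentially
# transposition-capable, 0.5 = defective remnant). The two fragments of
# the third plant are 400 bp apart on one strand and match consecutive
# protein parts, so they are joined and counted once.
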