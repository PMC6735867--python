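"""Inverted-repeat screen delimiting a mobile region.

Plants a transposase copy flanked by the self-reverse-complementary motif
CTAGCTAGCTAG on both sides -- the structure of a mobile nod-gene region --
and shows the repeat screen (window 12, 92% identity per window, arm
distance 0-11,000 bp) finding the bracketing arms.
"""

from tnfoot.repeats import RepeatParams, find_inverted_repeats
from tnfoot.simulate import PlantSpec, bundled_transposase_proteins, simulate_genome

proteins = bundled_transposase_proteins()
spec = PlantSpec("TNP_004", "c1", 3000, flank_with_ir=True)
genome, (truth,), _ = simulate_genome("demo", {"c1": [spec]}, {"c1": 8000},
                                      proteins, seed=7)
contig = genome.contigs["c1"]
element_start = truth.fragments[0][0]
element_end = truth.fragments[-1][1]
print(f"planted element: c1:{element_start}-{element_end}")

pairs = find_inverted_repeats(contig, RepeatParams(), contig_id="c1")
for p in pairs:
    if p.arm1_end == element_start - 1 and p.arm2_start == element_end + 1:
        tag = "<- the planted flanking pair"
    elif p.arm1_end < element_start and p.arm2_start > element_end:
        tag = "(spans the element)"
    else:
        tag = ""
    print(f"  arms {p.arm1_start}-{p.arm1_end} / {p.arm2_start}-{p.arm2_end} "
          f"len={p.arm_length} identity={p.identity:.2f} "
          f"distance={p.distance} {tag}")

# The pair abutting the planted element is its flanking motif; exact
# 12-mer inverted matches also arise by chance in a few kb of high-GC
# background, which is why the screen is read together with the
# transposase annotation rather than alone.
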