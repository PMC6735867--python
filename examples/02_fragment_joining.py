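"""The three fragment-joining criteria, demonstrated on hand-built segments.

Two hit fragments are joined into one transposase unit only when they are
within 1 kb of each other, on the same strand, and match consecutive
(+/- 50 aa) parts of database transposases.
"""

from tnfoot.footprints import AssignedSegment, JoinCriteria, join_fragments
from tnfoot.io import TransposaseHit


def segment(start, end, strand, sstart, send):
    hit = TransposaseHit("c1", start, end, strand, "TNP_010", sstart, send,
                         1e-30, 200.0)
    return AssignedSegment("c1", start, end, strand, "TNP_010", sstart, send, hit)


cases = {
    "gap 500, same strand, consecutive": [
        segment(1000, 1449, "+", 1, 150), segment(1950, 2399, "+", 151, 300)],
    "gap 1500 (too far)": [
        segment(1000, 1449, "+", 1, 150), segment(2950, 3399, "+", 151, 300)],
    "opposite strands": [
        segment(1000, 1449, "+", 1, 150), segment(1500, 1949, "-", 151, 300)],
    "subject discontinuity 80 aa (non-consecutive)": [
        segment(1000, 1449, "+", 1, 150), segment(1500, 1949, "+", 231, 380)],
}

for label, segs in cases.items():
    units = join_fragments(segs, JoinCriteria())
    print(f"{label:48s} -> {len(units)} unit(s)")

# Only the first case forms a single joined unit; every other case counts
# the two fragments as two separate transposase ORFs.
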