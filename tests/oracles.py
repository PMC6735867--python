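"""Independent brute-force oracles the test suite checks the package against.

Each oracle re-derives its quantity from first principles with a different
algorithm than the implementation: set-based interval union for footprints,
full rank-split enumeration for the exact rank-sum p, a quadratic
affine-gap Smith-Waterman DP for local alignment scores, an all-pairs
window scan for inverted repeats, and a pairwise criteria matrix for
fragment chaining.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices


# ---------------------------------------------------------------------------
# interval union (footprints)
# ---------------------------------------------------------------------------

def interval_union_footprints(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Connected components of the interval-overlap graph, brute force.

    Two intervals are connected iff they share >= 1 position (adjacency is
    not overlap); each component spans [min start, max end].  O(n^2) edge
    enumeration plus union-find by repeated relabelling.
    """
    n = len(intervals)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(i + 1, n):
                (a_lo, a_hi), (b_lo, b_hi) = intervals[i], intervals[j]
                if max(a_lo, b_lo) <= min(a_hi, b_hi) and labels[i] != labels[j]:
                    new = min(labels[i], labels[j])
                    old = max(labels[i], labels[j])
                    labels = [new if l == old else l for l in labels]
                    changed = True
    comps: dict[int, list[tuple[int, int]]] = {}
    for lab, iv in zip(labels, intervals):
        comps.setdefault(lab, []).append(iv)
    out = [(min(lo for lo, _ in ivs), max(hi for _, hi in ivs))
           for ivs in comps.values()]
    return sorted(out)


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum by enumeration
# ---------------------------------------------------------------------------

def exact_wilcoxon_two_sided(a: list[float], b: list[float]) -> float:
    """Two-sided exact p: doubled smaller tail of the U null, capped at 1.

    Enumerates every C(n1+n2, n1) assignment of the pooled values to group
    A; assumes no ties.
    """
    pooled = sorted(a) + sorted(b)
    n1 = len(a)

    def u_stat(group_a: tuple[float, ...], group_b: tuple[float, ...]) -> int:
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(tuple(a), tuple(b))
    us = []
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        ga = tuple(pooled[i] for i in comb)
        gb = tuple(pooled[i] for i in idx if i not in comb)
        us.append(u_stat(ga, gb))
    us = np.array(us)
    lo_tail = np.mean(us <= u_obs)
    hi_tail = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(lo_tail, hi_tail)))


# ---------------------------------------------------------------------------
# affine-gap local alignment DP
# ---------------------------------------------------------------------------

def smith_waterman_affine(query: str, subject: str, gap_open: float = 11.0,
                          gap_extend: float = 1.0,
                          matrix_name: str = "BLOSUM62") -> float:
    """Maximum local alignment score; a gap of length k costs open + k*extend."""
    mat = substitution_matrices.load(matrix_name)
    nq, ns = len(query), len(subject)
    NEG = -math.inf
    M = [[0.0] * (ns + 1) for _ in range(nq + 1)]
    X = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in subject
    Y = [[NEG] * (ns + 1) for _ in range(nq + 1)]  # gap in query
    best = 0.0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            s = mat[query[i - 1], subject[j - 1]]
            X[i][j] = max(M[i - 1][j] - (gap_open + gap_extend),
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - (gap_open + gap_extend),
                          Y[i][j - 1] - gap_extend)
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


# ---------------------------------------------------------------------------
# inverted repeats: all-pairs window scan
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def brute_force_inverted_repeats(seq: str, window: int, min_identity: float,
                                 min_distance: int, max_distance: int
                                 ) -> list[tuple[int, int, int, int]]:
    """All maximal inverted-repeat pairs (1-based arm coordinates).

    Scans every ordered pair of window start positions, marks the pair
    valid when the upstream window matches the reverse complement of the
    downstream one with at most floor(window*(1-min_identity)) mismatches,
    walks each valid pair to its maximal extension, and applies the
    distance / non-overlap constraints to the maximal arms.
    """
    seq = seq.upper()
    w = window
    mm_allowed = int(w * (1.0 - min_identity))
    n = len(seq)
    nw = n - w + 1
    if nw < 1:
        return []
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.frombuffer(seq.translate(_COMP).encode(), dtype=np.uint8)
    # C[i, j'] = 1 iff seq[i] pairs with seq[j'] (Watson-Crick)
    C = (code[:, None] == comp[None, :])
    # window validity: V[i, j] = matches of seq[i:i+w] vs revcomp(seq[j:j+w])
    V = np.zeros((nw, nw), dtype=np.int16)
    for k in range(w):
        V += C[k:k + nw, w - 1 - k:w - 1 - k + nw]
    valid = V >= (w - mm_allowed)

    def is_valid(i: int, j: int) -> bool:
        return 0 <= i < nw and 0 <= j < nw and bool(valid[i, j])

    pairs = []
    seen = set()
    for i in range(nw):
        for j in range(i + 1, nw):
            if not valid[i, j]:
                continue
            if is_valid(i - 1, j + 1) and i - 1 < j + 1:
                continue  # not the start of a maximal run
            ii, jj = i, j
            while is_valid(ii + 1, jj - 1) and ii + 1 < jj - 1:
                ii, jj = ii + 1, jj - 1
            a1s, a1e = i, ii + w - 1
            a2s, a2e = jj, j + w - 1
            if (a1s, a2s) in seen:
                continue
            seen.add((a1s, a2s))
            if a2s <= a1e:
                continue
            dist = a2s - a1e - 1
            if not (min_distance <= dist <= max_distance):
                continue
            pairs.append((a1s + 1, a1e + 1, a2s + 1, a2e + 1))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# fragment joining: pairwise criteria matrix
# ---------------------------------------------------------------------------

def pairwise_join_chains(segments, max_gap_nt: int = 1000,
                         tolerance_aa: int = 50) -> list[list]:
    """Partition sorted segments into chains via an explicit n x n
    pairwise-criteria matrix, restated directly from the three criteria."""
    segs = sorted(segments, key=lambda s: (s.contig_id, s.start, s.end))
    n = len(segs)
    ok = [[False] * n for _ in range(n)]
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            a, b = segs[x], segs[y]
            if a.contig_id != b.contig_id or a.start > b.start:
                continue
            within_1kb = (b.start - a.end - 1) <= max_gap_nt
            same_strand = a.strand == b.strand
            if a.strand == "-" and b.strand == "-":
                consecutive = abs(a.sstart - b.send - 1) <= tolerance_aa
            else:
                consecutive = abs(b.sstart - a.send - 1) <= tolerance_aa
            ok[x][y] = within_1kb and same_strand and consecutive
    chains: list[list] = []
    for x in range(n):
        if chains and ok[x - 1][x] and segs[x - 1].contig_id == segs[x].contig_id:
            chains[-1].append(segs[x])
        else:
            chains.append([segs[x]])
    return chains
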