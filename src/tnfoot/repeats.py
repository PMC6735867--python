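"""Inverted-repeat detection under a sliding-window identity rule.

An inverted repeat is a pair of arms on one contig where one arm matches
the reverse complement of the other.  Detection follows a per-window rule:
every window of ``window`` bp within the paired arms must match its
reverse-complement counterpart with identity >= ``min_identity``.  With the
defaults (window 12, 92%) the integer mismatch budget per window is
floor(12 * 0.08) = 0, so arms are exact reverse-complement matches of
length >= 12; these settings delimit mobile regions bounded by short
self-reverse-complementary motifs such as CTAGCTAGCTAG.

Geometry: pairing arm1 position i+k with arm2 position j+L-1-k keeps
i + j' constant, so valid window pairs lie on anti-diagonals of the
complement-match matrix and maximal arms are maximal runs of consecutive
valid windows along one anti-diagonal.  The implementation seeds runs by
hashing forward k-mers against reverse-complement k-mers (exact-window
case) or scans anti-diagonals directly (mismatch-tolerant case); both
reduce to the same run semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io import revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class RepeatParams:
    """Window/identity/distance settings of the repeat screen."""

    window: int = 12
    min_identity: float = 0.92
    min_distance: int = 0
    max_distance: int = 11000
    inverted: bool = True

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("window must be >= 4")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if not (0 <= self.min_distance <= self.max_distance):
            raise ValueError("need 0 <= min_distance <= max_distance")
        if not self.inverted:
            raise NotImplementedError("only inverted-repeat search is provided")

    @property
    def max_mismatches_per_window(self) -> int:
        return int(self.window * (1.0 - self.min_identity))


@dataclass(frozen=True)
class InvertedRepeatPair:
    """Two same-length arms; arm2 reverse-complement-matches arm1.

    Coordinates are 1-based inclusive with arm1 upstream; ``distance`` is
    the exclusive gap between arm1_end and arm2_start (0 = abutting).
    """

    contig_id: str
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    identity: float

    @property
    def arm_length(self) -> int:
        return self.arm1_end - self.arm1_start + 1

    @property
    def distance(self) -> int:
        return self.arm2_start - self.arm1_end - 1

    def validate(self, params: RepeatParams) -> None:
        if self.arm_length != self.arm2_end - self.arm2_start + 1:
            raise ValueError("arm lengths differ")
        if self.arm_length < params.window:
            raise ValueError("arm shorter than window")
        if not (params.min_distance <= self.distance <= params.max_distance):
            raise ValueError("distance out of bounds")
        if self.identity < params.min_identity:
            raise ValueError("identity below threshold")


def _runs_to_pairs(contig_id: str, seq: str, runs: Iterator[tuple[int, int, int]],
                   params: RepeatParams) -> list[InvertedRepeatPair]:
    """Convert maximal (diag, i_first, i_last) window runs to repeat pairs.

    ``diag`` is i + j over 0-based window starts; a run covers windows
    i_first..i_last on arm1 and (diag - i_last)..(diag - i_first) on arm2.
    Pairs whose arms overlap (palindrome centres) or whose gap is out of
    bounds are suppressed.
    """
    w = params.window
    out = []
    for diag, i_first, i_last in runs:
        a1s, a1e = i_first, i_last + w - 1            # 0-based inclusive
        j_first = diag - i_last
        a2s, a2e = j_first, diag - i_first + w - 1
        if a2s <= a1e:  # overlapping arms
            continue
        dist = a2s - a1e - 1
        if not (params.min_distance <= dist <= params.max_distance):
            continue
        arm1 = seq[a1s:a1e + 1]
        arm2 = seq[a2s:a2e + 1]
        n_match = sum(c1 == c2 for c1, c2 in zip(arm1, revcomp(arm2)))
        identity = n_match / len(arm1)
        out.append(InvertedRepeatPair(
            contig_id=contig_id, arm1_start=a1s + 1, arm1_end=a1e + 1,
            arm2_start=a2s + 1, arm2_end=a2e + 1, identity=identity,
        ))
    out.sort(key=lambda p: (p.arm1_start, p.arm2_start))
    return out


def _merge_runs(valid_pairs: set[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Group valid (i, j) window pairs into maximal anti-diagonal runs."""
    by_diag: dict[int, list[int]] = {}
    for i, j in valid_pairs:
        by_diag.setdefault(i + j, []).append(i)
    runs = []
    for diag, starts in by_diag.items():
        starts.sort()
        first = prev = starts[0]
        for i in starts[1:]:
            if i == prev + 1:
                prev = i
            else:
                runs.append((diag, first, prev))
                first = prev = i
        runs.append((diag, first, prev))
    return runs


def _seed_exact(seq: str, w: int) -> set[tuple[int, int]]:
    """All (i, j) with i < j where seq[i:i+w] == revcomp(seq[j:j+w])."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        kmer = seq[i:i + w]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for j in range(len(seq) - w + 1):
        kmer = seq[j:j + w]
        if "N" in kmer:
            continue
        target = revcomp(kmer)
        for i in index.get(target, ()):
            if i < j:
                pairs.add((i, j))
    return pairs


def _valid_windows_scan(seq: str, params: RepeatParams) -> set[tuple[int, int]]:
    """Mismatch-tolerant valid-window enumeration via anti-diagonal scan.

    Builds the complement-match indicator along each anti-diagonal of the
    position-pair matrix and slides a window sum; quadratic in contig
    length, so reserved for mismatch budgets > 0 at desk scale.
    """
    w = params.window
    mm = params.max_mismatches_per_window
    n = len(seq)
    code = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_tab = np.zeros(256, dtype=np.uint8)
    for a, b in _COMP.items():
        comp_tab[ord(a)] = ord(b)
    comp = comp_tab[code]  # comp[j'] = complement of seq[j']
    pairs: set[tuple[int, int]] = set()
    # anti-diagonal D = i + j' of the char-match matrix; window (i, j)
    # uses char pairs (i+k, j+w-1-k), all with i + j' = i + j + w - 1.
    for D in range(2 * w - 1, 2 * n - 1):
        lo = max(0, D - n + 1)
        hi = min(D, n - 1)
        idx_i = np.arange(lo, hi + 1)
        match = (code[idx_i] == comp[D - idx_i]).astype(np.int32)
        if len(match) < w:
            continue
        sums = np.convolve(match, np.ones(w, dtype=np.int32), mode="valid")
        for off in np.nonzero(sums >= w - mm)[0]:
            i = lo + int(off)
            j = D - w + 1 - i
            if i < j:
                pairs.add((i, j))
    return pairs


def find_inverted_repeats(contig: str, params: RepeatParams = RepeatParams(),
                          contig_id: str = "contig") -> list[InvertedRepeatPair]:
    """Report every maximal inverted-repeat pair satisfying ``params``.

    Returns pairs ordered by (arm1_start, arm2_start), each reported once
    with arm1 upstream.  Contigs shorter than two windows yield an empty
    list.
    """
    seq = contig.upper()
    w = params.window
    if len(seq) < 2 * w:
        return []
    if params.max_mismatches_per_window == 0:
        valid = _seed_exact(seq, w)
    else:
        valid = _valid_windows_scan(seq, params)
    runs = _merge_runs(valid)
    return _runs_to_pairs(contig_id, seq, runs, params)
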