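from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tnfoot.footprints import AssignedSegment
from tnfoot.io import TransposaseHit
from tnfoot.simulate import bundled_transposase_proteins

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def proteins():
    return bundled_transposase_proteins()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_hit(contig="c1", qstart=100, qend=399, strand="+", protein="TNP_001",
             sstart=1, send=100, evalue=1e-10, bitscore=200.0,
             identity=100.0) -> TransposaseHit:
    return TransposaseHit(contig_id=contig, qstart=qstart, qend=qend,
                          strand=strand, protein_id=protein, sstart=sstart,
                          send=send, evalue=evalue, bitscore=bitscore,
                          identity_pct=identity)


def make_segment(contig="c1", start=100, end=399, strand="+",
                 protein="TNP_001", sstart=1, send=100) -> AssignedSegment:
    hit = make_hit(contig, start, end, strand, protein, sstart, send)
    return AssignedSegment(contig_id=contig, start=start, end=end,
                           strand=strand, protein_id=protein, sstart=sstart,
                           send=send, source_hit=hit)
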