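import numpy as np
import pytest

from cck3r.screen import ReferenceBindingDomains, Segment, SegmentSet


def make_segment_set(record_id: str, **role_residues: str) -> SegmentSet:
    """Build a SegmentSet from role=residues pairs, intervals laid end to end."""
    segments = []
    offset = 0
    for role in ("NTERM", "ECL1", "ECL2", "ECL3"):
        if role in role_residues:
            res = role_residues[role]
            segments.append(Segment(role, offset, offset + len(res), res))
            offset += len(res)
    return SegmentSet(record_id=record_id, segments=tuple(segments))


def make_reference(receptor_id: str, **role_residues: str) -> ReferenceBindingDomains:
    segs = make_segment_set(receptor_id, **role_residues)
    return ReferenceBindingDomains(receptor_id=receptor_id, segments=segs.segments)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
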