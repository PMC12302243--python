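import pytest

from repdeplete.airr_io import Rearrangement, RepertoireSample


def make_rec(
    sid,
    locus="TRB",
    v_call="TRBV1*01",
    j_call="TRBJ1*01",
    junction="ATGCATGCATGC",
    duplicate_count=1,
    productive=True,
    sequence=None,
    sequence_alignment=None,
    germline_alignment=None,
    **extras,
):
    return Rearrangement(
        sequence_id=sid,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        junction=junction,
        duplicate_count=duplicate_count,
        productive=productive,
        sequence=sequence if sequence is not None else junction,
        sequence_alignment=sequence_alignment,
        germline_alignment=germline_alignment,
        extras=extras,
    )


def make_sample(records, locus="TRB", **meta):
    return RepertoireSample(records=list(records), locus=locus, **meta)


@pytest.fixture
def trb_sample():
    """Three TRB records: two share a sequence, one differs."""
    return make_sample(
        [
            make_rec("r1", sequence="AAAACCCCGGGG"),
            make_rec("r2", sequence="AAAACCCCGGGG"),
            make_rec("r3", sequence="TTTTCCCCGGGG", junction="TTTTCCCCGGGG"),
        ]
    )
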