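import warnings

import numpy as np
import pytest

from immunorep.models import RearrangementRecord, SampleRepertoire

warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


def make_record(
    cdr3_nt="TGTGCCAGCAGCTTATTTTTT",
    sample_id="S1",
    locus="TRB",
    v_call="TRBV7-2*01",
    j_call="TRBJ2-1*01",
    read_count=1,
    sequence_id="r0",
    **kwargs,
):
    cdr3_aa = kwargs.pop("cdr3_aa", None)
    if cdr3_aa is None:
        from immunorep.airr_io import translate_cdr3

        cdr3_aa = translate_cdr3(cdr3_nt)
    return RearrangementRecord(
        sample_id=sample_id,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        read_count=read_count,
        sequence_id=sequence_id,
        **kwargs,
    )


def make_repertoire(records, sample_id="S1", library_reads=1_000_000):
    return SampleRepertoire(sample_id, list(records), library_reads)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def trb_repertoire():
    recs = [
        make_record(cdr3_nt="TGTGCCAGCAGCTTATTTTTT", read_count=5, sequence_id="a"),
        make_record(cdr3_nt="TGTGCCAGCAGCTTATTTTTC", read_count=3, sequence_id="b"),
        make_record(cdr3_nt="TGTCATCATCATCATCATTGG", read_count=2, sequence_id="c"),
    ]
    return make_repertoire(recs)
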