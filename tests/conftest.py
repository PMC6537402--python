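import numpy as np
import pytest

from bcrml.io_airr import SequenceRecord


def make_record(
    sequence_id="s1",
    patient_id="P000",
    tissue="normal",
    v_call="IGHV1",
    j_call="IGHJ1",
    cdr1_aa="GFTFSSYA",
    cdr2_aa="ISYDGSNK",
    cdr3_aa="AKDRGYSSGWYYFDY",
    cdr3_nt=None,
    duplicate_count=1,
    shm_fr=2,
    shm_cdr=1,
    clone_id=None,
):
    """A valid record with overridable fields; cdr3_nt defaults to a
    consistent back-translation-length filler."""
    if cdr3_nt is None:
        cdr3_nt = "GCT" * len(cdr3_aa)
    return SequenceRecord(
        sequence_id=sequence_id,
        patient_id=patient_id,
        tissue=tissue,
        v_call=v_call,
        j_call=j_call,
        cdr1_aa=cdr1_aa,
        cdr2_aa=cdr2_aa,
        cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt,
        duplicate_count=duplicate_count,
        shm_fr=shm_fr,
        shm_cdr=shm_cdr,
        clone_id=clone_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused by read-only tests."""
    from bcrml import simulate

    cfg = simulate.study_config(seed=7, n_patients=4, clones_per_tissue=50)
    return simulate.simulate_cohort(cfg)
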