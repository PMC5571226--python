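import numpy as np
import pytest

from cardioabs import beats, filters, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_record():
    """One synthetic subject with a mix of all generated classes."""
    return simulate.gen_record(42, 150, simulate.TRAIN_MIX)


@pytest.fixture(scope="session")
def train_records():
    """Three small donor records for library construction."""
    return [
        simulate.gen_record(100 + i, 180, simulate.TRAIN_MIX,
                            subject_id=f"donor{i}")
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def small_library(train_records):
    return filters.build_library(train_records)


@pytest.fixture(scope="session")
def monitored_record():
    """A 'healthy' subject: clean 5-minute prefix, then sparse ectopy."""
    return simulate.gen_record(
        777, 560, simulate.TEST_MIX, subject_id="person_x",
        normal_prefix_s=300.0,
    )


def spike_record(n=3000, r=1500, fs=360.0):
    """Zero signal with a unit spike annotated as one N beat."""
    sig = np.zeros(n)
    sig[r] = 1.0
    return beats.EcgRecord(
        subject_id="spike", signal=sig, fs=fs,
        annotations=[beats.BeatAnnotation(r, beats.AAMI.N)],
    )
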