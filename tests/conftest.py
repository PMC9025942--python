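import numpy as np
import pytest

from ecgscalonet.records import CLASSES, ECGRecord
from ecgscalonet.synthetic_ecg import SynthesisConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_config():
    """Short recordings (4096 samples ~ 32 s at 128 Hz) for fast pipelines."""
    return SynthesisConfig(duration_samples=4096)


@pytest.fixture(scope="session")
def small_dataset(short_config):
    """9 synthetic recordings (3 per class), short duration."""
    return generate_dataset(3, short_config, seed=11)


def make_record(samples, fs=128.0, label="NSR", record_id="r1"):
    return ECGRecord(record_id=record_id, samples=np.asarray(samples, float),
                     sampling_rate_hz=fs, label=label)


@pytest.fixture()
def toy_records():
    """Three tiny hand-made records, one per class."""
    rng = np.random.default_rng(0)
    return [
        make_record(rng.normal(size=1200), label=cls, record_id=f"toy-{cls}")
        for cls in CLASSES
    ]
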