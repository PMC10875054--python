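import numpy as np
import pytest

from sleepso.io import EEGRecording
from sleepso.synthetic import (
    SyntheticConfig,
    label_candidates,
    labeled_candidate_corpus,
    simulate_recording,
)

#: Short stage schedule used by most tests (problem size, not a default).
SHORT_BLOCKS = (("Wa", 3.0), ("N1", 3.0), ("N2", 5.0), ("N3", 5.0))


@pytest.fixture(scope="session")
def short_config() -> SyntheticConfig:
    return SyntheticConfig(stage_blocks=SHORT_BLOCKS, seed=0)


@pytest.fixture(scope="session")
def simulated(short_config):
    """One short simulated recording shared across tests."""
    return simulate_recording(short_config)


@pytest.fixture(scope="session")
def rater_labels(simulated):
    """Candidates of the shared recording with synthetic-rater tags."""
    from sleepso.events import extract_candidates, measure_all

    recording, truth, hypnogram = simulated
    cands, filtered = extract_candidates(recording)
    tags = label_candidates(cands, truth, fs=recording.sampling_rate)
    morphs = measure_all(cands, filtered)
    return cands, filtered, morphs, tags


@pytest.fixture(scope="session")
def corpus_small():
    """400-event fixed-length corpus for classifier/DTW tests."""
    return labeled_candidate_corpus(400, seed=3, resample_to=64)


def flat_recording(data: np.ndarray, fs: float = 500.0, name: str = "Fz") -> EEGRecording:
    """Single-channel recording wrapper for hand-built traces."""
    return EEGRecording(channel_names=[name], data=np.atleast_2d(data),
                        sampling_rate=fs)
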