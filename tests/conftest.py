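import numpy as np
import pytest

from pepato.io_eurobench import PipelineConfig
from pepato.preprocessing import EnvelopeTensor, preprocess_trial, normalize_amplitude
from pepato.synthgen import SyntheticSpec, generate_trial


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Fixed module count and few restarts: keeps pipeline tests quick."""
    return PipelineConfig(module_number_method="fixed", fixed_n_modules=4,
                          nmf_restarts=5)


@pytest.fixture(scope="session")
def synthetic_trial():
    """One default 8-muscle, 10-cycle, 10%-noise trial (seed 1) plus truth."""
    return generate_trial(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def processed_tensor(synthetic_trial, fast_config):
    """Preprocessed + amplitude-normalized envelope tensor of the trial."""
    recording, events, _ = synthetic_trial
    tensor, quality = preprocess_trial(recording, events, fast_config)
    normalize_amplitude([tensor])
    return tensor, quality


def make_tensor(envelopes: np.ndarray, durations=None) -> EnvelopeTensor:
    """Wrap a (cycles, phase, muscles) array as an EnvelopeTensor."""
    envelopes = np.asarray(envelopes, dtype=float)
    if durations is None:
        durations = np.ones(envelopes.shape[0])
    names = [f"R_ch{i}" for i in range(envelopes.shape[2])]
    return EnvelopeTensor(envelopes, durations, names)
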