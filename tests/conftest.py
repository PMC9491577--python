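import numpy as np
import pytest

from sincdecode.data import IMAGINATION, VISUAL
from sincdecode.preprocessing import PreprocessConfig, preprocess_session
from sincdecode.synthetic import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """Small but structurally complete session layout: 4 classes, 8 channels."""
    return SyntheticConfig(
        n_subjects=1, n_classes=4, visual_trials_per_class=10,
        n_channels=8, native_rate_hz=500.0, shared_fraction=1.0,
        snr_db=3.0, eog_rate=3.0, seed=7)


@pytest.fixture(scope="session")
def visual_recording(tiny_config):
    return generate_session(tiny_config, subject_id=0, task=VISUAL)


@pytest.fixture(scope="session")
def imagination_recording(tiny_config):
    return generate_session(tiny_config, subject_id=0, task=IMAGINATION)


@pytest.fixture(scope="session")
def visual_trials(visual_recording):
    trials, _ = preprocess_session(
        visual_recording, PreprocessConfig(ica_components=6, seed=0))
    return trials


def finite_difference_grads(loss_fn, params, eps=1e-5):
    """Central finite differences of a scalar Tensor-valued callable."""
    for p in params:
        p.zero_grad()
    loss_fn().backward()
    analytic = [np.zeros_like(p.data) if p.grad is None else p.grad.copy()
                for p in params]
    numeric = []
    for p in params:
        g = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p.data[idx]
            p.data[idx] = orig + eps
            hi = loss_fn().item()
            p.data[idx] = orig - eps
            lo = loss_fn().item()
            p.data[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
        numeric.append(g)
    return analytic, numeric
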