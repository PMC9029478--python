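import numpy as np
import pytest
from hypothesis import settings

from atriomech import CONT_DEFAULTS, MCT_DEFAULTS
from atriomech.features import BeatWindow

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def noise_free(params):
    """Single-muscle, deterministic version of a parameter set."""
    return params.replace(noise_sd_force=0.0, noise_sd_fluor=0.0,
                          cv_inter_muscle=0.0, cv_kinetics=0.0)


@pytest.fixture(scope="session")
def cont():
    return CONT_DEFAULTS


@pytest.fixture(scope="session")
def mct():
    return MCT_DEFAULTS


@pytest.fixture(scope="session")
def cont_nf():
    return noise_free(CONT_DEFAULTS)


@pytest.fixture(scope="session")
def mct_nf():
    return noise_free(MCT_DEFAULTS)


def make_beat(force=None, ca=None, fs=1000.0, pre_window_ms=50.0, **kw):
    """BeatWindow from raw arrays; channels default to each other so tests
    can exercise a single channel."""
    if force is None and ca is None:
        raise ValueError("need at least one channel")
    if force is None:
        force = ca
    if ca is None:
        ca = force
    return BeatWindow(stimulus_time=0.0, sampling_rate=fs,
                      pre_window_ms=pre_window_ms,
                      force=np.asarray(force, dtype=float),
                      ca=np.asarray(ca, dtype=float), **kw)


def synthetic_beat(waveform, fs=1000.0, pre_window_ms=50.0, baseline=0.0):
    """Beat whose post-stimulus samples follow ``waveform(t_s)`` and whose
    baseline is flat at ``baseline``."""
    n_pre = int(round(pre_window_ms / 1e3 * fs))
    n_post = int(round(0.45 * fs))
    t = np.arange(n_post) / fs
    y = np.concatenate([np.full(n_pre, baseline), baseline + waveform(t)])
    return make_beat(force=y, ca=y, fs=fs, pre_window_ms=pre_window_ms)
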