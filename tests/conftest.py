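import numpy as np
import pytest

from infodyn.synth import SynthParams, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# weak intrinsic dynamics keep the injected single-lag coupling sharp, which
# the delay-recovery checks rely on
LEAN = dict(storage_gain=0.3, osc_components=(), recording_jitter_sd=0.0)


@pytest.fixture
def coupled_recording():
    params = SynthParams(
        n_epochs=8, epoch_len_s=1.0, coupling_gain=0.2, coupling_delay=10,
        seed=7, **LEAN,
    )
    return generate_recording(params, "test", "rec0")


@pytest.fixture
def uncoupled_recording():
    params = SynthParams(
        n_epochs=8, epoch_len_s=1.0, coupling_gain=0.0, coupling_delay=10,
        seed=7, **LEAN,
    )
    return generate_recording(params, "test", "rec0")


def ar1(rng, phi, n, sd=1.0, burn=100):
    x = np.zeros(n + burn)
    innov = rng.normal(0, sd, n + burn)
    for i in range(1, n + burn):
        x[i] = phi * x[i - 1] + innov[i]
    return x[burn:]
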