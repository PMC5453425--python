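"""Synthetic two-site epoched recordings with known ground truth.

The source channel is an AR(1) process (coefficient = ``storage_gain``)
plus optional oscillatory components and white noise; lowering
``source_entropy_scale`` both sharpens the amplitude distribution (an
entropy reduction that survives z-normalization) and shrinks the amplitude
(which weakens the injected transfer).  The target channel has its own AR(1) dynamics
plus ``coupling_gain`` times a delayed (optionally Gaussian-smoothed) copy
of the source — the same injection recipe used for in-silico coupling
throughout the analyses, so that downstream estimators face the structure
they assume.  Smoothing is off by default so a single-lag coupling stays
sharp for delay-recovery checks; the source-entropy study turns it on.

Epochs are independent realizations (embeddings never cross epoch
boundaries downstream).  One master seed yields deterministic per-recording
substreams, so identical parameters give bit-identical output.

The oscillatory defaults (8 Hz and 25 Hz components) are a free modelling
choice for an awake-like spectrum, not a published characterization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from infodyn.errors import ParameterError
from infodyn.preproc import Recording

__all__ = ["SynthParams", "generate_recording", "generate_condition_set"]

_BURN_IN = 200  # AR warm-up samples, trimmed


@dataclass(frozen=True)
class SynthParams:
    """Generative knobs for one family of recordings."""

    n_recordings_per_condition: int = 3
    n_epochs: int = 40
    epoch_len_s: float = 4.81
    fs: float = 1000.0
    coupling_gain: float = 0.2
    coupling_delay: int = 10
    source_entropy_scale: float = 1.0
    storage_gain: float = 0.7
    osc_components: tuple = ((8.0, 0.5), (25.0, 0.25))
    noise_sd: float = 1.0
    coupling_smooth_sd: float = 0.0
    recording_jitter_sd: float = 0.05
    artifact_epoch_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_samples = int(round(self.epoch_len_s * self.fs))
        if self.n_recordings_per_condition < 1:
            raise ParameterError("need at least 1 recording per condition")
        if self.n_epochs < 1:
            raise ParameterError("need at least 1 epoch")
        if self.fs <= 0 or self.epoch_len_s <= 0:
            raise ParameterError("fs and epoch length must be positive")
        if self.coupling_gain < 0:
            raise ParameterError("coupling_gain must be >= 0")
        if not 1 <= self.coupling_delay < n_samples:
            raise ParameterError(
                f"coupling_delay must be in [1, {n_samples}) samples, got {self.coupling_delay}"
            )
        if not 0 < self.source_entropy_scale <= 1:
            raise ParameterError("source_entropy_scale must be in (0, 1]")
        if self.storage_gain < 0 or self.storage_gain >= 1:
            raise ParameterError("storage_gain must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len_s * self.fs))


def _substream(seed: int, *labels) -> np.random.Generator:
    """Deterministic, platform-stable substream keyed by string labels."""
    key = [seed] + [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(key))


def _ar1(rng: np.random.Generator, phi: float, sd: float, n: int) -> np.ndarray:
    innov = rng.normal(0.0, sd, size=n + _BURN_IN)
    if phi == 0:
        return innov[_BURN_IN:]
    out = np.empty(n + _BURN_IN)
    out[0] = innov[0] / np.sqrt(1 - phi**2)
    for i in range(1, n + _BURN_IN):
        out[i] = phi * out[i - 1] + innov[i]
    return out[_BURN_IN:]


def _entropy_shape(x: np.ndarray, scale: float) -> np.ndarray:
    """Reduce entropy in a scale-free way for scale < 1.

    A signed power transform sharpens the amplitude distribution; since the
    Gaussian maximizes differential entropy at fixed variance, the
    transformed signal has lower entropy even after z-normalization.
    """
    if scale == 1.0:
        return x
    sd = x.std()
    s = x / sd
    shaped = np.sign(s) * np.abs(s) ** (1.0 / scale)
    return shaped / shaped.std() * sd  # same SD, sharper shape


def _oscillations(rng, components, fs, n) -> np.ndarray:
    t = np.arange(n) / fs
    out = np.zeros(n)
    for freq, amp in components:
        out += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return out


def generate_recording(
    params: SynthParams,
    condition: str = "base",
    session_id: str = "rec0",
) -> Recording:
    """Generate one recording (source site "V1", target site "PFC").

    Each epoch is an independent realization.  The target's coupled term at
    time ``t`` is ``coupling_gain * smooth(source)[t - coupling_delay]``
    where smoothing is Gaussian with SD ``coupling_smooth_sd`` samples
    (0 disables smoothing).
    """
    n = params.n_samples
    delay = params.coupling_delay
    rng = _substream(params.seed, condition, session_id)
    src_epochs = np.empty((params.n_epochs, n))
    tgt_epochs = np.empty((params.n_epochs, n))
    for ep in range(params.n_epochs):
        raw = _ar1(rng, params.storage_gain, params.noise_sd, n + delay)
        raw = raw + _oscillations(rng, params.osc_components, params.fs, n + delay)
        # entropy reduction acts on both shape (survives z-normalization)
        # and amplitude (weakens the injected transfer)
        raw = _entropy_shape(raw, params.source_entropy_scale)
        raw = raw * params.source_entropy_scale
        smoothed = (
            gaussian_filter1d(raw, params.coupling_smooth_sd)
            if params.coupling_smooth_sd > 0
            else raw
        )
        target = _ar1(rng, params.storage_gain, params.noise_sd, n)
        target = target + params.coupling_gain * smoothed[:n]
        src_epochs[ep] = raw[delay:]
        tgt_epochs[ep] = target
        if params.artifact_epoch_prob > 0 and rng.uniform() < params.artifact_epoch_prob:
            spike_at = rng.integers(0, n)
            tgt_epochs[ep, spike_at] += 50 * params.noise_sd
    return Recording(
        data={"V1": src_epochs, "PFC": tgt_epochs},
        fs=params.fs,
        condition=condition,
        session_id=session_id,
        ground_truth={
            "coupling_gain": params.coupling_gain,
            "coupling_delay": params.coupling_delay,
            "source_entropy_scale": params.source_entropy_scale,
            "storage_gain": params.storage_gain,
            "source_site": "V1",
            "target_site": "PFC",
        },
    )


def generate_condition_set(base: SynthParams, condition_map: dict) -> list:
    """Generate nested recordings: epochs within recordings within conditions.

    ``condition_map`` maps condition label to a dict of ``SynthParams``
    field overrides.  Per-recording multiplicative jitter on ``storage_gain``
    and ``noise_sd`` (log-normal, SD ``recording_jitter_sd``) injects
    between-recording variability so intraclass correlation is positive.
    """
    if len(condition_map) < 2:
        raise ParameterError("need at least 2 conditions")
    recordings = []
    for condition, overrides in condition_map.items():
        params = replace(base, **overrides)
        if params.n_recordings_per_condition < 2:
            raise ParameterError(
                f"condition {condition!r}: statistics stages need >= 2 recordings"
            )
        for r in range(params.n_recordings_per_condition):
            session_id = f"{condition}_rec{r}"
            jit_rng = _substream(params.seed, "jitter", condition, session_id)
            jittered = params
            if params.recording_jitter_sd > 0:
                g = float(np.clip(
                    params.storage_gain
                    * np.exp(jit_rng.normal(0, params.recording_jitter_sd)),
                    0.0, 0.98,
                ))
                s = float(
                    params.noise_sd * np.exp(jit_rng.normal(0, params.recording_jitter_sd))
                )
                jittered = replace(params, storage_gain=g, noise_sd=s)
            recordings.append(generate_recording(jittered, condition, session_id))
    return recordings
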