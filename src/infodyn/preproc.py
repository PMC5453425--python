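"""Recording container, epoching, QC and conventional time-series measures.

The on-disk container is one HDF5 file per recording (datasets ``<site>``
of shape epochs x samples, root attributes ``fs``, ``sites``, ``condition``,
``session_id``).  A plain-text dialect — a directory with a JSON sidecar and
one CSV per channel — is accepted for small fixtures.

Spectral estimates use the multitaper method with DPSS tapers; the taper
count follows the standard rule K = floor(2 * T * W) - 1 for smoothing
half-bandwidth W (default 1 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

from infodyn.errors import DegenerateSignalError, FormatError, ParameterError

__all__ = [
    "Recording",
    "EpochQC",
    "load_recording",
    "write_recording",
    "segment_epochs",
    "znormalize",
    "relative_delta_power",
    "reject_by_delta",
    "reject_by_amplitude",
    "band_power",
    "act",
    "butter_bandpass",
    "resample",
    "BANDS",
]

BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 40.0),
}


@dataclass
class Recording:
    """Two-site epoched recording.

    ``data`` maps site label to an (n_epochs, n_samples) array.  Both
    channels must agree in epoch count and length.
    """

    data: dict
    fs: float
    condition: str = ""
    session_id: str = ""
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != 2:
            raise FormatError(f"a recording holds exactly 2 channels, got {len(self.data)}")
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        shapes = set()
        for site, arr in list(self.data.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise FormatError(f"channel {site!r} must be epochs x samples")
            self.data[site] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise FormatError(f"channel shapes differ: {shapes}")

    @property
    def sites(self) -> list:
        return list(self.data)

    @property
    def n_epochs(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[1]

    def channel(self, site: str) -> np.ndarray:
        return self.data[site]

    def select_epochs(self, keep) -> "Recording":
        keep = np.asarray(keep)
        return Recording(
            data={s: a[keep] for s, a in self.data.items()},
            fs=self.fs,
            condition=self.condition,
            session_id=self.session_id,
            ground_truth=dict(self.ground_truth),
        )


@dataclass
class EpochQC:
    epoch_index: int
    rejected: bool
    reason: str | None = None          # "artifact" | "delta_power" | None
    relative_delta: float | None = None

    def as_row(self) -> dict:
        return {
            "epoch_index": self.epoch_index,
            "rejected": int(self.rejected),
            "reason": self.reason or "",
            "relative_delta": "" if self.relative_delta is None else self.relative_delta,
        }


# ---------------------------------------------------------------------------
# container I/O


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.attrs["fs"] = rec.fs
            f.attrs["sites"] = json.dumps(rec.sites)
            f.attrs["condition"] = rec.condition
            f.attrs["session_id"] = rec.session_id
            f.attrs["ground_truth"] = json.dumps(rec.ground_truth)
            for site, arr in rec.data.items():
                f.create_dataset(site, data=arr)
        return
    # plain-text dialect: directory with JSON sidecar + one CSV per channel
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": rec.fs,
        "sites": rec.sites,
        "condition": rec.condition,
        "session_id": rec.session_id,
        "n_epochs": rec.n_epochs,
        "n_samples": rec.n_samples,
        "ground_truth": rec.ground_truth,
    }
    (path / "recording.json").write_text(json.dumps(meta, indent=1))
    for site, arr in rec.data.items():
        np.savetxt(path / f"channel_{site}.csv", arr, delimiter=",", fmt="%.17g")


def load_recording(path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording: {path}")
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "fs" not in f.attrs:
                raise FormatError(f"{path}: missing fs metadata")
            sites = json.loads(f.attrs.get("sites", "null") or "null")
            if not sites:
                raise FormatError(f"{path}: missing site labels")
            data = {}
            for site in sites:
                if site not in f:
                    raise FormatError(f"{path}: missing channel {site!r}")
                data[site] = np.asarray(f[site], dtype=float)
            return Recording(
                data=data,
                fs=float(f.attrs["fs"]),
                condition=str(f.attrs.get("condition", "")),
                session_id=str(f.attrs.get("session_id", "")),
                ground_truth=json.loads(f.attrs.get("ground_truth", "{}") or "{}"),
            )
    meta_path = path / "recording.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing recording.json sidecar")
    meta = json.loads(meta_path.read_text())
    if "fs" not in meta:
        raise FormatError(f"{path}: missing fs metadata")
    data = {}
    for site in meta["sites"]:
        csv = path / f"channel_{site}.csv"
        if not csv.exists():
            raise FormatError(f"{path}: missing channel {site!r}")
        arr = np.loadtxt(csv, delimiter=",", ndmin=2)
        data[site] = arr
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        condition=meta.get("condition", ""),
        session_id=meta.get("session_id", ""),
        ground_truth=meta.get("ground_truth", {}),
    )


# ---------------------------------------------------------------------------
# epoching and normalization


def segment_epochs(series, fs: float, epoch_len_s: float = 4.81) -> np.ndarray:
    """Cut a continuous series into epochs; the trailing remainder is dropped."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ParameterError("segment_epochs expects a 1-D series")
    n = int(round(epoch_len_s * fs))
    if series.size < n:
        raise ParameterError(
            f"series of {series.size} samples shorter than one epoch ({n} samples)"
        )
    n_ep = series.size // n
    return series[: n_ep * n].reshape(n_ep, n)


def znormalize(epoch) -> np.ndarray:
    """Zero mean, unit variance along the last axis (per epoch)."""
    arr = np.asarray(epoch, dtype=float)
    sd = arr.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateSignalError("cannot z-normalize a constant epoch")
    return (arr - arr.mean(axis=-1, keepdims=True)) / sd


# ---------------------------------------------------------------------------
# spectral measures


def _multitaper_psd(epoch, fs: float, smoothing_hz: float = 1.0):
    epoch = np.asarray(epoch, dtype=float)
    n = epoch.size
    nw = max(1.0, smoothing_hz * n / fs)
    n_tapers = max(1, int(2 * nw) - 1)
    tapers = sps.windows.dpss(n, nw, n_tapers)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectra = np.abs(np.fft.rfft(tapers * epoch[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0) / fs
    psd[1:-1] *= 2.0  # one-sided
    return freqs, psd


def band_power(epoch, fs: float, band, smoothing_hz: float = 1.0) -> float:
    """Multitaper power in ``band = (lo, hi)`` Hz (DPSS tapers)."""
    lo, hi = band
    if not (0 <= lo < hi <= fs / 2):
        raise ParameterError(f"band {band} outside (0, Nyquist={fs / 2})")
    freqs, psd = _multitaper_psd(epoch, fs, smoothing_hz)
    mask = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return float(psd[mask].sum() * df)


def relative_delta_power(epoch, fs: float, smoothing_hz: float = 1.0) -> float:
    """Power in 0.5-4 Hz as a fraction of power in 0.5-50 Hz."""
    if fs < 100:
        raise ParameterError("relative delta power needs fs >= 100 Hz")
    total = band_power(epoch, fs, (0.5, 50.0), smoothing_hz)
    if total == 0:
        return 0.0
    return band_power(epoch, fs, (0.5, 4.0), smoothing_hz) / total


def reject_by_delta(epochs, fs: float, threshold: float = 0.30) -> list:
    """Flag epochs whose relative delta power exceeds ``threshold`` (strictly)."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    out = []
    for i, ep in enumerate(epochs):
        frac = relative_delta_power(ep, fs)
        rejected = frac > threshold
        out.append(
            EpochQC(
                epoch_index=i,
                rejected=bool(rejected),
                reason="delta_power" if rejected else None,
                relative_delta=float(frac),
            )
        )
    return out


def reject_by_amplitude(epochs, z_threshold: float = 8.0) -> list:
    """Amplitude-based artifact hook: flag epochs with extreme values.

    An epoch is rejected when any sample deviates more than ``z_threshold``
    recording-level standard deviations from the recording-level mean.  The
    threshold is an explicit artifact default, not a published criterion.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    mu, sd = epochs.mean(), epochs.std()
    if sd == 0:
        raise DegenerateSignalError("constant recording")
    z = np.abs(epochs - mu) / sd
    out = []
    for i in range(epochs.shape[0]):
        bad = bool(z[i].max() > z_threshold)
        out.append(EpochQC(epoch_index=i, rejected=bad, reason="artifact" if bad else None))
    return out


# ---------------------------------------------------------------------------
# autocorrelation decay time and filtering


def act(epoch) -> int:
    """Smallest positive lag at which the autocorrelation drops below 1/e."""
    arr = np.asarray(epoch, dtype=float)
    if arr.std() == 0:
        raise DegenerateSignalError("ACT undefined for a constant epoch")
    x = arr - arr.mean()
    n = x.size
    ac = np.correlate(x, x, mode="full")[n - 1:]
    ac = ac / ac[0]
    below = np.nonzero(ac[1:] < np.exp(-1.0))[0]
    if below.size == 0:
        raise DegenerateSignalError("autocorrelation never decays below 1/e within the epoch")
    return int(below[0] + 1)


def butter_bandpass(
    series, fs: float, lo: float, hi: float, order: int = 4, causal: bool = True
) -> np.ndarray:
    """Butterworth band-pass; one-pass (causal) by default."""
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(f"band ({lo}, {hi}) invalid for fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    series = np.asarray(series, dtype=float)
    if causal:
        return sps.sosfilt(sos, series, axis=-1)
    return sps.sosfiltfilt(sos, series, axis=-1)


def resample(series, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling helper (for sampling-rate sensitivity checks)."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(series, dtype=float), frac.numerator, frac.denominator, axis=-1)
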