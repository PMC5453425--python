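"""Delay-embedded state construction and embedding-parameter optimization.

States are vectors of ``d`` past samples spaced ``tau`` apart.  For a target
signal the state preceding time ``t`` is ``(y[t-1], y[t-1-tau], ...,
y[t-1-(d-1)*tau])``; for a source signal an additional transfer delay ``u``
replaces the one-sample offset, giving ``(x[t-u], x[t-u-tau], ...)``.
States never span epoch boundaries.

Embedding parameters are selected with a local-predictor criterion: each
state's next sample is predicted as the mean of the next samples of its
k nearest neighbors, and the (d, tau) pair minimizing the mean squared
prediction error wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from infodyn.errors import DegenerateSignalError, ParameterError

__all__ = [
    "EmbeddingSpec",
    "StateMatrix",
    "delay_embed",
    "ragwitz_optimize",
    "common_dimension",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding dimension ``d``, delay ``tau`` and transfer delay ``u``.

    ``u == 0`` marks a target (own-past) embedding whose state ends one
    sample before the present; ``u >= 1`` marks a source embedding lagged
    by ``u`` samples.
    """

    d: int
    tau: int = 1
    u: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ParameterError(f"embedding dimension must be >= 1, got {self.d}")
        if self.tau < 1:
            raise ParameterError(f"embedding delay must be >= 1, got {self.tau}")
        if self.u < 0:
            raise ParameterError(f"transfer delay must be >= 0, got {self.u}")

    @property
    def offset(self) -> int:
        """Lag of the most recent sample in the state relative to ``t``."""
        return max(self.u, 1)

    @property
    def span(self) -> int:
        """Number of samples a state plus its present sample reaches back."""
        return self.offset + (self.d - 1) * self.tau


@dataclass
class StateMatrix:
    """Embedded states with their per-row time and epoch bookkeeping."""

    states: np.ndarray        # (n_points, d)
    time_index: np.ndarray    # (n_points,) sample index of the present t
    epoch_index: np.ndarray   # (n_points,)

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def dim(self) -> int:
        return self.states.shape[1]


def _as_epochs(epochs) -> np.ndarray:
    arr = np.asarray(epochs, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ParameterError("epochs must be a 1-D series or (n_epochs, n_samples)")
    return arr


def delay_embed(epochs, spec: EmbeddingSpec, align: str = "past_of_t") -> StateMatrix:
    """Build the state matrix for every valid time point of every epoch.

    Parameters
    ----------
    epochs : array-like, (n_epochs, n_samples) or (n_samples,)
    spec : EmbeddingSpec
    align : {"past_of_t", "present_t"}
        "past_of_t": the state for time ``t`` holds samples strictly before
        ``t`` (offset ``max(u, 1)``).  "present_t": the state starts at
        ``t`` itself (used for present-sample extraction).

    Returns
    -------
    StateMatrix
        One row per valid ``t`` per epoch.  With align="past_of_t" each
        epoch contributes ``n_samples - ((d-1)*tau + max(u, 1))`` rows.
    """
    arr = _as_epochs(epochs)
    n_ep, n_samp = arr.shape
    if align == "past_of_t":
        offset = spec.offset
    elif align == "present_t":
        offset = 0
    else:
        raise ParameterError(f"unknown align {align!r}")
    t0 = offset + (spec.d - 1) * spec.tau
    if t0 >= n_samp:
        raise ParameterError(
            f"epoch of {n_samp} samples too short for d={spec.d}, tau={spec.tau}, "
            f"u={spec.u} (first usable index {t0})"
        )
    t = np.arange(t0, n_samp)
    lags = offset + spec.tau * np.arange(spec.d)
    states = arr[:, t[:, None] - lags[None, :]]            # (n_ep, n_t, d)
    n_t = t.size
    return StateMatrix(
        states=states.reshape(n_ep * n_t, spec.d),
        time_index=np.tile(t, n_ep),
        epoch_index=np.repeat(np.arange(n_ep), n_t),
    )


def common_dimension(specs) -> int:
    """Largest embedding dimension over a collection of specs.

    A shared dimension keeps estimator bias comparable across conditions
    and directions; the delay stays per-signal.
    """
    specs = list(specs)
    if not specs:
        raise ParameterError("common_dimension needs a non-empty list of specs")
    return max(s.d for s in specs)


def ragwitz_optimize(
    epochs,
    d_candidates,
    tau_candidates,
    k: int = 4,
):
    """Select (d, tau) by minimizing the k-NN local predictor's MSE.

    For each candidate pair, every valid point is embedded, its next sample
    is predicted as the mean next-sample of its ``k`` nearest embedded
    neighbors (max norm, self excluded), and candidates are scored by mean
    squared prediction error.  Ties break toward smaller ``d`` then smaller
    ``tau``.

    Returns
    -------
    (d, tau, mse_table)
        ``mse_table`` maps ``(d, tau)`` to the prediction MSE.
    """
    arr = _as_epochs(epochs)
    if np.ptp(arr) == 0:
        raise DegenerateSignalError("constant signal cannot be embedded/predicted")
    d_candidates = sorted(set(int(d) for d in d_candidates))
    tau_candidates = sorted(set(int(t) for t in tau_candidates))
    if not d_candidates or not tau_candidates:
        raise ParameterError("candidate grids must be non-empty")
    if len(d_candidates) * len(tau_candidates) < 2:
        raise ParameterError("need at least 2 candidate (d, tau) combinations")

    mse_table: dict[tuple[int, int], float] = {}
    for d in d_candidates:
        for tau in tau_candidates:
            spec = EmbeddingSpec(d=d, tau=tau)
            sm = delay_embed(arr, spec, align="past_of_t")
            if len(sm) <= k + 1:
                raise ParameterError(
                    f"not enough samples for d={d}, tau={tau} with k={k}"
                )
            future = arr[sm.epoch_index, sm.time_index]
            tree = cKDTree(sm.states)
            _, idx = tree.query(sm.states, k=k + 1, p=np.inf)
            pred = future[idx[:, 1:]].mean(axis=1)
            mse_table[(d, tau)] = float(np.mean((future - pred) ** 2))

    best = min(mse_table, key=lambda dt: (mse_table[dt], dt[0], dt[1]))
    return best[0], best[1], mse_table


def tau_from_act(act_samples: int, fractions=(0.2, 0.4, 0.6, 0.8, 1.0)):
    """Delay candidates as fractions of the autocorrelation decay time.

    Always at least one sample; duplicates removed, ascending.
    """
    taus = sorted({max(1, int(round(f * act_samples))) for f in fractions})
    return taus
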