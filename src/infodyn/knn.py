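"""Nearest-neighbor estimators for continuous epoched data.

Implements the Kozachenko-Leonenko differential-entropy estimator, the
Kraskov-Stögbauer-Grassberger (KSG) mutual-information estimator and its
conditional form, and on top of those: active information storage (AIS),
delay-aware transfer entropy with source lag ``u``, the transfer-delay scan,
and the normalized net-transfer index.

All neighbor searches use the maximum norm.  Values are in nats unless
converted with :func:`to_bits`.

Two digamma forms are used deliberately: the conditional-MI estimator uses
"+1" neighbor counts with strictly-inside counting, while the plain MI
estimator uses the "-1/k" variant whose marginal radii are set per marginal
by the k joint neighbors and counted inclusively.  Both are standard; they
are kept distinct because downstream measures are defined against one form
each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from infodyn.errors import EstimatorError, ParameterError

__all__ = [
    "EstimateRecord",
    "DelayScan",
    "kl_entropy",
    "ksg_mi",
    "ksg_cmi",
    "ais",
    "te_spo",
    "scan_delay",
    "te_net",
    "to_bits",
]

_LN2 = np.log(2.0)
_STRICT = 1.0 - 1e-12
_INCLUSIVE = 1.0 + 1e-12


def to_bits(nats: float) -> float:
    return nats / _LN2


@dataclass
class EstimateRecord:
    """One information-theoretic estimate with full provenance."""

    measure: str                  # H | AIS | TE_SPO | TE_net
    value: float
    unit: str = "nats"
    direction_or_site: str = ""
    condition: str = ""
    session_id: str = ""
    epoch_index: object = "pooled"
    params: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "measure": self.measure,
            "value": self.value,
            "unit": self.unit,
            "direction_or_site": self.direction_or_site,
            "condition": self.condition,
            "session_id": self.session_id,
            "epoch_index": self.epoch_index,
        }
        for key, val in sorted(self.params.items()):
            row[f"param_{key}"] = val
        return row


@dataclass
class DelayScan:
    """Transfer entropy as a function of the assumed transfer delay."""

    u_grid: np.ndarray
    te_values: np.ndarray
    u_opt: int
    peaks: list

    def as_dict(self) -> dict:
        return {
            "u_grid": [int(u) for u in self.u_grid],
            "te_values": [float(v) for v in self.te_values],
            "u_opt": int(self.u_opt),
            "peaks": [int(p) for p in self.peaks],
        }


# ---------------------------------------------------------------------------
# low-level neighbor machinery


def _as_2d(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "states", x), dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _check_alignment(*matrices) -> None:
    """StateMatrix inputs must share time/epoch indices realization-wise."""
    indexed = [m for m in matrices if hasattr(m, "time_index")]
    for other in indexed[1:]:
        if not (
            np.array_equal(indexed[0].time_index, other.time_index)
            and np.array_equal(indexed[0].epoch_index, other.epoch_index)
        ):
            raise EstimatorError("state matrices are misaligned in time/epoch")


def _maybe_jitter(arrays, jitter: bool, seed: int):
    """Break exact duplicates with tiny deterministic noise.

    Duplicate points make max-norm radii zero and the digamma sums
    ill-defined; discretized or quantized inputs are the usual culprit.
    """
    if not jitter:
        return arrays
    joint = np.hstack(arrays)
    uniq = np.unique(joint, axis=0)
    if uniq.shape[0] == joint.shape[0]:
        return arrays
    rng = np.random.default_rng(seed)
    out = []
    for arr in arrays:
        scale = 1e-10 * np.maximum(arr.std(axis=0), 1e-30)
        out.append(arr + rng.uniform(-1, 1, size=arr.shape) * scale)
    return out


def _kth_distance(points: np.ndarray, k: int) -> np.ndarray:
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1, p=np.inf)
    return dist[:, -1]


def _count_within(points: np.ndarray, radii: np.ndarray, inclusive: bool) -> np.ndarray:
    """Neighbors of each point within its own radius, self excluded."""
    factor = _INCLUSIVE if inclusive else _STRICT
    r = radii * factor
    if points.shape[1] == 1:
        flat = points[:, 0]
        order = np.argsort(flat, kind="stable")
        xs = flat[order]
        if inclusive:
            hi = np.searchsorted(xs, flat + r, side="right")
            lo = np.searchsorted(xs, flat - r, side="left")
        else:
            hi = np.searchsorted(xs, flat + r, side="left")
            lo = np.searchsorted(xs, flat - r, side="right")
        return hi - lo - 1
    tree = cKDTree(points)
    n = tree.query_ball_point(points, r, p=np.inf, return_length=True)
    return np.asarray(n) - 1


# ---------------------------------------------------------------------------
# core estimators


def kl_entropy(states, k: int = 4, jitter: bool = True, jitter_seed: int = 0) -> float:
    """Kozachenko-Leonenko differential entropy, in nats.

    ``H = -psi(k) + psi(N) + (dim/N) * sum_i log(eps_i)`` with ``eps_i``
    twice the max-norm distance from point ``i`` to its k-th neighbor.
    """
    pts = _as_2d(getattr(states, "states", states))
    n = pts.shape[0]
    if n <= k:
        raise EstimatorError(f"need more than k={k} points, got {n}")
    (pts,) = _maybe_jitter([pts], jitter, jitter_seed)
    eps = 2.0 * _kth_distance(pts, k)
    if np.any(eps == 0):
        raise EstimatorError(
            "duplicate points give zero neighbor distance; enable jitter"
        )
    return float(-digamma(k) + digamma(n) + pts.shape[1] * np.mean(np.log(eps)))


def ksg_mi(a, b, k: int = 4, jitter: bool = True, jitter_seed: int = 0) -> float:
    """KSG mutual information (the "-1/k" variant), in nats.

    Marginal radii are the per-marginal extent of each point's k joint
    neighbors; marginal counts are inclusive of that boundary.
    """
    _check_alignment(a, b)
    a, b = _as_2d(a), _as_2d(b)
    if a.shape[0] != b.shape[0]:
        raise EstimatorError("misaligned state matrices")
    n = a.shape[0]
    if n <= k:
        raise EstimatorError(f"need more than k={k} points, got {n}")
    a, b = _maybe_jitter([a, b], jitter, jitter_seed)
    joint = np.hstack([a, b])
    tree = cKDTree(joint)
    _, idx = tree.query(joint, k=k + 1, p=np.inf)
    neigh = idx[:, 1:]
    eps_a = np.abs(a[neigh] - a[:, None, :]).max(axis=(1, 2))
    eps_b = np.abs(b[neigh] - b[:, None, :]).max(axis=(1, 2))
    n_a = _count_within(a, eps_a, inclusive=True)
    n_b = _count_within(b, eps_b, inclusive=True)
    n_a = np.maximum(n_a, 1)
    n_b = np.maximum(n_b, 1)
    val = (
        digamma(k)
        - 1.0 / k
        + digamma(n)
        - np.mean(digamma(n_a) + digamma(n_b))
    )
    return float(val)


def ksg_cmi(a, b, cond, k: int = 4, jitter: bool = True, jitter_seed: int = 0) -> float:
    """KSG conditional mutual information I(a; b | cond), in nats.

    ``psi(k) + <psi(n_c + 1) - psi(n_ac + 1) - psi(n_bc + 1)>`` with counts
    strictly inside the joint k-th-neighbor radius.
    """
    _check_alignment(a, b, cond)
    a, b, cond = _as_2d(a), _as_2d(b), _as_2d(cond)
    if not (a.shape[0] == b.shape[0] == cond.shape[0]):
        raise EstimatorError("misaligned state matrices")
    n = a.shape[0]
    if n <= k:
        raise EstimatorError(f"need more than k={k} points, got {n}")
    a, b, cond = _maybe_jitter([a, b, cond], jitter, jitter_seed)
    joint = np.hstack([a, b, cond])
    eps = _kth_distance(joint, k)
    n_c = _count_within(cond, eps, inclusive=False)
    n_ac = _count_within(np.hstack([a, cond]), eps, inclusive=False)
    n_bc = _count_within(np.hstack([b, cond]), eps, inclusive=False)
    val = digamma(k) + np.mean(
        digamma(n_c + 1) - digamma(n_ac + 1) - digamma(n_bc + 1)
    )
    return float(val)


# ---------------------------------------------------------------------------
# aligned state extraction for the composite measures


def _as_epochs(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ParameterError("expected 1-D series or (n_epochs, n_samples)")
    return arr


def _self_states(epochs, d, tau):
    """(present, past-state) pairs pooled over epochs."""
    arr = _as_epochs(epochs)
    n_samp = arr.shape[1]
    t0 = 1 + (d - 1) * tau
    if t0 >= n_samp:
        raise ParameterError(f"epochs of {n_samp} samples too short for d={d}, tau={tau}")
    t = np.arange(t0, n_samp)
    lags = 1 + tau * np.arange(d)
    present = arr[:, t].reshape(-1, 1)
    past = arr[:, t[:, None] - lags[None, :]].reshape(-1, d)
    return present, past


def _te_states(source, target, d_x, d_y, tau_x, tau_y, u):
    """(present, source-state, target-past-state) aligned and pooled."""
    src = _as_epochs(source)
    tgt = _as_epochs(target)
    if src.shape != tgt.shape:
        raise EstimatorError(
            f"source/target epoch mismatch: {src.shape} vs {tgt.shape}"
        )
    if u < 1:
        raise ParameterError(f"transfer delay u must be >= 1, got {u}")
    n_samp = tgt.shape[1]
    t0 = max(1 + (d_y - 1) * tau_y, u + (d_x - 1) * tau_x)
    if t0 >= n_samp:
        raise ParameterError("epochs too short for the requested embeddings")
    t = np.arange(t0, n_samp)
    lags_y = 1 + tau_y * np.arange(d_y)
    lags_x = u + tau_x * np.arange(d_x)
    present = tgt[:, t].reshape(-1, 1)
    y_past = tgt[:, t[:, None] - lags_y[None, :]].reshape(-1, d_y)
    x_state = src[:, t[:, None] - lags_x[None, :]].reshape(-1, d_x)
    return present, x_state, y_past


def ais(
    epochs,
    d: int,
    tau: int = 1,
    k: int = 4,
    jitter: bool = True,
    jitter_seed: int = 0,
    **meta,
) -> EstimateRecord:
    """Active information storage: MI(present; own past state), nats."""
    present, past = _self_states(epochs, d, tau)
    value = ksg_mi(present, past, k=k, jitter=jitter, jitter_seed=jitter_seed)
    return EstimateRecord(
        measure="AIS",
        value=value,
        params={"k": k, "d": d, "tau": tau},
        **meta,
    )


def te_spo(
    source,
    target,
    d_x: int,
    d_y: int,
    tau: int | tuple = 1,
    u: int = 1,
    k: int = 4,
    jitter: bool = True,
    jitter_seed: int = 0,
    **meta,
) -> EstimateRecord:
    """Delay-aware transfer entropy I(present; lagged source state | own past)."""
    tau_x, tau_y = (tau, tau) if np.isscalar(tau) else tau
    present, x_state, y_past = _te_states(source, target, d_x, d_y, tau_x, tau_y, u)
    value = ksg_cmi(present, x_state, y_past, k=k, jitter=jitter, jitter_seed=jitter_seed)
    return EstimateRecord(
        measure="TE_SPO",
        value=value,
        params={"k": k, "d_x": d_x, "d_y": d_y, "tau_x": tau_x, "tau_y": tau_y, "u": u},
        **meta,
    )


def _local_maxima(values: np.ndarray, grid: np.ndarray) -> list:
    peaks = []
    n = len(values)
    for i in range(n):
        left_ok = i == 0 or values[i] > values[i - 1]
        right_ok = i == n - 1 or values[i] > values[i + 1]
        if n > 1 and left_ok and right_ok:
            peaks.append(int(grid[i]))
    return peaks


def scan_delay(
    source,
    target,
    d_x: int,
    d_y: int,
    tau: int | tuple = 1,
    u_grid=range(1, 21),
    k: int = 4,
    jitter: bool = True,
    jitter_seed: int = 0,
) -> DelayScan:
    """Estimate TE for every assumed delay in ``u_grid``.

    The reconstructed delay is the argmax (ties toward the smallest u);
    all local maxima are reported since multiple peaks can indicate
    multiple transfer channels.
    """
    grid = np.asarray(sorted(int(u) for u in u_grid))
    if grid.size == 0:
        raise ParameterError("u_grid must be non-empty")
    if grid[0] < 1:
        raise ParameterError("all assumed delays must be >= 1 sample")
    values = np.array(
        [
            te_spo(
                source, target, d_x, d_y, tau=tau, u=int(u), k=k,
                jitter=jitter, jitter_seed=jitter_seed,
            ).value
            for u in grid
        ]
    )
    u_opt = int(grid[int(np.argmax(values))])
    return DelayScan(
        u_grid=grid,
        te_values=values,
        u_opt=u_opt,
        peaks=_local_maxima(values, grid),
    )


def te_net(te_xy: float, te_yx: float) -> float:
    """Normalized difference (fwd - rev) / (fwd + rev) of two directed TEs."""
    denom = te_xy + te_yx
    if denom == 0:
        raise EstimatorError("te_net undefined: forward + reverse TE is zero")
    return (te_xy - te_yx) / denom
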