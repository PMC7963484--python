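"""Feedforward network: weight initialization and the cortical rate response.

The cortex is a layer of linear rate units driven through a nonnegative,
bounded weight matrix with periodic topology in both layers:

    tau_m dv/dt = -v + W u + v_spon.

Because the membrane time constant (10 ms) is far shorter than event
durations (150 ms), the learning loop evaluates v at its fixed point
``W u + v_spon`` for the duration of each event; the explicit Euler
integrator is retained for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "NetworkParams",
    "Weights",
    "init_weights",
    "steady_state_response",
    "integrate_response",
    "matched_positions",
    "periodic_distance",
]


@dataclass(frozen=True)
class NetworkParams:
    tau_m: float = 0.01
    w_ini_low: float = 0.15
    w_ini_high: float = 0.25
    bias_amp: float = 0.05
    bias_spread: float = 4.0
    wmax: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.w_ini_low < self.w_ini_high <= self.wmax):
            raise ValueError("need 0 < w_ini_low < w_ini_high <= wmax")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.bias_amp < 0:
            raise ValueError("bias_amp must be non-negative")


@dataclass
class Weights:
    """Nv x Nu nonnegative weight matrix bounded by ``wmax``."""

    matrix: np.ndarray
    wmax: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("weight matrix must be 2-D")

    @property
    def n_ctx(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_thal(self) -> int:
        return self.matrix.shape[1]

    def copy(self) -> "Weights":
        return Weights(self.matrix.copy(), self.wmax)

    def save_txt(self, path) -> None:
        np.savetxt(path, self.matrix, header=f"wmax={self.wmax}")

    @classmethod
    def load_txt(cls, path, wmax: float | None = None) -> "Weights":
        if wmax is None:
            with open(path) as fh:
                first = fh.readline()
            if "wmax=" not in first:
                raise ValueError("no wmax metadata in file; pass wmax=")
            wmax = float(first.split("wmax=")[1])
        return cls(np.loadtxt(path), wmax)


def periodic_distance(i: np.ndarray | int, j: np.ndarray | int, n: int):
    """Shortest circular distance between indices on a ring of size n."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)


def matched_positions(n_ctx: int, n_thal: int) -> np.ndarray:
    """Topographically matched thalamic position of each cortical cell."""
    return np.round(np.arange(n_ctx) * n_thal / n_ctx).astype(int) % n_thal


def init_weights(
    params: NetworkParams,
    n_thal: int,
    n_ctx: int,
    rng: np.random.Generator,
) -> Weights:
    """Uniform random weights plus an additive Gaussian topographic bias.

    Each cortical cell's connections peak at its matched thalamic position
    and decay with the periodic index distance; the result is clipped to
    ``[0, wmax]``.
    """
    if n_thal <= 0 or n_ctx <= 0:
        raise ValueError("layer sizes must be positive")
    w = rng.uniform(params.w_ini_low, params.w_ini_high, size=(n_ctx, n_thal))
    if params.bias_amp > 0:
        centers = matched_positions(n_ctx, n_thal)
        d = periodic_distance(
            np.arange(n_thal)[None, :], centers[:, None], n_thal
        )
        w = w + params.bias_amp * np.exp(-(d**2) / (2 * params.bias_spread**2))
    np.clip(w, 0.0, params.wmax, out=w)
    return Weights(w, params.wmax)


def steady_state_response(
    W: Weights | np.ndarray, u: np.ndarray, v_spon: np.ndarray | float = 0.0
) -> np.ndarray:
    """Fixed point of the rate dynamics: ``v = W u + v_spon``."""
    m = W.matrix if isinstance(W, Weights) else np.asarray(W)
    u = np.asarray(u, dtype=float)
    if u.shape[0] != m.shape[1]:
        raise ValueError("thalamic rate vector does not match weight matrix")
    v_spon = np.asarray(v_spon, dtype=float)
    if v_spon.ndim and v_spon.shape[0] != m.shape[0]:
        raise ValueError("v_spon does not match the cortical layer")
    return m @ u + v_spon


def integrate_response(
    W: Weights | np.ndarray,
    u: Callable[[float], np.ndarray] | np.ndarray,
    v_spon: Callable[[float], np.ndarray] | np.ndarray,
    dt: float,
    t_span: tuple[float, float],
    tau_m: float = 0.01,
    v_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit-Euler trajectory of the membrane equation.

    ``u``/``v_spon`` may be constant vectors or callables of time.  Used for
    validating the quasi-static response, not in the learning loop.
    Returns ``(times, v_traj)`` with ``v_traj`` of shape (n_steps+1, Nv).
    """
    m = W.matrix if isinstance(W, Weights) else np.asarray(W)
    if dt > tau_m / 5:
        raise ValueError("dt too large for stable integration (need <= tau_m/5)")
    t0, t1 = t_span
    n = int(np.ceil((t1 - t0) / dt))
    u_fn = u if callable(u) else (lambda t, _u=np.asarray(u, float): _u)
    s_fn = (
        v_spon
        if callable(v_spon)
        else (lambda t, _s=np.broadcast_to(
            np.asarray(v_spon, float), (m.shape[0],)
        ): _s)
    )
    v = np.zeros(m.shape[0]) if v_init is None else np.asarray(v_init, float)
    times = t0 + dt * np.arange(n + 1)
    traj = np.empty((n + 1, m.shape[0]))
    traj[0] = v
    for k in range(n):
        t = times[k]
        v = v + dt / tau_m * (-v + m @ u_fn(t) + s_fn(t))
        traj[k + 1] = v
    return times, traj
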