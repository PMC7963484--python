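"""Plasticity rules and the event-driven simulation loop.

Three rules refine the thalamocortical weights:

* ``hebb`` — Hebbian covariance rule ``tau_w dw/dt = v (u - theta_u)``.
  During L-events coincident activity potentiates the driven weights; during
  H-events (no presynaptic drive) every weight of an active cell depresses
  in proportion to ``theta_u``.
* ``hebb_adaptive`` — same rule, but each cell's intrinsic H-event rate is
  scaled by an activity trace ``eta`` that integrates its firing rate over
  ``tau_eta`` (homeostatic adaptation of H-event amplitude).
* ``bcm`` — ``tau_w dw/dt = v u (v - theta_v)`` with the sliding threshold
  ``tau_theta dtheta_v/dt = -theta_v + v^2 / v0``.

Because the membrane time constant is far shorter than event durations,
which in turn are far shorter than the learning time constant, the default
loop is quasi-static: the cortical rate sits at its fixed point for the
duration of each event and is exactly zero between events.  The timeline is
decomposed into elementary segments on which the set of active events is
constant (at most one L- and one H-event, since events of one train never
coexist), so overlapping drives superpose exactly.  A full explicit-Euler
loop over the same schedule is provided as a validation oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .events import (EventSchedule, EventTrainConfig, build_schedule,
                     build_schedule_arrays, _train_events)
from .network import NetworkParams, Weights, init_weights

__all__ = [
    "PlasticityParams",
    "CorticalState",
    "SimConfig",
    "SimResult",
    "hebb_update",
    "bcm_update",
    "slide_threshold",
    "update_adaptation",
    "effective_h_amplitude",
    "run_simulation",
    "run_simulation_euler",
    "record_traces",
]

_RULES = ("hebb", "hebb_adaptive", "bcm")


@dataclass(frozen=True)
class PlasticityParams:
    rule: Literal["hebb", "hebb_adaptive", "bcm"] = "hebb"
    #: learning time constant; None selects the rule default (500 s for the
    #: Hebbian covariance rule, 1000 s for BCM)
    tau_w: float | None = None
    theta_u: float = 0.5
    v0: float = 0.7
    tau_theta: float = 20.0
    tau_eta: float = 1.0
    #: weight-bound handling: "hard" clips to [0, wmax]; "soft_potentiation"
    #: additionally scales potentiation by (wmax-w)/wmax; "soft" also scales
    #: depression by w/wmax
    bounds: Literal["hard", "soft_potentiation", "soft"] = "hard"

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.theta_u < 0:
            raise ValueError("theta_u must be non-negative")
        if self.v0 <= 0 or self.tau_theta <= 0 or self.tau_eta <= 0:
            raise ValueError("v0, tau_theta, tau_eta must be positive")
        if self.bounds not in ("hard", "soft_potentiation", "soft"):
            raise ValueError(f"unknown bounds mode {self.bounds!r}")

    @property
    def tau_w_eff(self) -> float:
        if self.tau_w is not None:
            return self.tau_w
        return 1000.0 if self.rule == "bcm" else 500.0

    @property
    def adaptive(self) -> bool:
        return self.rule == "hebb_adaptive"


@dataclass
class CorticalState:
    """Per-cortical-cell dynamic state carried across events."""

    v: np.ndarray
    eta: np.ndarray
    theta_v: np.ndarray
    t: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    events: EventTrainConfig = field(default_factory=EventTrainConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    snapshot_times: tuple[float, ...] = ()
    engine: Literal["numba", "numpy"] = "numba"

    def __post_init__(self) -> None:
        if any(
            b < a
            for a, b in zip(self.snapshot_times, self.snapshot_times[1:])
        ):
            raise ValueError("snapshot_times must be non-decreasing")


@dataclass
class SimResult:
    weights: Weights
    snapshots: dict[float, np.ndarray]
    schedule: EventSchedule
    h_onsets: np.ndarray
    h_eff: np.ndarray
    h_eta: np.ndarray
    state: CorticalState
    config: SimConfig
    seed: int | None = None


# ---------------------------------------------------------------------------
# pure single-step update functions


_BOUND_CODE = {"hard": 0, "soft_potentiation": 1, "soft": 2}


def _apply_bounds(raw: np.ndarray, w: np.ndarray, wmax: float,
                  bounds: str) -> np.ndarray:
    """Weight-dependent scaling of the raw update before clipping."""
    if bounds == "hard":
        return raw
    if bounds == "soft_potentiation":
        return np.where(raw > 0, raw * (wmax - w) / wmax, raw)
    return np.where(raw > 0, raw * (wmax - w) / wmax, raw * w / wmax)


def hebb_update(
    W: np.ndarray,
    v: np.ndarray,
    u: np.ndarray,
    theta_u: float,
    dt_eff: float,
    tau_w: float,
    bounds: str = "hard",
    wmax: float = 0.5,
) -> np.ndarray:
    """One event's worth of the Hebbian covariance rule; returns a new matrix."""
    raw = np.outer(v, u - theta_u) * (dt_eff / tau_w)
    raw = _apply_bounds(raw, W, wmax, bounds)
    return np.clip(W + raw, 0.0, wmax)


def bcm_update(
    W: np.ndarray,
    v: np.ndarray,
    u: np.ndarray,
    theta_v: np.ndarray,
    dt_eff: float,
    tau_w: float,
    bounds: str = "hard",
    wmax: float = 0.5,
) -> np.ndarray:
    """One event's worth of the BCM rule; returns a new matrix."""
    raw = np.outer(v * (v - theta_v), u) * (dt_eff / tau_w)
    raw = _apply_bounds(raw, W, wmax, bounds)
    return np.clip(W + raw, 0.0, wmax)


def slide_threshold(
    theta_v: np.ndarray,
    v: np.ndarray,
    v0: float,
    tau_theta: float,
    dt: float,
) -> np.ndarray:
    """Euler step of the sliding BCM threshold toward v^2/v0."""
    return theta_v + dt / tau_theta * (-theta_v + v**2 / v0)


def update_adaptation(
    eta: np.ndarray, v: np.ndarray | float, tau_eta: float, elapsed: float
) -> np.ndarray:
    """Exact update of the activity trace for piecewise-constant v."""
    if elapsed < 0:
        raise ValueError("elapsed must be non-negative")
    decay = math.exp(-elapsed / tau_eta)
    return v + (eta - v) * decay


def effective_h_amplitude(
    eta: np.ndarray | float, h_amp_event: float, adaptive: bool = True
) -> np.ndarray | float:
    """Intrinsic cortical rate during an H-event: eta-scaled when adaptive."""
    if adaptive:
        return eta * h_amp_event
    return np.broadcast_to(np.asarray(h_amp_event, float), np.shape(eta)).copy() \
        if np.ndim(eta) else h_amp_event


# ---------------------------------------------------------------------------
# segment decomposition of a schedule


def _event_arrays(schedule: EventSchedule, kind: str, layer: int):
    evs = schedule.of_kind(kind)
    onset = np.array([e.onset for e in evs])
    end = np.array([e.end for e in evs])
    amp = np.array([e.amplitude for e in evs])
    # flattened participating indices + offsets (supports scattered geometry)
    idx_lists = [e.indices(layer) for e in evs]
    offsets = np.zeros(len(evs) + 1, dtype=np.int64)
    if evs:
        offsets[1:] = np.cumsum([len(ix) for ix in idx_lists])
        flat = np.concatenate(idx_lists).astype(np.int64)
    else:
        flat = np.empty(0, dtype=np.int64)
    return onset, end, amp, offsets, flat


def _segments(l_onset, l_end, h_onset, h_end):
    """Elementary intervals on which the active-event pair is constant.

    Returns (t0, dt, l_idx, h_idx) with index -1 for an inactive train.
    """
    bounds = np.unique(np.concatenate([l_onset, l_end, h_onset, h_end]))
    if bounds.size < 2:
        z = np.empty(0)
        return z, z, z.astype(np.int64), z.astype(np.int64)
    mids = 0.5 * (bounds[:-1] + bounds[1:])

    def stab(onset, end):
        if onset.size == 0:
            return np.full(mids.size, -1, dtype=np.int64)
        k = np.searchsorted(onset, mids, side="right") - 1
        kc = np.clip(k, 0, onset.size - 1)
        active = (k >= 0) & (mids < end[kc])
        return np.where(active, kc, -1)

    li = stab(l_onset, l_end)
    hi = stab(h_onset, h_end)
    keep = (li >= 0) | (hi >= 0)
    return bounds[:-1][keep], np.diff(bounds)[keep], li[keep], hi[keep]


# ---------------------------------------------------------------------------
# quasi-static engines

try:  # pragma: no cover - import guard exercised implicitly
    from ._kernels import run_segments_numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _run_segments_py(
    W,
    eta,
    theta_v,
    t_prev,
    seg_t0,
    seg_dt,
    seg_l,
    seg_h,
    l_amp,
    l_off,
    l_flat,
    h_amp,
    h_off,
    h_flat,
    params: PlasticityParams,
    wmax: float,
    h_eff,
    h_eta,
    traces=None,
    trace_dt: float = 0.01,
    trace_t0: float = 0.0,
):
    """Reference (numpy) implementation of the quasi-static segment loop.

    Mirrors the numba kernel; optionally paints the cortical rate into a
    pre-allocated trace matrix sampled at ``trace_dt``.
    """
    n_ctx = W.shape[0]
    tau_w = params.tau_w_eff
    is_bcm = params.rule == "bcm"
    adaptive = params.adaptive
    cur_h = -1
    vspon = np.zeros(n_ctx)
    for s in range(seg_t0.size):
        t0 = seg_t0[s]
        dt = seg_dt[s]
        gap = t0 - t_prev
        if gap > 0:
            eta *= math.exp(-gap / params.tau_eta)
            if is_bcm:
                theta_v *= math.exp(-gap / params.tau_theta)
        li = int(seg_l[s])
        hi = int(seg_h[s])
        if hi != cur_h:
            vspon[:] = 0.0
            if hi >= 0:
                members = h_flat[h_off[hi] : h_off[hi + 1]]
                amp = effective_h_amplitude(
                    eta[members], h_amp[hi], adaptive
                )
                vspon[members] = amp
                h_eff[hi] = float(np.mean(vspon[members]))
                h_eta[hi] = float(np.mean(eta[members]))
            cur_h = hi
        u = None
        if li >= 0:
            u = np.zeros(W.shape[1])
            u[l_flat[l_off[li] : l_off[li + 1]]] = l_amp[li]
            v = W @ u
            if hi >= 0:
                v = v + vspon
        else:
            v = vspon.copy() if hi >= 0 else np.zeros(n_ctx)
        # weight update over the segment
        if not is_bcm:
            uu = u if u is not None else np.zeros(W.shape[1])
            W[:] = hebb_update(
                W, v, uu, params.theta_u, dt, tau_w,
                params.bounds, wmax,
            )
        else:
            if li >= 0:
                W[:] = bcm_update(
                    W, v, u, theta_v, dt, tau_w, params.bounds, wmax
                )
            nsub = max(1, int(math.ceil(dt / (params.tau_theta / 20.0))))
            h = dt / nsub
            for _ in range(nsub):
                theta_v[:] = slide_threshold(
                    theta_v, v, params.v0, params.tau_theta, h
                )
        if traces is not None:
            k0 = max(0, int(math.ceil((t0 - trace_t0) / trace_dt)))
            k1 = min(
                traces.shape[1], int(math.floor((t0 + dt - trace_t0) / trace_dt)) + 1
            )
            if k1 > k0:
                traces[:, k0:k1] = v[:, None]
        eta[:] = update_adaptation(eta, v, params.tau_eta, dt)
        t_prev = t0 + dt
    return t_prev


def _rng_from(seed) -> tuple[np.random.Generator, int | None]:
    if isinstance(seed, np.random.Generator):
        return seed, None
    return np.random.default_rng(seed), seed


def _prepare(cfg: SimConfig, rng: np.random.Generator,
             keep_schedule: bool = True):
    l_train, h_train = build_schedule_arrays(cfg.events, rng)
    W = init_weights(cfg.network, cfg.events.n_thal, cfg.events.n_ctx, rng)
    l_off, l_flat = l_train.flat_indices(cfg.events.n_thal)
    h_off, h_flat = h_train.flat_indices(cfg.events.n_ctx)
    segs = _segments(l_train.onset, l_train.end, h_train.onset, h_train.end)
    arrays = dict(
        l_amp=l_train.amplitude, l_off=l_off, l_flat=l_flat,
        h_onset=h_train.onset, h_amp=h_train.amplitude,
        h_off=h_off, h_flat=h_flat,
    )
    schedule = None
    if keep_schedule:
        events = _train_events(l_train) + _train_events(h_train)
        events.sort(key=lambda e: e.onset)
        schedule = EventSchedule(events=tuple(events),
                                 horizon=cfg.events.horizon)
    return schedule, W, segs, arrays


def _dispatch_segments(cfg, W, eta, theta_v, t_prev, segs, arrays, h_eff, h_eta,
                       lo, hi_):
    """Run segments [lo, hi_) with the configured engine."""
    seg_t0, seg_dt, seg_l, seg_h = segs
    p = cfg.plasticity
    sl = slice(lo, hi_)
    if cfg.engine == "numba" and _HAVE_NUMBA:
        return run_segments_numba(
            W.matrix, eta, theta_v, t_prev,
            seg_t0[sl], seg_dt[sl], seg_l[sl], seg_h[sl],
            arrays["l_amp"], arrays["l_off"], arrays["l_flat"],
            arrays["h_amp"], arrays["h_off"], arrays["h_flat"],
            1 if p.rule == "bcm" else 0,
            1 if p.adaptive else 0,
            _BOUND_CODE[p.bounds],
            p.theta_u, p.tau_w_eff, W.wmax,
            p.v0, p.tau_theta, p.tau_eta,
            h_eff, h_eta,
        )
    return _run_segments_py(
        W.matrix, eta, theta_v, t_prev,
        seg_t0[sl], seg_dt[sl], seg_l[sl], seg_h[sl],
        arrays["l_amp"], arrays["l_off"], arrays["l_flat"],
        arrays["h_amp"], arrays["h_off"], arrays["h_flat"],
        p, W.wmax, h_eff, h_eta,
    )


def run_simulation(cfg: SimConfig, rng, keep_schedule: bool = True) -> SimResult:
    """Simulate the full learning loop over one sampled schedule.

    ``rng`` is an integer seed or a ``numpy.random.Generator``.  Events are
    iterated in time order; within each elementary segment the cortical rate
    is quasi-static, the configured rule is applied over the segment
    duration, the adaptation trace is updated in closed form, and the BCM
    threshold relaxes by Euler substeps (closed-form decay between events).
    ``keep_schedule=False`` skips materializing the event log (grid runs).
    """
    rng, seed = _rng_from(rng)
    schedule, W, segs, arrays = _prepare(cfg, rng, keep_schedule)
    n_ctx = cfg.events.n_ctx
    eta = np.ones(n_ctx)
    theta_v = np.full(n_ctx, cfg.plasticity.v0)
    n_h = arrays["h_amp"].size
    h_eff = np.full(n_h, np.nan)
    h_eta = np.full(n_h, np.nan)
    seg_t0 = segs[0]
    t_prev = 0.0
    snapshots: dict[float, np.ndarray] = {}
    lo = 0
    for t_snap in cfg.snapshot_times:
        hi_ = int(np.searchsorted(seg_t0, t_snap))
        t_prev = _dispatch_segments(
            cfg, W, eta, theta_v, t_prev, segs, arrays, h_eff, h_eta, lo, hi_
        )
        snapshots[float(t_snap)] = W.matrix.copy()
        lo = hi_
    t_prev = _dispatch_segments(
        cfg, W, eta, theta_v, t_prev, segs, arrays, h_eff, h_eta,
        lo, seg_t0.size,
    )
    if not np.all(np.isfinite(W.matrix)):
        raise FloatingPointError("weight matrix diverged (NaN/overflow)")
    state = CorticalState(
        v=np.zeros(n_ctx), eta=eta, theta_v=theta_v, t=cfg.events.horizon
    )
    return SimResult(
        weights=W,
        snapshots=snapshots,
        schedule=schedule,
        h_onsets=arrays["h_onset"],
        h_eff=h_eff,
        h_eta=h_eta,
        state=state,
        config=cfg,
        seed=seed,
    )


def record_traces(
    cfg: SimConfig,
    duration: float,
    rng,
    state: CorticalState | None = None,
    W: Weights | None = None,
    dt: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, SimResult]:
    """Continue (or start) a simulation while sampling cortical rates.

    Plasticity stays on.  Returns ``(times, traces, result)`` where
    ``traces`` has shape (Nv, n_samples) at resolution ``dt`` — the
    high-resolution recording used by the event-detection analysis.
    """
    rng, seed = _rng_from(rng)
    cfg2 = replace(cfg, events=replace(cfg.events, horizon=duration),
                   engine="numpy", snapshot_times=())
    schedule = build_schedule(cfg2.events, rng)
    if W is None:
        W = init_weights(cfg2.network, cfg2.events.n_thal, cfg2.events.n_ctx, rng)
    else:
        W = W.copy()
    n_ctx = cfg2.events.n_ctx
    if state is None:
        eta = np.ones(n_ctx)
        theta_v = np.full(n_ctx, cfg2.plasticity.v0)
    else:
        eta = state.eta.copy()
        theta_v = state.theta_v.copy()
    l_onset, l_end, l_amp, l_off, l_flat = _event_arrays(
        schedule, "L", cfg2.events.n_thal
    )
    h_onset, h_end, h_amp, h_off, h_flat = _event_arrays(
        schedule, "H", cfg2.events.n_ctx
    )
    segs = _segments(l_onset, l_end, h_onset, h_end)
    n_samples = int(round(duration / dt))
    traces = np.zeros((n_ctx, n_samples))
    h_eff = np.full(h_amp.size, np.nan)
    h_eta = np.full(h_amp.size, np.nan)
    _run_segments_py(
        W.matrix, eta, theta_v, 0.0, *segs,
        l_amp, l_off, l_flat, h_amp, h_off, h_flat,
        cfg2.plasticity, W.wmax, h_eff, h_eta,
        traces=traces, trace_dt=dt, trace_t0=0.0,
    )
    times = dt * np.arange(n_samples)
    result = SimResult(
        weights=W, snapshots={}, schedule=schedule, h_onsets=h_onset,
        h_eff=h_eff, h_eta=h_eta,
        state=CorticalState(np.zeros(n_ctx), eta, theta_v, duration),
        config=cfg2, seed=seed,
    )
    return times, traces, result


# ---------------------------------------------------------------------------
# explicit-Euler oracle


def run_simulation_euler(cfg: SimConfig, rng, dt: float = 0.002) -> SimResult:
    """Full Euler integration of the membrane + learning dynamics.

    Uses the identical schedule and initial weights as :func:`run_simulation`
    under the same seed; serves as the independent numerical oracle for the
    quasi-static loop.  Between events the membrane decays freely and the
    loop fast-forwards once the rate is negligible.
    """
    if dt > cfg.network.tau_m / 5:
        raise ValueError("dt too large relative to tau_m")
    rng, seed = _rng_from(rng)
    schedule, W, segs, arrays = _prepare(cfg, rng)
    seg_t0, seg_dt, seg_l, seg_h = segs
    p = cfg.plasticity
    n_ctx, n_thal = W.matrix.shape
    tau_m = cfg.network.tau_m
    tau_w = p.tau_w_eff
    wmax = W.wmax
    is_bcm = p.rule == "bcm"
    v = np.zeros(n_ctx)
    eta = np.ones(n_ctx)
    theta_v = np.full(n_ctx, p.v0)
    h_eff = np.full(arrays["h_amp"].size, np.nan)
    h_eta = np.full(arrays["h_amp"].size, np.nan)
    vspon = np.zeros(n_ctx)
    u = np.zeros(n_thal)
    cur_h = -1
    t = 0.0
    m = W.matrix
    for s in range(seg_t0.size):
        t0, dseg = seg_t0[s], seg_dt[s]
        li, hi = int(seg_l[s]), int(seg_h[s])
        # free decay until the segment starts (weights barely move; the
        # Hebbian leak term -theta_u*v integrates to ~v*tau_m/tau_w ~ 1e-7)
        if t0 > t:
            gap = t0 - t
            if np.max(v) > 1e-12:
                n_relax = min(int(math.ceil(gap / dt)), int(10 * tau_m / dt))
                for _ in range(n_relax):
                    if not is_bcm:
                        raw = np.outer(v, -p.theta_u * np.ones(n_thal)) * (dt / tau_w)
                        raw = _apply_bounds(raw, m, wmax, p.bounds)
                        np.clip(m + raw, 0.0, wmax, out=m)
                    eta += dt / p.tau_eta * (-eta + v)
                    if is_bcm:
                        theta_v += dt / p.tau_theta * (-theta_v + v**2 / p.v0)
                    v += dt / tau_m * (-v)
                rest = gap - n_relax * dt
            else:
                rest = gap
            if rest > 0:
                v *= math.exp(-rest / tau_m)
                eta *= math.exp(-rest / p.tau_eta)
                if is_bcm:
                    theta_v *= math.exp(-rest / p.tau_theta)
            t = t0
        if hi != cur_h:
            vspon[:] = 0.0
            if hi >= 0:
                mem = arrays["h_flat"][arrays["h_off"][hi]: arrays["h_off"][hi + 1]]
                amp = effective_h_amplitude(eta[mem], arrays["h_amp"][hi], p.adaptive)
                vspon[mem] = amp
                h_eff[hi] = float(np.mean(vspon[mem]))
                h_eta[hi] = float(np.mean(eta[mem]))
            cur_h = hi
        u[:] = 0.0
        if li >= 0:
            u[arrays["l_flat"][arrays["l_off"][li]: arrays["l_off"][li + 1]]] = \
                arrays["l_amp"][li]
        drive = m @ u + vspon
        nst = int(math.ceil(dseg / dt))
        hh = dseg / nst
        for _ in range(nst):
            if not is_bcm:
                raw = np.outer(v, u - p.theta_u) * (hh / tau_w)
                raw = _apply_bounds(raw, m, wmax, p.bounds)
                np.clip(m + raw, 0.0, wmax, out=m)
            else:
                raw = np.outer(v * (v - theta_v), u) * (hh / tau_w)
                raw = _apply_bounds(raw, m, wmax, p.bounds)
                np.clip(m + raw, 0.0, wmax, out=m)
                theta_v += hh / p.tau_theta * (-theta_v + v**2 / p.v0)
            eta += hh / p.tau_eta * (-eta + v)
            if li >= 0:
                drive = m @ u + vspon  # weights move during the event
            v += hh / tau_m * (-v + drive)
        t = t0 + dseg
    state = CorticalState(v=v, eta=eta, theta_v=theta_v, t=cfg.events.horizon)
    return SimResult(
        weights=W, snapshots={}, schedule=schedule,
        h_onsets=arrays["h_onset"], h_eff=h_eff, h_eta=h_eta,
        state=state, config=cfg, seed=seed,
    )
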