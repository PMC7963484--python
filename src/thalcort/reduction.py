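"""Two-dimensional reduction of the Hebbian weight dynamics.

The Nv x Nu weight matrix is summarized by two scalars: the mean of the n
weights that form the receptive field of a cell (``w_rf``, contiguous and
centered on the topographic bias) and the mean of the remaining Nu - n
weights (``w_c``).  The reduced flow is the exact expectation of the
per-event Hebbian update over the L-event ensemble — size drawn as a
uniform fraction of the layer and position uniform on the ring, with the
circular overlap between the event block and the RF block enumerated
exactly — plus the mean depression exerted by H-events, expressed through
the dimensionless H-event strength

    <R_H> = (Lint / Hint) * <Hamp>      (durations and Lamp = 1 cancel).

Weight bounds follow the simulation's convention (hard clipping to
[0, wmax] by default, with the soft variants available), so the corners of
[0, wmax]^2 absorb trajectories: (wmax, 0) and (0, wmax) are selective
outcomes, (0, 0) is decoupled and (wmax, wmax) non-selective.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .plasticity import SimResult

__all__ = [
    "ReducedParams",
    "PhasePlaneResult",
    "strength_RH",
    "reduced_derivatives",
    "classify_basins",
    "adapted_strength",
    "selectivity_band",
]


def strength_RH(
    l_int_mean: float, h_int_mean: float, h_amp_mean: float
) -> float:
    """Rate gain of H- relative to L-drive: (Lint/Hint) * <Hamp>."""
    if l_int_mean <= 0 or h_int_mean <= 0 or h_amp_mean < 0:
        raise ValueError("intervals must be positive, amplitude non-negative")
    return l_int_mean / h_int_mean * h_amp_mean


@dataclass(frozen=True)
class ReducedParams:
    n_rf: int = 25
    n_total: int = 50
    theta_u: float = 0.5
    tau_w: float = 500.0
    l_amp: float = 1.0
    l_pct_range: tuple[float, float] = (0.2, 0.8)
    l_dur_mean: float = 0.15
    l_int_mean: float = 1.5
    h_pct_mean: float = 0.9
    h_strength: float = 2.571428571428571  # <R_H> at Table-1 means
    wmax: float = 0.5
    bounds: str = "hard"

    def __post_init__(self) -> None:
        if not 0 < self.n_rf < self.n_total:
            raise ValueError("need 0 < n_rf < n_total")
        if self.h_strength < 0:
            raise ValueError("h_strength must be non-negative")


@dataclass(frozen=True)
class PhasePlaneResult:
    area_selective: float
    area_non_selective: float
    area_decoupled: float
    labels: np.ndarray
    w_rf0: np.ndarray
    w_c0: np.ndarray
    n_unresolved: int


def _size_distribution(pct_range, n_total) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the integer event size round(p*N), p ~ U(pct_range)."""
    lo, hi = pct_range
    sizes = np.arange(int(np.ceil(lo * n_total - 0.5)),
                      int(np.floor(hi * n_total + 0.5)) + 1)
    # mass of p-interval mapping to each size by rounding
    left = np.maximum((sizes - 0.5) / n_total, lo)
    right = np.minimum((sizes + 0.5) / n_total, hi)
    mass = np.clip(right - left, 0.0, None)
    keep = (mass > 0) & (sizes >= 1)
    sizes, mass = sizes[keep], mass[keep]
    return sizes, mass / mass.sum()


@lru_cache(maxsize=64)
def _drift_coeffs(params: ReducedParams):
    """Expectation coefficients of the reduced flow, split by drift sign.

    Returns (pot_rf, dep_rf, pot_c, dep_c, h_dep) where each pot/dep entry
    is an (a, b) pair such that the corresponding drift magnitude is
    a*w_rf + b*w_c; all entries are non-negative.  Units: 1/s per unit
    weight.
    """
    n, N = params.n_rf, params.n_total
    theta = params.theta_u
    lam = params.l_amp
    sizes, probs = _size_distribution(params.l_pct_range, N)
    # RF block fixed at [0, n); event block start uniform over the ring
    in_rf = np.zeros(N, dtype=bool)
    in_rf[:n] = True
    pot_rf = np.zeros(2)
    dep_rf = np.zeros(2)
    pot_c = np.zeros(2)
    dep_c = np.zeros(2)
    for s, ps in zip(sizes, probs):
        for start in range(N):
            k = int(in_rf[(start + np.arange(s)) % N].sum())
            w_combo = ps / N
            vlin = np.array([k * lam, (s - k) * lam])  # v = vlin . (w_rf, w_c)
            coef_rf = lam * k / n - theta
            coef_c = lam * (s - k) / (N - n) - theta
            if coef_rf >= 0:
                pot_rf += w_combo * coef_rf * vlin
            else:
                dep_rf += w_combo * (-coef_rf) * vlin
            if coef_c >= 0:
                pot_c += w_combo * coef_c * vlin
            else:
                dep_c += w_combo * (-coef_c) * vlin
    scale = params.l_dur_mean / (params.l_int_mean * params.tau_w)
    # H-events: pure depression -theta_u * Hamp at rate 1/Hint for a cell
    # participating with probability h_pct_mean; Hamp/Hint = R_H / Lint
    h_dep = (
        theta
        * params.h_strength
        / params.l_int_mean
        * params.l_dur_mean
        * params.h_pct_mean
        / params.tau_w
    )
    return (
        pot_rf * scale,
        dep_rf * scale,
        pot_c * scale,
        dep_c * scale,
        h_dep,
    )


def reduced_derivatives(
    w_rf: np.ndarray | float,
    w_c: np.ndarray | float,
    params: ReducedParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-bounded drift (dw_rf/dt, dw_c/dt) of the reduced system."""
    pot_rf, dep_rf, pot_c, dep_c, h_dep = _drift_coeffs(params)
    w_rf = np.asarray(w_rf, dtype=float)
    w_c = np.asarray(w_c, dtype=float)
    wmax = params.wmax
    one = np.ones_like(w_rf)
    if params.bounds == "hard":
        up = dn = one
        up_c = dn_c = one
    elif params.bounds == "soft_potentiation":
        up, dn = (wmax - w_rf) / wmax, one
        up_c, dn_c = (wmax - w_c) / wmax, one
    else:
        up, dn = (wmax - w_rf) / wmax, w_rf / wmax
        up_c, dn_c = (wmax - w_c) / wmax, w_c / wmax
    d_rf = (pot_rf[0] * w_rf + pot_rf[1] * w_c) * up - (
        dep_rf[0] * w_rf + dep_rf[1] * w_c + h_dep
    ) * dn
    d_c = (pot_c[0] * w_rf + pot_c[1] * w_c) * up_c - (
        dep_c[0] * w_rf + dep_c[1] * w_c + h_dep
    ) * dn_c
    return d_rf, d_c


def classify_basins(
    params: ReducedParams,
    n_side: int = 50,
    tol: float = 1e-3,
    max_steps: int = 200_000,
    step_frac: float = 0.01,
) -> PhasePlaneResult:
    """Integrate a lattice of initial conditions and label their basins.

    The default 50 x 50 uniform lattice over [0, wmax]^2 gives the 2500
    initial conditions; each trajectory is integrated with an adaptive-step
    explicit scheme (global step bounded so the fastest point moves
    ``step_frac * wmax``) until it is within ``tol * wmax`` of a corner.
    Trajectories not absorbed within ``max_steps`` are labelled by the
    nearest corner and counted as unresolved.

    Labels: 0 selective, 1 non_selective, 2 decoupled.
    """
    wmax = params.wmax
    g = np.linspace(0.0, wmax, n_side)
    w_rf0, w_c0 = np.meshgrid(g, g, indexing="ij")
    w_rf = w_rf0.ravel().copy()
    w_c = w_c0.ravel().copy()
    atol = tol * wmax
    done = np.zeros(w_rf.size, dtype=bool)
    n_steps = 0
    while n_steps < max_steps:
        act = ~done
        if not act.any():
            break
        d_rf, d_c = reduced_derivatives(w_rf[act], w_c[act], params)
        vmax = max(np.max(np.abs(d_rf)), np.max(np.abs(d_c)), 1e-300)
        dt = step_frac * wmax / vmax
        w_rf[act] = np.clip(w_rf[act] + dt * d_rf, 0.0, wmax)
        w_c[act] = np.clip(w_c[act] + dt * d_c, 0.0, wmax)
        n_steps += 1
        if n_steps % 50 == 0:
            near_rf = np.minimum(w_rf, wmax - w_rf) < atol
            near_c = np.minimum(w_c, wmax - w_c) < atol
            cand = near_rf & near_c
            if cand.any():
                d_rf_all, d_c_all = reduced_derivatives(
                    w_rf[cand], w_c[cand], params
                )
                # absorbed only when the drift presses into the bound
                out_rf = np.where(
                    w_rf[cand] < atol, d_rf_all <= 0, d_rf_all >= 0
                )
                out_c = np.where(
                    w_c[cand] < atol, d_c_all <= 0, d_c_all >= 0
                )
                done = done.copy()
                done[np.nonzero(cand)[0][out_rf & out_c]] = True
    n_unresolved = int((~done).sum())
    hi_rf = w_rf > wmax / 2
    hi_c = w_c > wmax / 2
    labels = np.where(
        hi_rf ^ hi_c, 0, np.where(hi_rf & hi_c, 1, 2)
    ).astype(np.int8)
    n = labels.size
    return PhasePlaneResult(
        area_selective=float((labels == 0).sum() / n),
        area_non_selective=float((labels == 1).sum() / n),
        area_decoupled=float((labels == 2).sum() / n),
        labels=labels.reshape(n_side, n_side),
        w_rf0=w_rf0,
        w_c0=w_c0,
        n_unresolved=n_unresolved,
    )


def adapted_strength(sim: SimResult, final_frac: float = 0.05) -> float:
    """<R_H> recomputed from the mean effective H amplitude at stationarity.

    Requires an adaptive-rule simulation run with fixed (mean-valued)
    inter-event intervals; averages the eta-scaled H amplitudes over the
    final ``final_frac`` of simulated time.
    """
    cfg = sim.config
    if not cfg.plasticity.adaptive:
        raise ValueError("adapted strength requires the hebb_adaptive rule")
    t_cut = (1.0 - final_frac) * cfg.events.horizon
    late = sim.h_onsets >= t_cut
    vals = sim.h_eff[late]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no H-events in the final window")
    return strength_RH(
        cfg.events.l_int_mean, cfg.events.h_int_mean, float(vals.mean())
    )


def selectivity_band(
    params: ReducedParams,
    rh_values: np.ndarray,
    n_side: int = 50,
    frac: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep <R_H>; return (selective areas, mask of the maximizing band).

    The band collects strengths whose selective area is within ``frac`` of
    the sweep maximum.
    """
    from dataclasses import replace

    areas = np.array(
        [
            classify_basins(
                replace(params, h_strength=float(rh)), n_side=n_side
            ).area_selective
            for rh in rh_values
        ]
    )
    band = areas >= frac * areas.max()
    return areas, band
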