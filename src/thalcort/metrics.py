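"""Receptive-field statistics on the refined weight matrix.

A thalamic input belongs to a cortical cell's receptive field (RF) when its
weight exceeds ``wmax/5`` (robust to soft-bound fluctuations around zero).
The per-cell RF size is the suprathreshold count normalized by the input
layer; the network RF size averages over non-decoupled cells only, and is 0
when every cell has decoupled.  Topography compares each cell's RF center
with its matched diagonal position under periodic distance, normalized by
the error of a column receptive field, Xi = Nu^2/12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import Weights, matched_positions

__all__ = [
    "RFMetrics",
    "rf_size",
    "rf_center",
    "topography",
    "decoupling",
    "classify_outcome",
    "compute_metrics",
]

_EQ_TOL = 1e-9


def _as_matrix(W, wmax=None) -> tuple[np.ndarray, float]:
    if isinstance(W, Weights):
        return W.matrix, W.wmax
    if wmax is None:
        raise ValueError("pass wmax when W is a bare array")
    return np.asarray(W, dtype=float), float(wmax)


@dataclass(frozen=True)
class RFMetrics:
    rf_size: float
    topography: float | None
    decoupling: float
    outcome: Literal["selective", "non_selective", "decoupled"]
    rf_centers: tuple[float | None, ...]


def _supra(m: np.ndarray, wmax: float) -> np.ndarray:
    return m > wmax / 5.0


def rf_size(W, wmax: float | None = None) -> float:
    """Mean fraction of suprathreshold inputs over non-decoupled cells."""
    m, wmax = _as_matrix(W, wmax)
    ind = _supra(m, wmax)
    per_cell = ind.mean(axis=1)
    alive = per_cell > 0
    if not alive.any():
        return 0.0
    return float(per_cell[alive].mean())


def rf_center(row: np.ndarray, wmax: float) -> float | None:
    """Weighted least-squares circular center of the suprathreshold weights.

    Minimizes ``sum_i w_i d(i, c)^2`` over continuous positions c on the
    periodic index ring, by evaluating the weighted mean of every circular
    unwrapping (cut enumeration).  Returns None for a decoupled row; ties
    resolve to the smallest center (mod n).
    """
    row = np.asarray(row, dtype=float)
    n = row.size
    sel = row > wmax / 5.0
    if not sel.any():
        return None
    idx = np.nonzero(sel)[0].astype(float)
    w = row[sel]
    wsum = w.sum()
    best_cost = np.inf
    best_c = None
    for cut in range(len(idx)):
        # unwrap so that idx[cut] is the smallest coordinate
        pos = np.where(idx < idx[cut], idx + n, idx)
        c = float(np.sum(w * pos) / wsum)
        cost = float(np.sum(w * (pos - c) ** 2))
        c_mod = c % n
        if cost < best_cost - _EQ_TOL or (
            abs(cost - best_cost) <= _EQ_TOL
            and best_c is not None
            and c_mod < best_c
        ):
            best_cost = cost
            best_c = c_mod
    return best_c


def topography(W, wmax: float | None = None, clip: bool = True) -> float | None:
    """Topography score: 1 - xi/Xi with Xi = Nu^2/12.

    xi is the mean squared periodic deviation of RF centers from the matched
    diagonal position, over cells that still have a receptive field.
    Returns None when every cell has decoupled.  Scores below 0 (worse than
    a column RF) are clipped to 0 unless ``clip=False``.
    """
    m, wmax = _as_matrix(W, wmax)
    n_ctx, n_thal = m.shape
    diag = matched_positions(n_ctx, n_thal)
    errs = []
    for j in range(n_ctx):
        c = rf_center(m[j], wmax)
        if c is None:
            continue
        d = abs(c - diag[j])
        d = min(d, n_thal - d)
        errs.append(d * d)
    if not errs:
        return None
    xi = float(np.mean(errs))
    big_xi = n_thal**2 / 12.0
    score = 1.0 - xi / big_xi
    return max(score, 0.0) if clip else score


def decoupling(W, wmax: float | None = None) -> float:
    """Fraction of cortical cells with no suprathreshold incoming weight."""
    m, wmax = _as_matrix(W, wmax)
    return float(np.mean(~_supra(m, wmax).any(axis=1)))


def classify_outcome(rf: float) -> str:
    """Map the average RF size to selective / non_selective / decoupled."""
    if not 0.0 <= rf <= 1.0 + _EQ_TOL:
        raise ValueError("rf size must lie in [0, 1]")
    if rf <= _EQ_TOL:
        return "decoupled"
    if rf >= 1.0 - _EQ_TOL:
        return "non_selective"
    return "selective"


def compute_metrics(W, wmax: float | None = None) -> RFMetrics:
    """All receptive-field statistics of one weight matrix."""
    m, wmax = _as_matrix(W, wmax)
    centers = tuple(rf_center(m[j], wmax) for j in range(m.shape[0]))
    size = rf_size(m, wmax)
    return RFMetrics(
        rf_size=size,
        topography=topography(m, wmax),
        decoupling=decoupling(m, wmax),
        outcome=classify_outcome(size),
        rf_centers=centers,
    )
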