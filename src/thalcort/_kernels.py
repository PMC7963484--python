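"""Numba-compiled inner loop of the quasi-static simulation.

Semantics match ``plasticity._run_segments_py`` exactly; the Monte Carlo
grid experiments rely on this kernel for speed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_segments_numba(
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
    is_bcm,
    adaptive,
    soft,
    theta_u,
    tau_w,
    wmax,
    v0,
    tau_theta,
    tau_eta,
    h_eff,
    h_eta,
):
    n_ctx, n_thal = W.shape
    vspon = np.zeros(n_ctx)
    u = np.zeros(n_thal)
    v = np.zeros(n_ctx)
    cur_h = -1
    for s in range(seg_t0.shape[0]):
        t0 = seg_t0[s]
        dt = seg_dt[s]
        gap = t0 - t_prev
        if gap > 0.0:
            de = math.exp(-gap / tau_eta)
            for j in range(n_ctx):
                eta[j] *= de
            if is_bcm == 1:
                dth = math.exp(-gap / tau_theta)
                for j in range(n_ctx):
                    theta_v[j] *= dth
        li = seg_l[s]
        hi = seg_h[s]
        if hi != cur_h:
            for j in range(n_ctx):
                vspon[j] = 0.0
            if hi >= 0:
                acc = 0.0
                acc_eta = 0.0
                cnt = 0
                for m in range(h_off[hi], h_off[hi + 1]):
                    j = h_flat[m]
                    if adaptive == 1:
                        vspon[j] = eta[j] * h_amp[hi]
                    else:
                        vspon[j] = h_amp[hi]
                    acc += vspon[j]
                    acc_eta += eta[j]
                    cnt += 1
                h_eff[hi] = acc / cnt
                h_eta[hi] = acc_eta / cnt
            cur_h = hi
        # presynaptic drive and quasi-static rate
        for i in range(n_thal):
            u[i] = 0.0
        if li >= 0:
            for m in range(l_off[li], l_off[li + 1]):
                u[l_flat[m]] = l_amp[li]
            for j in range(n_ctx):
                acc = 0.0
                for m in range(l_off[li], l_off[li + 1]):
                    acc += W[j, l_flat[m]]
                v[j] = acc * l_amp[li] + (vspon[j] if hi >= 0 else 0.0)
        else:
            for j in range(n_ctx):
                v[j] = vspon[j] if hi >= 0 else 0.0
        # weight update over the segment
        c = dt / tau_w
        if is_bcm == 0:
            for j in range(n_ctx):
                vj = v[j]
                if vj == 0.0:
                    continue
                for i in range(n_thal):
                    raw = vj * (u[i] - theta_u) * c
                    w = W[j, i]
                    if raw > 0.0:
                        if soft >= 1:
                            raw *= (wmax - w) / wmax
                    elif soft == 2:
                        raw *= w / wmax
                    w += raw
                    if w < 0.0:
                        w = 0.0
                    elif w > wmax:
                        w = wmax
                    W[j, i] = w
        else:
            if li >= 0:
                for j in range(n_ctx):
                    a = v[j] * (v[j] - theta_v[j]) * c
                    if a == 0.0:
                        continue
                    for m in range(l_off[li], l_off[li + 1]):
                        i = l_flat[m]
                        raw = a * l_amp[li]
                        w = W[j, i]
                        if raw > 0.0:
                            if soft >= 1:
                                raw *= (wmax - w) / wmax
                        elif soft == 2:
                            raw *= w / wmax
                        w += raw
                        if w < 0.0:
                            w = 0.0
                        elif w > wmax:
                            w = wmax
                        W[j, i] = w
            nsub = int(math.ceil(dt / (tau_theta / 20.0)))
            if nsub < 1:
                nsub = 1
            hsub = dt / nsub
            for _ in range(nsub):
                for j in range(n_ctx):
                    theta_v[j] += hsub / tau_theta * (
                        -theta_v[j] + v[j] * v[j] / v0
                    )
        # exact adaptation-trace update for piecewise-constant v
        de = math.exp(-dt / tau_eta)
        for j in range(n_ctx):
            eta[j] = v[j] + (eta[j] - v[j]) * de
        t_prev = t0 + dt
    return t_prev
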