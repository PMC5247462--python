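"""Numba hot loop for the coupled three-module network.

The full system (V1 field, V2 border-ownership field, parietal field, two
inhibitory units) is advanced with classical RK4 at a fixed step.  Two
structural facts keep this affordable:

* The transfer function is exactly zero below rheobase (tau*A <= 1), so a
  unit whose activity stays sub-rheobase emits no rate and receives no
  recurrent term: its equation is affine and one RK4 step has the closed
  form ``A' = u + rho * (A - u)`` with ``rho`` the RK4 stability
  polynomial of ``-dt/tau``.  Only the "active" subset (units with drive
  support or activity near rheobase) runs the full nonlinear stages.
* Surround convolutions and the parietal afferent change on the slow
  membrane timescale, so they are refreshed every ``couple_every`` steps
  by the caller and held constant in between, like the per-step noise.

Active sets are recomputed at every refresh with a promotion threshold of
half the rheobase; within one refresh interval (<= 2 ms at the default
settings) a sub-threshold unit cannot drift from that threshold to
rheobase, so the affine update is exact for every unit it is applied to.
The only approximation on the affine path concerns V1 units whose drive is
too small ever to reach rheobase: they are integrated with unit attention
gain (their drive would otherwise track the parietal feedback), which
cannot change any emitted rate because they stay silent either way.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["advance_chunk", "rk4_linear_factor"]


def rk4_linear_factor(dt: float, tau: float) -> float:
    """RK4 stability polynomial R(z) at z = -dt/tau (affine-update factor)."""
    z = -dt / tau
    return 1.0 + z + z**2 / 2.0 + z**3 / 6.0 + z**4 / 24.0


@njit(cache=True, fastmath=True)
def _transfer(x: float, tau: float, tr: float) -> float:
    tx = tau * x
    if tx > 1.0 + 1e-12:
        return 1.0 / (tr - tau * math.log1p(-1.0 / tx))
    return 0.0


@njit(cache=True, fastmath=True)
def advance_chunk(
    a1, a2, ap, inh,          # states: (n1,), (n2,), (hw,), (2,) [v2_inh, pp_inh]
    act1, act2, actp,         # int64 index arrays of the active subsets
    act1_px, act2_px,         # pixel index of each active unit
    contrast, inv_pool,       # (n1,), (hw,): static per stimulus epoch
    c0,                       # (n1,): unit-gain V1 drive for the affine path
    o2,                       # (n2,): frozen surround term (gain applied)
    aff_cue,                  # (hw,): frozen afferent + attention drive
    noise,                    # (nsteps, n1 + n2 + hw), float32
    nu_out,                   # (nsteps,): BO signal in Hz after each step
    crf_idx,                  # pixel indices of the readout nodes
    dt, tau, tr, mu, gamma, lam, kap2, kapp, w_fb, w1, pp_floor, rho,
    n_types, hw,
):
    n1 = a1.size
    n2 = a2.size
    na1 = act1.size
    na2 = act2.size
    nap = actp.size
    nsteps = noise.shape[0]

    drive1 = np.empty(na1)
    drive2 = np.empty(na2)
    s_map = np.empty(hw)
    eta1 = np.empty(na1)
    eta2 = np.empty(na2)
    etap = np.empty(nap)
    affp = np.empty(nap)

    y1 = np.empty(na1); k1sum = np.empty(na1); k1 = np.empty(na1)
    y2 = np.empty(na2); k2sum = np.empty(na2); k2 = np.empty(na2)
    yp = np.empty(nap); kpsum = np.empty(nap); kp = np.empty(nap)

    for pi in range(nap):
        affp[pi] = aff_cue[actp[pi]]

    for t in range(nsteps):
        # --- per-step frozen quantities -------------------------------
        for p in range(hw):
            s_map[p] = 0.0
        m = pp_floor  # parietal feedback normalization: field max, floored
        for pi in range(nap):
            v = ap[actp[pi]]
            if v > m:
                m = v
            etap[pi] = noise[t, n1 + n2 + actp[pi]]

        # V1 drive: attention-scaled contrast over the divisive pool;
        # the pooled V1 rate map feeds O1 and the inhibitory sums below
        for ii in range(na1):
            i = act1[ii]
            p = act1_px[ii]
            y1[ii] = a1[i]
            f = _transfer(y1[ii], tau, tr)
            if f > 0.0:
                s_map[p] += f
            g = ap[p]
            if g < 0.0:
                g = 0.0
            d = contrast[i] * math.exp(w_fb * g / m) * inv_pool[p]
            if d > 2.0:
                d = 2.0
            drive1[ii] = d
            eta1[ii] = noise[t, i]

        f_i2 = _transfer(inh[0], tau, tr)
        f_ip = _transfer(inh[1], tau, tr)
        i2_0 = inh[0]; ip_0 = inh[1]
        i2sum = 0.0; ipsum = 0.0
        ki2 = 0.0; kip = 0.0

        # --- RK4 stages (noise and drives frozen within the step) ------
        for stage in range(4):
            if stage == 0:
                h = 0.0
            elif stage == 3:
                h = dt
            else:
                h = 0.5 * dt
            w = 2.0 if stage == 1 or stage == 2 else 1.0
            i2t = i2_0 + h * ki2
            ipt = ip_0 + h * kip
            f_i2t = _transfer(i2t, tau, tr)
            f_ipt = _transfer(ipt, tau, tr)

            sum2 = 0.0
            if stage == 0:
                # stage 0 also assembles the V2 drive from the current O1
                for jj in range(na2):
                    j = act2[jj]
                    o1 = w1 * s_map[act2_px[jj]]
                    d2 = o1 * (o1 + o2[j])
                    drive2[jj] = d2
                    e = noise[t, n1 + j]
                    eta2[jj] = e
                    yt = a2[j]
                    y2[jj] = yt
                    f = _transfer(yt, tau, tr)
                    sum2 += f
                    k = (-yt + mu * f - gamma * f_i2t + d2 + e) / tau
                    k2[jj] = k
                    k2sum[jj] = k
            else:
                for jj in range(na2):
                    yt = y2[jj] + h * k2[jj]
                    f = _transfer(yt, tau, tr)
                    sum2 += f
                    k = (-yt + mu * f - gamma * f_i2t + drive2[jj] + eta2[jj]) / tau
                    if stage < 3:
                        k2[jj] = k
                    k2sum[jj] += w * k
            ki2 = (-i2t + lam * f_i2t + kap2 * sum2) / tau
            i2sum = ki2 if stage == 0 else i2sum + w * ki2

            sump = 0.0
            if stage == 0:
                for pi in range(nap):
                    yt = ap[actp[pi]]
                    yp[pi] = yt
                    f = _transfer(yt, tau, tr)
                    sump += f
                    k = (-yt + mu * f - gamma * f_ipt + affp[pi] + etap[pi]) / tau
                    kp[pi] = k
                    kpsum[pi] = k
            else:
                for pi in range(nap):
                    yt = yp[pi] + h * kp[pi]
                    f = _transfer(yt, tau, tr)
                    sump += f
                    k = (-yt + mu * f - gamma * f_ipt + affp[pi] + etap[pi]) / tau
                    if stage < 3:
                        kp[pi] = k
                    kpsum[pi] += w * k
            kip = (-ipt + lam * f_ipt + kapp * sump) / tau
            ipsum = kip if stage == 0 else ipsum + w * kip

            if stage == 0:
                for ii in range(na1):
                    yt = y1[ii]
                    f = _transfer(yt, tau, tr)
                    k = (-yt + mu * f + drive1[ii] + eta1[ii]) / tau
                    k1[ii] = k
                    k1sum[ii] = k
            else:
                for ii in range(na1):
                    yt = y1[ii] + h * k1[ii]
                    f = _transfer(yt, tau, tr)
                    k = (-yt + mu * f + drive1[ii] + eta1[ii]) / tau
                    if stage < 3:
                        k1[ii] = k
                    k1sum[ii] += w * k

        sixth = dt / 6.0
        for ii in range(na1):
            a1[act1[ii]] = y1[ii] + sixth * k1sum[ii]
        for jj in range(na2):
            a2[act2[jj]] = y2[jj] + sixth * k2sum[jj]
        for pi in range(nap):
            ap[actp[pi]] = yp[pi] + sixth * kpsum[pi]
        inh[0] = i2_0 + sixth * i2sum
        inh[1] = ip_0 + sixth * ipsum

        # --- affine update of every sub-rheobase (inactive) unit --------
        # Inactive units carry their (tiny or inhibitory) input exactly;
        # they cannot fire, so the step has the closed linear-RK4 form.
        mark1 = 0
        for i in range(n1):
            if mark1 < na1 and act1[mark1] == i:
                mark1 += 1
                continue
            u = c0[i] + noise[t, i]
            a1[i] = u + rho * (a1[i] - u)
        g_i2 = -gamma * f_i2
        mark2 = 0
        for j in range(n2):
            if mark2 < na2 and act2[mark2] == j:
                mark2 += 1
                continue
            u = g_i2 + noise[t, n1 + j]
            a2[j] = u + rho * (a2[j] - u)
        g_ip = -gamma * f_ip
        markp = 0
        for p in range(hw):
            if markp < nap and actp[markp] == p:
                markp += 1
                continue
            u = aff_cue[p] + g_ip + noise[t, n1 + n2 + p]
            ap[p] = u + rho * (ap[p] - u)

        # --- BO signal at the recorded location ------------------------
        nu = 0.0
        for k in range(n_types):
            for q in range(crf_idx.size):
                nu += _transfer(a2[k * hw + crf_idx[q]], tau, tr)
        for k in range(n_types, 2 * n_types):
            for q in range(crf_idx.size):
                nu -= _transfer(a2[k * hw + crf_idx[q]], tau, tr)
        nu_out[t] = 1000.0 * nu / crf_idx.size

        if not (math.isfinite(nu_out[t]) and math.isfinite(inh[0])):
            return t  # signal NaN/overflow to the caller
    return nsteps
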