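"""Numba forward-Euler beat integrator.

One generic kernel integrates any model expressed as a :class:`TableSet`
(tabulated gate kinetics + current topology), so the reference family and the
toy fixture model share a single compiled code path.

Time is handled in integer ticks of ``dt_min`` so that stimulus, sample-grid
and beat boundaries are exact: the adaptive rule takes ``nsub`` ticks
(``dt_max``) only when the membrane is slow (|dV/dt| below threshold), the
stimulus is off, and the step starts on a ``dt_max``-aligned tick, which
guarantees no step ever crosses a stimulus or sample boundary.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True, fastmath=True)
def integrate_beat(y, G, POW, DRIVE, ISCA, EREV, RECT, CAFLX, XINF, TAU,
                   v0, dv, cao, k_ca, tau_ca, ca_rest,
                   stim_signed, cl_ticks, stim_ticks, nsub, dt_min, dvdt_thr,
                   out_every, Vout, Iout, CaOut):
    """Advance state ``y`` through one beat, recording on the output grid.

    Returns (status, max_gate_excursion, fail_time_ms).
    """
    nC = G.shape[0]
    nG = XINF.shape[0]
    nV = XINF.shape[1]
    lastI = np.empty(nC)
    max_exc = 0.0
    t = 0
    half_rtf = 13.356  # RT/2F in mV

    while True:
        V = y[0]
        # table index
        x = (V - v0) / dv
        if x < 0.0:
            x = 0.0
        elif x > nV - 1.000001:
            x = nV - 1.000001
        i0 = int(x)
        w = x - i0

        cai = y[1 + nG]
        e_ca = half_rtf * math.log(cao / cai)

        sumI = 0.0
        caflux = 0.0
        for c in range(nC):
            val = G[c] * (RECT[c, i0] + w * (RECT[c, i0 + 1] - RECT[c, i0]))
            for g in range(nG):
                p = POW[c, g]
                for _ in range(p):
                    val *= y[1 + g]
            if ISCA[c] == 1:
                val *= (V - e_ca)
            elif DRIVE[c] == 1:
                val *= (V - EREV[c])
            lastI[c] = val
            sumI += val
            caflux += CAFLX[c] * val

        # record at sample times (state and currents at time t, pre-step)
        if t % out_every == 0:
            k = t // out_every
            Vout[k] = V
            CaOut[k] = cai
            for c in range(nC):
                Iout[c, k] = lastI[c]

        if t >= cl_ticks:
            break

        in_stim = t < stim_ticks
        istim = stim_signed if in_stim else 0.0
        dvdt = -(sumI + istim)

        use_min = in_stim or (abs(dvdt) > dvdt_thr) or (t % nsub != 0)
        n = 1 if use_min else nsub
        if t + n > cl_ticks:
            n = cl_ticks - t
        dt = dt_min * n

        y[0] = V + dt * dvdt
        for g in range(nG):
            xi = XINF[g, i0] + w * (XINF[g, i0 + 1] - XINF[g, i0])
            ta = TAU[g, i0] + w * (TAU[g, i0 + 1] - TAU[g, i0])
            yn = y[1 + g] + dt * (xi - y[1 + g]) / ta
            if yn < 0.0:
                if -yn > max_exc:
                    max_exc = -yn
                yn = 0.0
            elif yn > 1.0:
                if yn - 1.0 > max_exc:
                    max_exc = yn - 1.0
                yn = 1.0
            y[1 + g] = yn
        ca = cai + dt * (-k_ca * caflux - (cai - ca_rest) / tau_ca)
        if ca < 1.0e-9:
            ca = 1.0e-9
        y[1 + nG] = ca

        t += n

        if not math.isfinite(y[0]) or y[0] < -150.0 or y[0] > 80.0:
            return STATUS_NONFINITE, max_exc, t * dt_min

    return STATUS_OK, max_exc, 0.0
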