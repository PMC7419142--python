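"""Numba kernel for the Euler integration of the LIF network.

The network state is advanced one Euler step at a time.  Output currents
are handled with circular buffers of length ``len(psc_wave)``: when a
neuron fires, the postsynaptic-current template is added to its future
output-current slots; when a stimulus spike arrives, the same template is
added to the neuron's private input buffer.  During an action potential the
membrane potential is overwritten by the AP template and threshold
detection is suspended (template playback acts as the refractory period).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def integrate(
    M_T,          # (N, N) float64, M_T[i, j] = weight from presynaptic j onto i
    g_leak,       # (N,) float64, leak conductance in siemens
    C_m,          # (N,) float64, capacitance in farads
    V0,           # resting potential (V)
    Vthr,         # threshold (V)
    stim_counts,  # (N, T) int16, stimulus spike counts per neuron per step
    i_ext,        # (N, T) float64 injected current (A); (1, 1) when unused
    ap_wave,      # (K,) float64, AP template samples (V)
    psc_wave,     # (L,) float64, PSC template samples (A)
    dt,           # step (s)
    record_v,     # bool: record membrane traces
):
    N, T = stim_counts.shape
    K = ap_wave.size
    L = psc_wave.size

    V = np.full(N, V0)
    ap_pos = np.full(N, -1, np.int64)
    spikes = np.zeros((N, T), np.bool_)
    out_buf = np.zeros((N, L))
    in_buf = np.zeros((N, L))
    if record_v:
        V_trace = np.zeros((N, T))
    else:
        V_trace = np.zeros((1, 1))

    bad_neuron = -1
    bad_step = -1
    use_iext = i_ext.shape[0] == N

    for t in range(T):
        col = t % L
        I_out = out_buf[:, col].copy()
        I_in_stim = in_buf[:, col].copy()
        for i in range(N):
            out_buf[i, col] = 0.0
            in_buf[i, col] = 0.0

        # inject PSC templates for stimulus spikes arriving this step
        for i in range(N):
            c = stim_counts[i, t]
            if c > 0:
                for k in range(L):
                    in_buf[i, (t + k) % L] += c * psc_wave[k]

        I_syn = np.dot(M_T, I_out)

        for i in range(N):
            if ap_pos[i] >= 0:
                # template playback; no integration, no threshold detection
                V[i] = ap_wave[ap_pos[i]]
                ap_pos[i] += 1
                if ap_pos[i] >= K:
                    ap_pos[i] = -1
            else:
                I_total = I_syn[i] + I_in_stim[i]
                if use_iext:
                    I_total += i_ext[i, t]
                V[i] += dt * ((V0 - V[i]) * g_leak[i] + I_total) / C_m[i]
                if not np.isfinite(V[i]):
                    bad_neuron = i
                    bad_step = t
                    break
                if V[i] >= Vthr:
                    spikes[i, t] = True
                    V[i] = ap_wave[0]
                    ap_pos[i] = 1
                    for k in range(L):
                        out_buf[i, (t + k) % L] += psc_wave[k]
            if record_v:
                V_trace[i, t] = V[i]
        if bad_neuron >= 0:
            break

    return spikes, V_trace, bad_neuron, bad_step
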