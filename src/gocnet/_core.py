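"""Numba time-stepping kernel for the network simulation.

One flat neuron array holds granule cells first, then Golgi cells. Synaptic
conductances are kept per (receptor, neuron) as two exponential state
variables with exact per-step decay; delayed events are accumulated in a
ring buffer of weight arrivals quantized to the time step. Gap-junction
currents use previous-step voltages (explicit coupling). The update order
per neuron matches ``neurons.step_neuron`` exactly.

Error codes returned in ``status[0]``: 0 ok, 1 non-finite state (neuron and
step in status[1:3]), 2 spike-buffer overflow.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_core(dt, n_steps, n_gc,
             # per-neuron parameters (length N)
             c, g1, e1, g2, e2, gna, vt, dti, na_on,
             v_reset, v_peak, v_detect, tref_steps,
             ahp_b, ahp_decay, e_ahp,
             # receptor constants (length 3)
             rec_e, dec_r, dec_d, norm,
             # internal outgoing synapses, CSR over neurons
             out_ptr, out_post, out_rec, out_w, out_d,
             # mossy-fiber outgoing synapses, CSR over fibers
             mf_ptr, mf_post, mf_rec, mf_w, mf_d,
             # mossy-fiber spikes sorted by step
             mf_steps, mf_fiber,
             # gap junctions (global indices)
             gj_a, gj_b, gj_g,
             # external drive
             i_const, sin_amp_pA, sin_freq_hz, sin_mask,
             # state (modified in place)
             v, g_ahp,
             # ring buffer slot count
             S,
             # recording
             trace_ids, trace_every, traces,
             spike_i, spike_t, status):
    N = c.shape[0]
    g_r = np.zeros((3, N))
    g_d = np.zeros((3, N))
    buf = np.zeros((S, 3, N))
    refrac = np.zeros(N, dtype=np.int64)
    pending = np.zeros(N, dtype=np.uint8)
    i_gap = np.zeros(N)
    n_spikes = 0
    mp = 0
    n_mf_events = mf_steps.shape[0]
    max_spikes = spike_i.shape[0]
    n_traces = trace_ids.shape[0]
    two_pi = 2.0 * math.pi

    for s in range(n_steps):
        slot = s % S
        # decay conductance states and take up this step's arrivals
        for r in range(3):
            dr = dec_r[r]
            dd = dec_d[r]
            nm = norm[r]
            for i in range(N):
                a = buf[slot, r, i]
                gr = g_r[r, i] * dr
                gd = g_d[r, i] * dd
                if a != 0.0:
                    gr += a * nm
                    gd += a * nm
                    buf[slot, r, i] = 0.0
                g_r[r, i] = gr
                g_d[r, i] = gd

        # mossy-fiber spikes arriving at this step
        while mp < n_mf_events and mf_steps[mp] == s:
            f = mf_fiber[mp]
            for k in range(mf_ptr[f], mf_ptr[f + 1]):
                buf[(s + mf_d[k]) % S, mf_rec[k], mf_post[k]] += mf_w[k]
            mp += 1

        # gap-junction currents from previous-step voltages
        for i in range(N):
            i_gap[i] = 0.0
        for p in range(gj_a.shape[0]):
            a = gj_a[p]
            b = gj_b[p]
            cur = gj_g[p] * (v[b] - v[a])
            i_gap[a] += cur
            i_gap[b] -= cur

        t_ms = s * dt
        sin_i = 0.0
        if sin_amp_pA != 0.0:
            sin_i = sin_amp_pA * math.sin(two_pi * sin_freq_hz * t_ms / 1000.0)

        for i in range(N):
            vi = v[i]
            if pending[i] == 1:
                vi = v_reset[i]
                g_ahp[i] += ahp_b[i]
                pending[i] = 0
            g_ahp[i] *= ahp_decay[i]

            cur = g1[i] * (e1[i] - vi) + g2[i] * (e2[i] - vi)
            if na_on[i] == 1:
                arg = (vi - vt[i]) / dti[i]
                if arg > 16.0:
                    arg = 16.0
                cur += gna[i] * dti[i] * math.exp(arg)
            cur += g_ahp[i] * (e_ahp[i] - vi)
            for r in range(3):
                cur += (g_d[r, i] - g_r[r, i]) * (rec_e[r] - vi)
            cur += i_gap[i] + i_const[i] + sin_i * sin_mask[i]

            vi = vi + dt * cur / c[i]
            if vi > v_peak[i]:
                vi = v_peak[i]

            if refrac[i] > 0:
                refrac[i] -= 1
            elif na_on[i] == 1 and vi >= v_detect[i]:
                # spike: pin at peak for one step, reset next step
                vi = v_peak[i]
                pending[i] = 1
                refrac[i] = tref_steps[i]
                if n_spikes >= max_spikes:
                    status[0] = 2
                    status[2] = s
                    return n_spikes
                spike_i[n_spikes] = i
                spike_t[n_spikes] = t_ms
                n_spikes += 1
                for k in range(out_ptr[i], out_ptr[i + 1]):
                    buf[(s + out_d[k]) % S, out_rec[k], out_post[k]] += out_w[k]
            v[i] = vi

        if n_traces > 0 and s % trace_every == 0:
            idx = s // trace_every
            if idx < traces.shape[1]:
                for k in range(n_traces):
                    traces[k, idx] = v[trace_ids[k]]

        if s % 2000 == 0:
            for i in range(N):
                if not math.isfinite(v[i]):
                    status[0] = 1
                    status[1] = i
                    status[2] = s
                    return n_spikes

    for i in range(N):
        if not math.isfinite(v[i]):
            status[0] = 1
            status[1] = i
            status[2] = n_steps - 1
            return n_spikes
    return n_spikes
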