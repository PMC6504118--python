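"""Numba inner loop of the network integrator.

The network state is advanced on a fixed grid (default 0.1 ms).  Per step
and neuron: delayed spike arrivals are folded into the receptor state
variables, receptor conductances are summed per receptor family (NMDA gated
by the magnesium block at the current membrane potential, held fixed within
the step), the membrane potential and adaptation current are advanced with
one classical RK4 step, threshold crossings are reset and queued for
delivery, and the receptor states decay by their exact per-step exponential
factors.

Receptor state layout: 16 exponential components per neuron, 4 slots per
receptor family in the order AMPA, NMDA, GABA_A, GABA_B (unused slots carry
zero increment and zero decay).  Spike arrival with weight w increments the
active components of the matching polarity by w * comp_inc, which makes the
summed conductance the exact superposition of single-spike transients on the
grid.
"""

import numpy as np
from numba import njit

#: per-family slot ranges in the 16-component state layout
SLOTS = {"AMPA": (0, 4), "NMDA": (4, 8), "GABA_A": (8, 12), "GABA_B": (12, 16)}
N_COMP = 16

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_NOT_FINITE = 2


@njit(cache=True)
def run_network(
    n_steps, dt, n_exc,
    # per-neuron parameters
    EL, Vth, Vr, gL, Cm, ref_steps, a, b, inv_tau_w, mg_coef, E_ga, E_gb,
    # receptor components (N, 16)
    comp_inc, comp_decay,
    # connectivity, CSR by source neuron
    src_ptr, edge_dst, edge_w, edge_dsteps,
    # background Poisson drive
    bg_lambda, bg_w, bg_dsteps,
    # injected current signal
    inj_amp, u_seq, steps_per_input,
    # externally forced presynaptic spikes (sorted by step)
    forced_steps, forced_ids,
    # initial state
    V, w_adapt,
    # rng
    seed,
    # recording
    rec_every, v_rec_idx, cur_rec_idx,
    V_rec, Iexc_rec, Iinh_rec, G_sum,
    # spike output
    spike_step, spike_id,
):
    N = len(EL)
    D = 2
    for e in range(len(edge_dsteps)):
        if edge_dsteps[e] + 2 > D:
            D = edge_dsteps[e] + 2
    for i in range(N):
        if bg_dsteps[i] + 2 > D:
            D = bg_dsteps[i] + 2

    np.random.seed(seed)
    bufE = np.zeros((D, N))
    bufI = np.zeros((D, N))
    comp = np.zeros((N, N_COMP))
    refr_until = np.zeros(N, dtype=np.int64)
    sp_ids = np.empty(N, dtype=np.int64)
    max_spikes = len(spike_step)
    n_spikes = 0
    n_u = len(u_seq)
    fptr = 0
    n_forced = len(forced_steps)

    for t in range(n_steps):
        slot = t % D
        # deliver externally forced presynaptic spikes through the neuron's
        # outgoing synapses (the neuron itself does not fire)
        while fptr < n_forced and forced_steps[fptr] == t:
            i = forced_ids[fptr]
            exc = i < n_exc
            for e in range(src_ptr[i], src_ptr[i + 1]):
                tgt_slot = (t + edge_dsteps[e]) % D
                if exc:
                    bufE[tgt_slot, edge_dst[e]] += edge_w[e]
                else:
                    bufI[tgt_slot, edge_dst[e]] += edge_w[e]
            fptr += 1
        n_sp = 0
        for i in range(N):
            # fold delayed arrivals into the receptor states
            he = bufE[slot, i]
            if he != 0.0:
                for c in range(8):
                    comp[i, c] += he * comp_inc[i, c]
                bufE[slot, i] = 0.0
            hi = bufI[slot, i]
            if hi != 0.0:
                for c in range(8, N_COMP):
                    comp[i, c] += hi * comp_inc[i, c]
                bufI[slot, i] = 0.0
            # background input, queued at its own delay
            if bg_lambda[i] > 0.0:
                cnt = np.random.poisson(bg_lambda[i])
                if cnt > 0:
                    bufE[(t + bg_dsteps[i]) % D, i] += cnt * bg_w[i]

            Vi = V[i]
            wi = w_adapt[i]
            gA = comp[i, 0] + comp[i, 1] + comp[i, 2] + comp[i, 3]
            gN_raw = comp[i, 4] + comp[i, 5] + comp[i, 6] + comp[i, 7]
            gGa = comp[i, 8] + comp[i, 9] + comp[i, 10] + comp[i, 11]
            gGb = comp[i, 12] + comp[i, 13] + comp[i, 14] + comp[i, 15]
            gate = 1.0 / (1.0 + mg_coef[i] * np.exp(-0.062 * Vi))
            gN = gN_raw * gate
            G_sum[i] += gL[i] + gA + gN + gGa + gGb

            Ii = 0.0
            if steps_per_input > 0 and inj_amp[i] != 0.0:
                n_in = t // steps_per_input
                if n_in >= n_u:
                    n_in = n_u - 1
                Ii = inj_amp[i] * u_seq[n_in]

            if t >= refr_until[i]:
                # one RK4 step of the coupled (V, I_adapt) dynamics with the
                # synaptic conductances held fixed across the step
                gLi = gL[i]
                ELi = EL[i]
                iCm = 1.0 / Cm[i]
                ai = a[i]
                itw = inv_tau_w[i]
                Ega = E_ga[i]
                Egb = E_gb[i]

                kv1 = (-gLi * (Vi - ELi) - wi - gA * Vi - gN * Vi
                       - gGa * (Vi - Ega) - gGb * (Vi - Egb) + Ii) * iCm
                kw1 = (ai * (Vi - ELi) - wi) * itw
                V2 = Vi + 0.5 * dt * kv1
                w2 = wi + 0.5 * dt * kw1
                kv2 = (-gLi * (V2 - ELi) - w2 - gA * V2 - gN * V2
                       - gGa * (V2 - Ega) - gGb * (V2 - Egb) + Ii) * iCm
                kw2 = (ai * (V2 - ELi) - w2) * itw
                V3 = Vi + 0.5 * dt * kv2
                w3 = wi + 0.5 * dt * kw2
                kv3 = (-gLi * (V3 - ELi) - w3 - gA * V3 - gN * V3
                       - gGa * (V3 - Ega) - gGb * (V3 - Egb) + Ii) * iCm
                kw3 = (ai * (V3 - ELi) - w3) * itw
                V4 = Vi + dt * kv3
                w4 = wi + dt * kw3
                kv4 = (-gLi * (V4 - ELi) - w4 - gA * V4 - gN * V4
                       - gGa * (V4 - Ega) - gGb * (V4 - Egb) + Ii) * iCm
                kw4 = (ai * (V4 - ELi) - w4) * itw
                Vi = Vi + dt / 6.0 * (kv1 + 2.0 * kv2 + 2.0 * kv3 + kv4)
                wi = wi + dt / 6.0 * (kw1 + 2.0 * kw2 + 2.0 * kw3 + kw4)

                if Vi >= Vth[i]:
                    Vi = Vr[i]
                    wi = wi + b[i]
                    refr_until[i] = t + 1 + ref_steps[i]
                    sp_ids[n_sp] = i
                    n_sp += 1
            else:
                # refractory: V clamped at reset, adaptation decays exactly
                Vi = Vr[i]
                winf = a[i] * (Vi - EL[i])
                wi = winf + (wi - winf) * np.exp(-dt * inv_tau_w[i])

            V[i] = Vi
            w_adapt[i] = wi

        # spike bookkeeping and delayed delivery
        if n_sp > 0:
            if n_spikes + n_sp > max_spikes:
                return n_spikes, STATUS_SPIKE_OVERFLOW
            for s in range(n_sp):
                i = sp_ids[s]
                spike_step[n_spikes] = t + 1
                spike_id[n_spikes] = i
                n_spikes += 1
                exc = i < n_exc
                for e in range(src_ptr[i], src_ptr[i + 1]):
                    tgt_slot = (t + 1 + edge_dsteps[e]) % D
                    if exc:
                        bufE[tgt_slot, edge_dst[e]] += edge_w[e]
                    else:
                        bufI[tgt_slot, edge_dst[e]] += edge_w[e]

        # exact exponential decay of the receptor states
        for i in range(N):
            for c in range(N_COMP):
                comp[i, c] *= comp_decay[i, c]

        # recording at the end of the step
        if rec_every > 0 and (t + 1) % rec_every == 0:
            row = (t + 1) // rec_every - 1
            if row < V_rec.shape[0]:
                for j in range(len(v_rec_idx)):
                    V_rec[row, j] = V[v_rec_idx[j]]
                for j in range(len(cur_rec_idx)):
                    i = cur_rec_idx[j]
                    Vi = V[i]
                    gA = comp[i, 0] + comp[i, 1] + comp[i, 2] + comp[i, 3]
                    gN_raw = comp[i, 4] + comp[i, 5] + comp[i, 6] + comp[i, 7]
                    gGa = comp[i, 8] + comp[i, 9] + comp[i, 10] + comp[i, 11]
                    gGb = (comp[i, 12] + comp[i, 13] + comp[i, 14]
                           + comp[i, 15])
                    gate = 1.0 / (1.0 + mg_coef[i] * np.exp(-0.062 * Vi))
                    Iexc_rec[row, j] = (gA + gN_raw * gate) * Vi
                    Iinh_rec[row, j] = (gGa * (Vi - E_ga[i])
                                        + gGb * (Vi - E_gb[i]))

        if (t + 1) % 1000 == 0:
            if not np.isfinite(V[0]):
                return n_spikes, STATUS_NOT_FINITE

    for i in range(N):
        if not np.isfinite(V[i]):
            return n_spikes, STATUS_NOT_FINITE
    return n_spikes, STATUS_OK
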