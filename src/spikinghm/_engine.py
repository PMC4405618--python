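"""Numba inner loop of the spiking-network simulator.

One jitted function advances the whole network state in place with a
fixed time step.  Per step, in order: (1) delayed spike delivery with
pre-event plasticity, (2) external Poisson drives and Poisson-generator
pools, (3) forward-Euler integration of the Izhikevich neurons with
spike detection/reset, (4) post-event (STDPi) plasticity, (5) rate-trace
increments for this step's spikes, (6) exponential decay of conductances
and traces.  Traces read during an event therefore exclude every spike
of the current step (the "just before" convention), and a spike emitted
at step ``t`` reaches its targets at step ``t + delay_steps``.

Plasticity rule codes: 0 = Spiking BCM (exponential trace), 1 = STDPi
(difference-of-exponentials traces).  All state arrays live in the
:class:`~spikinghm.network.SpikingNetwork` wrapper; nothing here is part
of the public API.
"""

import numpy as np
from numba import njit

RULE_BCM = 0
RULE_STDPI = 1

ERR_OK = 0
ERR_BLOWUP = 1


@njit(cache=True)
def run_steps(
    n_steps,
    dt,
    seed,
    # neuron state
    kind,            # int8[N]: 0 izh, 1 poisson generator
    pa, pb, pc, pd,  # float64[N] izhikevich params
    V, u,
    ge1, ge2, gi, gr,
    gen_rate,        # Hz, generator pools
    ext_rate, ext_w, # external nonspecific drive
    I_dc,
    # synapses (CSR by presynaptic neuron)
    out_ptr, syn_pre, syn_post, syn_w, syn_inh, syn_plastic, syn_gate, syn_learn,
    # plastic-synapse incoming lists (CSR by postsynaptic neuron)
    in_ptr, in_syn,
    # traces
    tr1, tr2,
    # constants
    tau_e1, tau_e2, tau_i, Ee, Ei, mg_ext, nmda_frac,
    f_mean, f_std,
    rule, A, r_theta, Am, Ap,
    k1, k2, trace_d1, trace_d2,  # trace scale (Hz) and per-step decay factors
    w_max,
    delay_steps,
    ring,            # uint8[delay_steps, N] spike history ring buffer
    ring_pos,        # int64[1] current write slot
    plasticity_on,
    # outputs
    spike_counts,    # int64[N], accumulated
    rec_neuron, rec_step, rec_n,  # spike recording buffers (int32, int32, int64[1])
):
    np.random.seed(seed)
    N = V.size
    de1 = np.exp(-dt / tau_e1)
    de2 = np.exp(-dt / tau_e2)
    di = np.exp(-dt / tau_i)
    p_ext_scale = dt / 1000.0
    spiked = np.zeros(N, np.uint8)
    rec_cap = rec_neuron.size

    for step in range(n_steps):
        pos = ring_pos[0]
        # slot `pos` holds the spikes emitted exactly delay_steps steps ago
        # (it is overwritten with this step's spikes at the end of the step)
        for i in range(N):
            if ring[pos, i] == 1:
                for sidx in range(out_ptr[i], out_ptr[i + 1]):
                    g = syn_gate[sidx]
                    if g == 0.0:
                        continue
                    w = syn_w[sidx]
                    post = syn_post[sidx]
                    if syn_plastic[sidx] == 1 and plasticity_on == 1 and syn_learn[sidx] == 1:
                        # pre-synaptic plasticity event
                        rpost = k1 * tr1[post] - k2 * tr2[post]
                        if rule == RULE_BCM:
                            w = w + A * rpost * (rpost - r_theta)
                        else:
                            w = w - Am * rpost
                        if w < 0.0:
                            w = 0.0
                        elif w > w_max:
                            w = w_max
                        syn_w[sidx] = w
                    f = f_mean + f_std * np.random.standard_normal()
                    if f < 0.0:
                        f = 0.0
                    dg = w * f * g
                    if syn_inh[sidx] == 1:
                        gi[post] += dg
                    else:
                        ge1[post] += dg
                        ge2[post] += dg * nmda_frac
        # external drives and generator pools
        for i in range(N):
            if ext_rate[i] > 0.0:
                if np.random.random() < ext_rate[i] * p_ext_scale:
                    gr[i] += ext_w[i]
            if kind[i] == 1:
                if gen_rate[i] > 0.0 and np.random.random() < gen_rate[i] * p_ext_scale:
                    spiked[i] = 1
                else:
                    spiked[i] = 0
        # integrate izhikevich neurons
        blown = -1
        for i in range(N):
            if kind[i] != 0:
                continue
            # two half-steps keep the stiff conductance terms of strongly
            # inhibited neurons inside the Euler stability region
            Vi = V[i]
            ui = u[i]
            did_spike = False
            half = 0.5 * dt
            for _sub in range(2):
                nmda = 1.0 / (1.0 + (mg_ext / 3.57) * np.exp(-0.062 * Vi))
                Ie = (ge1[i] + ge2[i] * nmda) * (Ee - Vi)
                Ii = gi[i] * (Ei - Vi)
                Ir = gr[i] * (Ee - Vi)
                Vn = Vi + half * (
                    0.04 * Vi * Vi + 5.0 * Vi + 140.0 - ui + Ie + Ii + Ir + I_dc[i]
                )
                un = ui + half * pa[i] * (pb[i] * Vi - ui)
                if Vn > 0.0:
                    did_spike = True
                    Vi = pc[i]
                    ui = un + pd[i]
                else:
                    Vi = Vn
                    ui = un
            if did_spike:
                spiked[i] = 1
            else:
                spiked[i] = 0
                if not (np.isfinite(Vi) and np.isfinite(ui)):
                    blown = i
                    break
            V[i] = Vi
            u[i] = ui
        if blown >= 0:
            return ERR_BLOWUP, blown
        # post-event plasticity (STDPi potentiation at post spikes)
        if rule == RULE_STDPI and plasticity_on == 1:
            for i in range(N):
                if spiked[i] == 1 and kind[i] == 0 and in_ptr[i] < in_ptr[i + 1]:
                    rpost = k1 * tr1[i] - k2 * tr2[i]
                    if rpost != 0.0:
                        for kk in range(in_ptr[i], in_ptr[i + 1]):
                            sidx = in_syn[kk]
                            if syn_learn[sidx] == 0 or syn_gate[sidx] == 0.0:
                                continue
                            rpre = k1 * tr1[syn_pre[sidx]] - k2 * tr2[syn_pre[sidx]]
                            w = syn_w[sidx] + Ap * rpre * rpost
                            if w < 0.0:
                                w = 0.0
                            elif w > w_max:
                                w = w_max
                            syn_w[sidx] = w
        # trace increments, spike bookkeeping, ring update
        for i in range(N):
            if spiked[i] == 1:
                tr1[i] += 1.0
                if rule == RULE_STDPI:
                    tr2[i] += 1.0
                spike_counts[i] += 1
                ring[pos, i] = 1
                if rec_cap > 0 and rec_n[0] < rec_cap:
                    rec_neuron[rec_n[0]] = i
                    rec_step[rec_n[0]] = step
                    rec_n[0] += 1
            else:
                ring[pos, i] = 0
        ring_pos[0] = (pos + 1) % delay_steps
        # exponential decays
        for i in range(N):
            ge1[i] *= de1
            ge2[i] *= de2
            gi[i] *= di
            gr[i] *= de1
            tr1[i] *= trace_d1
            tr2[i] *= trace_d2
    return ERR_OK, -1
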