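"""Compiled integration loop.

One call advances the network by up to ``n_steps`` Euler steps and returns
early when the weight stop-rule fires.  The Python wrapper in
:mod:`ftsts.simulate` owns all setup (connectivity, stimulus waveforms, noise
draws) and recording; the kernel only performs the per-step arithmetic, in
exactly the same operation order as the pure-Python reference engine so that
the two produce bit-identical trajectories for the pair-STDP rules.

Projection slots are fixed: IE (E-to-I), EI (I-to-E), EE, II.  Unused slots
receive 1x1 dummy arrays with ``has_* = False``.  Plasticity rules: 0 = none,
1 = trace-based pair rule, 2 = symmetric ISI rule (IE slot only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True)
def run_chunk(  # noqa: C901 - deliberately one flat loop
    step0,
    n_steps,
    dt,
    n_e,
    n_i,
    v,
    a_leak,  # (N,) dt / tau_m
    mu,
    sigma_amp,  # (N,) sigma * sqrt(dt / tau_m)
    noise,  # (n_steps, N)
    stim,  # (n_steps, N)
    v_th,
    v_reset,
    ring,  # (D, N) uint8 ring buffer of past spikes
    inv_tau_r,
    c_r,  # dt / tau_r
    c_d,  # dt / tau_d
    has_ie, W_ie, M_ie, g_ie, X_ie, S_ie,
    has_ei, W_ei, M_ei, g_ei, X_ei, S_ei,
    has_ee, W_ee, M_ee, g_ee, X_ee, S_ee,
    has_ii, W_ii, M_ii, g_ii, X_ii, S_ii,
    rule_ie,
    coeff_ltp_ie,  # eta_e * a_ltp
    coeff_ltd_ie,  # eta_e * a_ltd
    a0_ie,
    dec_pre_ie,
    dec_post_ie,
    pre_tr_ie,  # (n_e,)
    post_tr_ie,  # (n_i,)
    wlo_ie,
    whi_ie,
    sym_cp,
    sym_cd,
    sym_taup,
    sym_taud,
    rule_ei,
    coeff_ltp_ei,
    coeff_ltd_ei,
    a0_ei,
    dec_pre_ei,
    dec_post_ei,
    pre_tr_ei,  # (n_i,)
    post_tr_ei,  # (n_e,)
    wlo_ei,
    whi_ei,
    last_spike_t,  # (N,) ms, -inf if never fired
    spike_steps,  # out: (cap,) int64
    spike_ids,  # out: (cap,) int64
    sample_every,
    jw_scale_ie,  # J_ie / n_synapses_ie (0 if absent)
    jw_scale_ei,
    w_samples_ie,  # out: per-sample mean J*W
    w_samples_ei,
    sample_steps,  # out: global step of each sample
    stop_mode,  # 0 none, 1 stop when mean J*W <= thr, 2 when >= thr
    stop_thr,
):
    N = n_e + n_i
    D = ring.shape[0]
    n_spk = 0
    n_smp = 0
    stop_step = np.int64(-1)
    cur = np.empty(N, dtype=np.int64)

    for s in range(n_steps):
        g = step0 + s

        # (1) synaptic drive from current filter state
        # (2) membrane Euler-Maruyama step
        for n in range(n_e):
            Z = g_ei * S_ei[n] if has_ei else 0.0
            if has_ee:
                Z = Z + g_ee * S_ee[n]
            v[n] = (
                v[n]
                + a_leak[n] * (((-v[n] + Z) + mu[n]) + stim[s, n])
                + sigma_amp[n] * noise[s, n]
            )
        for m in range(n_i):
            n = n_e + m
            Z = g_ie * S_ie[m] if has_ie else 0.0
            if has_ii:
                Z = Z + g_ii * S_ii[m]
            v[n] = (
                v[n]
                + a_leak[n] * (((-v[n] + Z) + mu[n]) + stim[s, n])
                + sigma_amp[n] * noise[s, n]
            )

        # (3) threshold detection and reset
        nc = 0
        for n in range(N):
            if v[n] >= v_th:
                v[n] = v_reset
                cur[nc] = n
                nc += 1
        for k in range(nc):
            spike_steps[n_spk] = g
            spike_ids[n_spk] = cur[k]
            n_spk += 1

        # (4) decay traces to the current step (before sampling, so that
        # trace accumulation equals the all-pairs kernel sum exactly and
        # simultaneous pairs contribute nothing)
        if rule_ie == 1:
            for j in range(n_e):
                pre_tr_ie[j] *= dec_pre_ie
            for i in range(n_i):
                post_tr_ie[i] *= dec_post_ie
        if rule_ei == 1:
            for i in range(n_i):
                pre_tr_ei[i] *= dec_pre_ei
            for j in range(n_e):
                post_tr_ei[j] *= dec_post_ei

        # (5) plasticity updates for this step's spikes
        if nc > 0:
            t_now = g * dt
            if rule_ie == 1:
                for k in range(nc):
                    n = cur[k]
                    if n >= n_e:  # postsynaptic (I) spike: LTP from pre traces
                        i = n - n_e
                        for j in range(n_e):
                            if M_ie[i, j]:
                                W_ie[i, j] += coeff_ltp_ie * pre_tr_ie[j]
                for k in range(nc):
                    n = cur[k]
                    if n < n_e:  # presynaptic (E) spike: LTD from post traces
                        for i in range(n_i):
                            if M_ie[i, n]:
                                W_ie[i, n] += coeff_ltd_ie * post_tr_ie[i]
            elif rule_ie == 2:
                # presynaptic events first, then postsynaptic, each against
                # the last opposite-side spike recorded before this step
                for k in range(nc):
                    n = cur[k]
                    if n < n_e:
                        for i in range(n_i):
                            if M_ie[i, n] and last_spike_t[n_e + i] > -np.inf:
                                isi = abs(t_now - last_spike_t[n_e + i])
                                dw = sym_cp * np.exp(-isi / sym_taup) - sym_cd * np.exp(
                                    -isi / sym_taud
                                )
                                W_ie[i, n] += dw
                for k in range(nc):
                    n = cur[k]
                    if n >= n_e:
                        i = n - n_e
                        for j in range(n_e):
                            if M_ie[i, j] and last_spike_t[j] > -np.inf:
                                isi = abs(t_now - last_spike_t[j])
                                dw = sym_cp * np.exp(-isi / sym_taup) - sym_cd * np.exp(
                                    -isi / sym_taud
                                )
                                W_ie[i, j] += dw
            if rule_ei == 1:
                for k in range(nc):
                    n = cur[k]
                    if n < n_e:  # postsynaptic (E) spike for the I-to-E projection
                        for i in range(n_i):
                            if M_ei[n, i]:
                                W_ei[n, i] += coeff_ltp_ei * pre_tr_ei[i]
                for k in range(nc):
                    n = cur[k]
                    if n >= n_e:  # presynaptic (I) spike
                        i = n - n_e
                        for j in range(n_e):
                            if M_ei[j, i]:
                                W_ei[j, i] += coeff_ltd_ei * post_tr_ei[j]
            # clip plastic weights to bounds
            if rule_ie != 0:
                for i in range(n_i):
                    for j in range(n_e):
                        if M_ie[i, j]:
                            if W_ie[i, j] < wlo_ie:
                                W_ie[i, j] = wlo_ie
                            elif W_ie[i, j] > whi_ie:
                                W_ie[i, j] = whi_ie
            if rule_ei != 0:
                for j in range(n_e):
                    for i in range(n_i):
                        if M_ei[j, i]:
                            if W_ei[j, i] < wlo_ei:
                                W_ei[j, i] = wlo_ei
                            elif W_ei[j, i] > whi_ei:
                                W_ei[j, i] = whi_ei

        # (6) trace increments and spike-time bookkeeping
        if nc > 0:
            t_now = g * dt
            for k in range(nc):
                n = cur[k]
                if n < n_e:
                    if rule_ie == 1:
                        pre_tr_ie[n] += a0_ie
                    if rule_ei == 1:
                        post_tr_ei[n] += a0_ei
                else:
                    i = n - n_e
                    if rule_ie == 1:
                        post_tr_ie[i] += a0_ie
                    if rule_ei == 1:
                        pre_tr_ei[i] += a0_ei
                last_spike_t[n] = t_now

        # (7) delayed delivery and synaptic cascade update
        idx = g % D
        # decay X
        if has_ie:
            for i in range(n_i):
                X_ie[i] = X_ie[i] + c_r * (-X_ie[i])
        if has_ei:
            for i in range(n_e):
                X_ei[i] = X_ei[i] + c_r * (-X_ei[i])
        if has_ee:
            for i in range(n_e):
                X_ee[i] = X_ee[i] + c_r * (-X_ee[i])
        if has_ii:
            for i in range(n_i):
                X_ii[i] = X_ii[i] + c_r * (-X_ii[i])
        # deliver spikes emitted D steps ago (accumulate coupling per target
        # in ascending source order, then scale by 1/tau_r)
        if has_ie:
            for i in range(n_i):
                acc = 0.0
                for j in range(n_e):
                    if ring[idx, j] != 0 and M_ie[i, j]:
                        acc += W_ie[i, j]
                if acc != 0.0:
                    X_ie[i] = X_ie[i] + acc * inv_tau_r
        if has_ee:
            for i in range(n_e):
                acc = 0.0
                for j in range(n_e):
                    if ring[idx, j] != 0 and M_ee[i, j]:
                        acc += W_ee[i, j]
                if acc != 0.0:
                    X_ee[i] = X_ee[i] + acc * inv_tau_r
        if has_ei:
            for i in range(n_e):
                acc = 0.0
                for jj in range(n_i):
                    if ring[idx, n_e + jj] != 0 and M_ei[i, jj]:
                        acc += W_ei[i, jj]
                if acc != 0.0:
                    X_ei[i] = X_ei[i] + acc * inv_tau_r
        if has_ii:
            for i in range(n_i):
                acc = 0.0
                for jj in range(n_i):
                    if ring[idx, n_e + jj] != 0 and M_ii[i, jj]:
                        acc += W_ii[i, jj]
                if acc != 0.0:
                    X_ii[i] = X_ii[i] + acc * inv_tau_r
        # S low-pass
        if has_ie:
            for i in range(n_i):
                S_ie[i] = S_ie[i] + c_d * (-S_ie[i] + X_ie[i])
        if has_ei:
            for i in range(n_e):
                S_ei[i] = S_ei[i] + c_d * (-S_ei[i] + X_ei[i])
        if has_ee:
            for i in range(n_e):
                S_ee[i] = S_ee[i] + c_d * (-S_ee[i] + X_ee[i])
        if has_ii:
            for i in range(n_i):
                S_ii[i] = S_ii[i] + c_d * (-S_ii[i] + X_ii[i])
        # enqueue this step's spikes for delivery at step g + D
        for n in range(N):
            ring[idx, n] = 0
        for k in range(nc):
            ring[idx, cur[k]] = 1

        # (8) weight sampling and stop rule
        if (g + 1) % sample_every == 0:
            jw_ie = 0.0
            if jw_scale_ie > 0.0:
                tot = 0.0
                for i in range(n_i):
                    for j in range(n_e):
                        tot += W_ie[i, j]
                jw_ie = tot * jw_scale_ie
            jw_ei = 0.0
            if jw_scale_ei > 0.0:
                tot = 0.0
                for j in range(n_e):
                    for i in range(n_i):
                        tot += W_ei[j, i]
                jw_ei = tot * jw_scale_ei
            w_samples_ie[n_smp] = jw_ie
            w_samples_ei[n_smp] = jw_ei
            sample_steps[n_smp] = g
            n_smp += 1
            if stop_mode == 1 and jw_ie <= stop_thr:
                stop_step = g
                return n_spk, n_smp, stop_step
            if stop_mode == 2 and jw_ie >= stop_thr:
                stop_step = g
                return n_spk, n_smp, stop_step

    return n_spk, n_smp, stop_step
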