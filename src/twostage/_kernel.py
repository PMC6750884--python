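"""Compiled per-session likelihood used by the fitting routines.

This mirrors, step for step, the pure-Python observation model in
:mod:`twostage.agents` (values -> softmax policies -> latent-mode marginal ->
responsibility-weighted updates); a property test pins the two paths together
to 1e-10.  It exists purely so that MAP fits over many subjects and candidate
models run in seconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .agents import A2I, S2I, ModelSpec, Params


@njit(cache=True)
def _session_nll(
    a1, s2, a2, r,
    cont_l,
    is_flat, has_single, has_seq, use_mf, learn_T, resp_weighted,
    w_mb, alpha1, alpha2, alpha_seq, alpha_T, lam,
    beta1, beta2, p_int, b_disc, eps, q0, kappa,
):
    n = a1.shape[0]
    Q2 = np.full((2, 2), q0)
    Q1 = np.full(2, q0)
    Qs = np.full(2, q0)
    Qf = np.full(2, q0)
    T = np.empty((2, 2))
    hi = (1.0 + kappa / 2.0) / (1.0 + kappa)
    T[0, cont_l] = hi
    T[0, 1 - cont_l] = 1.0 - hi
    T[1, 1 - cont_l] = hi
    T[1, cont_l] = 1.0 - hi

    util = np.empty(4)
    prob = np.empty(4)
    avail = np.empty(4, np.bool_)
    nll = 0.0
    for t in range(n):
        i1 = a1[t]
        si = s2[t]
        i2 = a2[t]
        rew = r[t]
        for k in range(4):
            avail[k] = False
        if is_flat:
            util[0] = beta1 * Qf[0]
            util[1] = beta1 * Qf[1]
            avail[0] = True
            avail[1] = True
        else:
            if has_single:
                for a in range(2):
                    v = 0.0
                    if w_mb > 0.0:
                        for sj in range(2):
                            if Q2[sj, 0] == Q2[sj, 1]:
                                m = 0.5 * (Q2[sj, 0] + Q2[sj, 1])
                            elif Q2[sj, 0] > Q2[sj, 1]:
                                m = Q2[sj, 0]
                            else:
                                m = Q2[sj, 1]
                            v += T[a, sj] * m
                    util[a] = beta1 * (w_mb * v + (1.0 - w_mb) * Q1[a])
                    avail[a] = True
            if has_seq:
                util[2] = beta1 * Qs[0]
                util[3] = beta1 * Qs[1]
                avail[2] = True
                avail[3] = True
        # softmax with lapse over the available options
        mx = -1e308
        cnt = 0
        for k in range(4):
            if avail[k]:
                cnt += 1
                if util[k] > mx:
                    mx = util[k]
        ssum = 0.0
        for k in range(4):
            if avail[k]:
                prob[k] = np.exp(util[k] - mx)
                ssum += prob[k]
        for k in range(4):
            if avail[k]:
                prob[k] = (1.0 - eps) * prob[k] / ssum + eps / cnt

        # stage-2 choice probability of the observed a2
        if is_flat:
            u0 = beta1 * Qf[0]
            u1 = beta1 * Qf[1]
        else:
            u0 = beta2 * Q2[si, 0]
            u1 = beta2 * Q2[si, 1]
            # discriminative action index equals the state index
            if si == 0:
                u0 += b_disc
            else:
                u1 += b_disc
        m2 = u0 if u0 > u1 else u1
        e0 = np.exp(u0 - m2)
        e1 = np.exp(u1 - m2)
        z = e0 + e1
        if i2 == 0:
            p2 = (1.0 - eps) * e0 / z + eps / 2.0
        else:
            p2 = (1.0 - eps) * e1 / z + eps / 2.0

        resp_seq = 0.0
        if is_flat:
            p_obs = prob[i1] * p2
        else:
            p_single = prob[i1] if has_single else 0.0
            p_seq = 0.0
            if has_seq:
                comp = 1.0 if i2 == 1 - i1 else 0.0
                p_seq = prob[2 + i1] * ((1.0 - p_int) * comp + p_int * p2)
            p_obs = p_single * p2 + p_seq
            if p_obs > 0.0:
                resp_seq = p_seq / p_obs
        if p_obs < 1e-300:
            p_obs = 1e-300
        nll -= np.log(p_obs)

        # learning updates
        if is_flat:
            Qf[i1] += alpha1 * (0.0 - Qf[i1])
            Qf[i2] += alpha1 * (rew - Qf[i2])
        else:
            q2b = Q2[si, i2]
            Q2[si, i2] += alpha2 * (rew - Q2[si, i2])
            if use_mf:
                Q1[i1] += alpha1 * (q2b - Q1[i1]) + alpha1 * lam * (rew - q2b)
            if learn_T:
                T[i1, si] += alpha_T * (1.0 - T[i1, si])
                T[i1, 1 - si] = 1.0 - T[i1, si]
            if has_seq:
                wgt = resp_seq if resp_weighted else 1.0
                Qs[i1] += wgt * alpha_seq * (rew - Qs[i1])
    return nll


def infer_cont_l(session_df) -> int:
    """Index of the common stage-2 state of action L for one session,
    inferred from the first (a1, s2, transition) row."""
    row = session_df.iloc[0]
    s_idx = S2I[row["s2"]]
    common_of_a1 = s_idx if row["transition"] == "common" else 1 - s_idx
    return common_of_a1 if row["a1"] == "L" else 1 - common_of_a1


def session_arrays(session_df) -> dict:
    """Integer-coded arrays for one session's non-aborted trials."""
    df = session_df[session_df["aborted"].astype(int) == 0]
    return {
        "a1": df["a1"].map(A2I).to_numpy(np.int64),
        "s2": df["s2"].map(S2I).to_numpy(np.int64),
        "a2": df["a2"].map(A2I).to_numpy(np.int64),
        "r": df["outcome"].to_numpy(np.float64),
        "cont_l": infer_cont_l(df) if len(df) else 1,
    }


def kernel_args(spec: ModelSpec, params: Params) -> tuple:
    """Flag/parameter tuple for :func:`_session_nll` given a spec."""
    if spec.is_hybrid:
        w_mb = params.w
    else:
        w_mb = 1.0 if spec.uses_mb else 0.0
    return (
        spec.is_flat,
        spec.has_single_actions and not spec.is_flat,
        spec.has_sequences,
        spec.uses_mf,
        spec.uses_mb and spec.learn_transitions,
        spec.resp_weighted_seq,
        w_mb,
        params.alpha1, params.alpha2, params.alpha_seq, params.alpha_T,
        params.lam, params.beta1, params.beta2, params.p_int,
        params.b_disc, params.eps, spec.q0, spec.kappa,
    )


def dataset_nll(spec: ModelSpec, params: Params, sessions: list[dict]) -> float:
    """Total negative log-likelihood over pre-coded sessions.

    Learned values are re-initialised at every session start (each session is
    modelled as an independent learning episode starting from q0 and the
    smoothed trained contingency).
    """
    args = kernel_args(spec, params)
    nll = 0.0
    for sess in sessions:
        if len(sess["a1"]) == 0:
            continue
        nll += _session_nll(
            sess["a1"], sess["s2"], sess["a2"], sess["r"], sess["cont_l"], *args
        )
    return nll
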