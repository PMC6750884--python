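"""Independent brute-force oracles used by the tests.

These recompute choice probabilities directly from the learned-value arrays
with scipy's softmax and exhaustive enumeration of the latent modes (selected
option x interruption), sharing no code path with the package's likelihood.
"""

import numpy as np
from scipy.special import softmax

from twostage.agents import SEQUENCES, A2I, S2I, ModelSpec, Params
from twostage.task import discriminative


def _stage1_option_probs(spec: ModelSpec, params: Params, state) -> dict:
    opts = []
    utils = []
    if spec.is_flat:
        for a in ("L", "R"):
            opts.append(a)
            utils.append(params.beta1 * state.Qflat[A2I[a]])
    else:
        if spec.has_single_actions:
            if spec.is_hybrid:
                w = params.w
            elif spec.uses_mb:
                w = 1.0
            else:
                w = 0.0
            for a in ("L", "R"):
                ai = A2I[a]
                v_mb = 0.0
                for si in (0, 1):
                    q = state.Q2[si]
                    m = 0.5 * (q[0] + q[1]) if q[0] == q[1] else max(q[0], q[1])
                    v_mb += state.T[ai, si] * m
                opts.append(a)
                utils.append(params.beta1 * (w * v_mb + (1 - w) * state.Q1mf[ai]))
        if spec.has_sequences:
            for k, seq in enumerate(SEQUENCES):
                opts.append(seq)
                utils.append(params.beta1 * state.Qseq[k])
    p = softmax(np.asarray(utils))
    p = (1 - params.eps) * p + params.eps / len(p)
    return dict(zip(opts, p))


def _stage2_probs(s2: str, spec: ModelSpec, params: Params, state) -> dict:
    if spec.is_flat:
        utils = params.beta1 * state.Qflat
    else:
        si = S2I[s2]
        utils = params.beta2 * state.Q2[si].copy()
        utils[A2I[discriminative(s2)]] += params.b_disc
    p = softmax(utils)
    p = (1 - params.eps) * p + params.eps / 2
    return {"L": p[0], "R": p[1]}


def enum_trial_prob(trial, spec: ModelSpec, params: Params, state) -> float:
    """P(a1, a2 | state) by exhaustive enumeration over latent assignments."""
    p1 = _stage1_option_probs(spec, params, state)
    p2 = _stage2_probs(trial.s2, spec, params, state)
    total = 0.0
    for opt, p_opt in p1.items():
        if opt in SEQUENCES:
            first, second = opt.split("->")
            if first != trial.a1:
                continue
            # interrupted vs completed execution branches
            total += p_opt * params.p_int * p2[trial.a2]
            if second == trial.a2:
                total += p_opt * (1 - params.p_int)
        else:
            if opt == trial.a1:
                total += p_opt * p2[trial.a2]
    return total
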