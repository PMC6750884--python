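"""Candidate decision-making agents for the two-stage task.

Eight families formalise competing hypotheses about the state-space and action
repertoire the animal uses:

========  ==================  ============================
family    state-space         stage-1 options
========  ==================  ============================
FLAT      single merged       L, R
MF        S0, S1, S2          L, R          (cached values)
MB        S0, S1, S2          L, R          (planning over T)
MB-MF     S0, S1, S2          L, R          (w-weighted hybrid)
H         S0                  L->R, R->L    (sequences only)
H-MF      S0, S1, S2          L, R, L->R, R->L
H-MB      S0, S1, S2          L, R, L->R, R->L
H-MB-MF   S0, S1, S2          L, R, L->R, R->L
========  ==================  ============================

Sequence options are temporally extended actions selected once at stage 1 and
executed as a unit; with probability ``p_int`` execution is interrupted after
the first press and the stage-2 policy resumes control.  Because the selected
option is latent when only (a1, s2, a2) is observed, the trial likelihood
marginalises over the latent modes consistent with a1, and learning about
sequence values is weighted by the posterior responsibility of the sequence
mode.

The stage-2 policy includes a discrimination-tendency bias ``b_disc`` toward
the only action ever rewarded in each stage-2 state (R in S2, L in S1),
independent of learned values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .task import (
    ACTIONS,
    DEFAULT_CONTINGENCY,
    STATES,
    Trial,
    discriminative,
)

FAMILIES = ("FLAT", "MF", "MB", "MB-MF", "H", "H-MF", "H-MB", "H-MB-MF")
SEQ_FAMILIES = ("H", "H-MF", "H-MB", "H-MB-MF")
MB_FAMILIES = ("MB", "MB-MF", "H-MB", "H-MB-MF")
MF_FAMILIES = ("MF", "MB-MF", "H-MF", "H-MB-MF")

SEQUENCES = ("L->R", "R->L")

A2I = {"L": 0, "R": 1}
S2I = {"S1": 0, "S2": 1}


class SpecError(ValueError):
    """A model specification is internally inconsistent."""


class ImpossibleObservation(ValueError):
    """The observed choice pair has probability zero under the model.

    Raised instead of silently returning -inf; occurs only when a pure
    sequence family has p_int = 0 and eps = 0 and the stage-2 action does not
    complete the selected sequence.
    """


def sequence_for(a1: str) -> str:
    """The unique sequence option starting with ``a1``."""
    return "L->R" if a1 == "L" else "R->L"


def sequence_second(seq: str) -> str:
    return seq.split("->")[1]


@dataclass(frozen=True)
class ModelSpec:
    """Family identity plus the free-parameter toggles of one model.

    Toggles passed as None resolve to the family's base model: shared learning
    rate, eligibility weight fixed at 1, interruption parameter free for
    sequence families, discrimination bias free for all state-aware families,
    no lapse floor, transition estimates fixed at their initial values.
    ``fixed`` pins named parameters to constants (removing them from the free
    set).
    """

    family: str
    separate_alphas: bool = False
    eligibility: bool = False
    interruption: Optional[bool] = None
    disc_bias: Optional[bool] = None
    lapse: bool = False
    learn_transitions: bool = False
    resp_weighted_seq: bool = True
    fixed: tuple[tuple[str, float], ...] = ()
    kappa: float = 0.2
    q0: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        if isinstance(self.fixed, dict):
            object.__setattr__(self, "fixed", tuple(sorted(self.fixed.items())))
        if self.interruption is None:
            object.__setattr__(self, "interruption", self.has_sequences)
        elif self.interruption and not self.has_sequences:
            raise SpecError(f"interruption toggle is inapplicable to {self.family}")
        if self.disc_bias is None:
            object.__setattr__(self, "disc_bias", self.family != "FLAT")
        elif self.disc_bias and self.family == "FLAT":
            raise SpecError("disc_bias toggle is inapplicable to FLAT")
        if self.eligibility and not self.uses_mf:
            raise SpecError(f"eligibility toggle is inapplicable to {self.family}")
        if self.learn_transitions and not self.uses_mb:
            raise SpecError(f"learn_transitions toggle is inapplicable to {self.family}")
        if self.separate_alphas and self.family == "FLAT":
            raise SpecError("separate_alphas toggle is inapplicable to FLAT")
        if not 0.0 <= self.q0 <= 1.0:
            raise SpecError("q0 must be in [0, 1]")
        if self.kappa < 0:
            raise SpecError("kappa must be >= 0")
        fx = dict(self.fixed)
        if self.family == "H" and not self.lapse:
            # Pure sequence agents need some escape hatch or some observations
            # are impossible; fitting keeps p_int > 0 via its transform.  An
            # explicitly fixed p_int (even zero) is taken as deliberate — the
            # likelihood then signals impossible observations itself.
            if not self.interruption and "p_int" not in fx and "eps" not in fx:
                raise SpecError(
                    "family H needs a free or positive interruption probability "
                    "or a lapse floor; otherwise incomplete sequences are "
                    "impossible observations"
                )

    # -- family structure ---------------------------------------------------
    @property
    def has_sequences(self) -> bool:
        return self.family in SEQ_FAMILIES

    @property
    def has_single_actions(self) -> bool:
        """Single lever presses among the stage-1 options (all but pure H)."""
        return self.family != "H"

    @property
    def uses_mb(self) -> bool:
        return self.family in MB_FAMILIES

    @property
    def uses_mf(self) -> bool:
        return self.family in MF_FAMILIES

    @property
    def is_hybrid(self) -> bool:
        return self.uses_mb and self.uses_mf

    @property
    def is_flat(self) -> bool:
        return self.family == "FLAT"

    def option_set(self) -> tuple[str, ...]:
        if self.is_flat:
            return ACTIONS
        if self.family == "H":
            return SEQUENCES
        if self.has_sequences:
            return ACTIONS + SEQUENCES
        return ACTIONS

    # -- free parameters ----------------------------------------------------
    def free_params(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.is_flat:
            names += ["alpha1", "beta1"]
        else:
            if self.separate_alphas:
                if self.uses_mf:
                    names.append("alpha1")
                names.append("alpha2")
                if self.has_sequences:
                    names.append("alpha_seq")
            else:
                names.append("alpha")
            if self.eligibility:
                names.append("lam")
            names += ["beta1", "beta2"]
            if self.is_hybrid:
                names.append("w")
            if self.has_sequences and self.interruption:
                names.append("p_int")
            if self.disc_bias:
                names.append("b_disc")
            if self.learn_transitions:
                names.append("alpha_T")
        if self.lapse:
            names.append("eps")
        fx = dict(self.fixed)
        return tuple(n for n in names if n not in fx)

    @property
    def df(self) -> int:
        """Number of free parameters (degrees of freedom)."""
        return len(self.free_params())

    def spec_id(self) -> str:
        flags = []
        if self.separate_alphas:
            flags.append("sep")
        if self.eligibility:
            flags.append("elig")
        if self.has_sequences and not self.interruption:
            flags.append("noint")
        if not self.disc_bias and not self.is_flat:
            flags.append("nodisc")
        if self.lapse:
            flags.append("lapse")
        if self.learn_transitions:
            flags.append("learnT")
        for k, v in self.fixed:
            flags.append(f"{k}={v:g}")
        return self.family + ("" if not flags else "[" + ",".join(flags) + "]")


@dataclass(frozen=True)
class Params:
    """Full parameter set; families ignore entries outside their toggle set.

    Learning rates and probabilities live in [0, 1], inverse temperatures are
    non-negative, ``b_disc`` is an unconstrained log-odds bias, ``eps`` is a
    lapse floor in [0, 0.5).
    """

    alpha1: float = 0.5
    alpha2: float = 0.5
    alpha_seq: float = 0.5
    alpha_T: float = 0.2
    lam: float = 1.0
    beta1: float = 3.0
    beta2: float = 3.0
    w: float = 0.5
    p_int: float = 0.0
    b_disc: float = 0.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha_seq", "alpha_T", "lam", "w", "p_int"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be non-negative")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")


def resolve_params(spec: ModelSpec, values: Mapping[str, float]) -> Params:
    """Build a full :class:`Params` from free-parameter values of ``spec``.

    A shared ``alpha`` fills every learning rate the family uses; ``fixed``
    entries of the spec are applied on top of the defaults.
    """
    free = set(spec.free_params())
    unknown = set(values) - free
    if unknown:
        raise SpecError(f"values {sorted(unknown)} are not free parameters of {spec.spec_id()}")
    kw: dict[str, float] = {}
    merged = dict(spec.fixed)
    merged.update(values)
    for name, v in merged.items():
        if name == "alpha":
            kw["alpha1"] = kw["alpha2"] = kw["alpha_seq"] = v
        else:
            kw[name] = v
    return Params(**kw)


@dataclass
class AgentState:
    """All learned quantities of an agent.

    Arrays are indexed by integer codes (L=0, R=1; S1=0, S2=1; sequences
    L->R=0, R->L=1).  ``Q2[s, a]`` are stage-2 action values, ``Q1mf`` cached
    stage-1 values, ``T[a, s]`` transition estimates (rows sum to one),
    ``Qseq`` sequence values, ``Qflat`` the single-state values of FLAT.
    """

    Q2: np.ndarray
    Q1mf: np.ndarray
    T: np.ndarray
    Qseq: np.ndarray
    Qflat: np.ndarray

    @classmethod
    def init(
        cls,
        spec: ModelSpec,
        params: Params,
        contingency: Mapping[str, str] = DEFAULT_CONTINGENCY,
    ) -> "AgentState":
        q0 = spec.q0
        T = np.empty((2, 2))
        # Transition estimates start at the trained deterministic contingency
        # smoothed by pseudo-count weight kappa.
        hi = (1.0 + spec.kappa / 2.0) / (1.0 + spec.kappa)
        for a in ACTIONS:
            ai = A2I[a]
            ci = S2I[contingency[a]]
            T[ai, ci] = hi
            T[ai, 1 - ci] = 1.0 - hi
        return cls(
            Q2=np.full((2, 2), q0),
            Q1mf=np.full(2, q0),
            T=T,
            Qseq=np.full(2, q0),
            Qflat=np.full(2, q0),
        )

    def copy(self) -> "AgentState":
        return AgentState(
            self.Q2.copy(), self.Q1mf.copy(), self.T.copy(),
            self.Qseq.copy(), self.Qflat.copy(),
        )


@dataclass(frozen=True)
class Responsibilities:
    """Posterior over the latent execution modes of one observed trial.

    ``p_sequence`` is the probability that a sequence option was selected at
    stage 1; ``p_completed`` that it was selected *and* ran to completion;
    ``p_stage2_choice`` (= 1 - p_completed) that the stage-2 action came from
    the stage-2 policy, either after a single action or after an interruption.
    """

    p_sequence: float
    p_completed: float

    @property
    def p_stage2_choice(self) -> float:
        return 1.0 - self.p_completed


# ---------------------------------------------------------------------------
# Values and policies
# ---------------------------------------------------------------------------

def _max_tie_mean(q: np.ndarray) -> float:
    """Max over stage-2 values; exact ties average (uniform tie-break)."""
    return float(q.mean()) if q[0] == q[1] else float(q.max())


def stage1_values(spec: ModelSpec, params: Params, state: AgentState) -> dict[str, float]:
    """Value of every stage-1 option in the spec's option set."""
    vals: dict[str, float] = {}
    if spec.is_flat:
        for a in ACTIONS:
            vals[a] = float(state.Qflat[A2I[a]])
        return vals
    if spec.has_single_actions:
        if spec.is_hybrid:
            w = params.w
        else:
            w = 1.0 if spec.uses_mb else 0.0
        for a in ACTIONS:
            ai = A2I[a]
            v_mb = 0.0
            if w > 0.0:
                v_mb = sum(
                    state.T[ai, si] * _max_tie_mean(state.Q2[si]) for si in (0, 1)
                )
            vals[a] = w * v_mb + (1.0 - w) * float(state.Q1mf[ai])
    if spec.has_sequences:
        for k, seq in enumerate(SEQUENCES):
            vals[seq] = float(state.Qseq[k])
    return vals


def _softmax_lapse(utils: np.ndarray, eps: float) -> np.ndarray:
    z = utils - utils.max()
    p = np.exp(z)
    p /= p.sum()
    return (1.0 - eps) * p + eps / len(p)


def stage1_policy(spec: ModelSpec, params: Params, state: AgentState) -> dict[str, float]:
    """Softmax (inverse temperature beta1) over stage-1 option values, mixed
    with a uniform lapse of weight eps."""
    vals = stage1_values(spec, params, state)
    opts = list(vals)
    utils = params.beta1 * np.array([vals[o] for o in opts])
    p = _softmax_lapse(utils, params.eps)
    return dict(zip(opts, p))


def stage2_policy(
    s2: str, spec: ModelSpec, params: Params, state: AgentState
) -> dict[str, float]:
    """Stage-2 choice distribution over {L, R} in state ``s2``.

    Utilities are beta2 * Q2[s2, a] plus the discrimination bias b_disc on the
    state's discriminative action.  FLAT agents do not represent stage-2
    states and keep choosing from their single-state values with beta1.
    """
    if s2 not in STATES:
        raise ValueError(f"unknown stage-2 state {s2!r}")
    if spec.is_flat:
        utils = params.beta1 * state.Qflat
    else:
        si = S2I[s2]
        disc = A2I[discriminative(s2)]
        utils = params.beta2 * state.Q2[si].copy()
        utils[disc] += params.b_disc
    p = _softmax_lapse(utils, params.eps)
    return {"L": float(p[0]), "R": float(p[1])}


# ---------------------------------------------------------------------------
# Observation likelihood
# ---------------------------------------------------------------------------

def trial_loglik(
    trial: Trial, spec: ModelSpec, params: Params, state: AgentState
) -> tuple[float, Responsibilities]:
    """Log-likelihood of the observed pair (a1, a2), marginalised over the
    latent selection of a sequence option and its possible interruption.

    Returns the log-likelihood and the posterior responsibilities of the
    latent modes given the observation.
    """
    if trial.aborted:
        raise ValueError("aborted trials carry no modelled choices; exclude them")
    a1, s2, a2 = trial.a1, trial.s2, trial.a2
    p1 = stage1_policy(spec, params, state)
    p2 = stage2_policy(s2, spec, params, state)[a2]
    p_single = p1.get(a1, 0.0) if spec.has_single_actions and not spec.is_flat else 0.0
    if spec.is_flat:
        p_single = p1[a1]
    if spec.has_sequences:
        seq = sequence_for(a1)
        p_seq_opt = p1[seq]
        completed = float(a2 == sequence_second(seq))
        p_int = params.p_int
        p_seq_path = p_seq_opt * ((1.0 - p_int) * completed + p_int * p2)
        p_completed_path = p_seq_opt * (1.0 - p_int) * completed
    else:
        p_seq_path = 0.0
        p_completed_path = 0.0
    p_obs = p_single * p2 + p_seq_path
    if p_obs <= 0.0:
        raise ImpossibleObservation(
            f"observation (a1={a1}, s2={s2}, a2={a2}) has probability zero "
            f"under {spec.spec_id()} with p_int={params.p_int}, eps={params.eps}"
        )
    resp = Responsibilities(
        p_sequence=p_seq_path / p_obs, p_completed=p_completed_path / p_obs
    )
    return float(np.log(p_obs)), resp


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------

def update(
    state: AgentState,
    trial: Trial,
    resp: Responsibilities,
    spec: ModelSpec,
    params: Params,
) -> AgentState:
    """One-trial learning update; returns a new state.

    Stage-2 values move toward the reward, stage-1 cached values follow a
    SARSA rule with eligibility weight lam, transition estimates drift toward
    the experienced transition, and sequence values are updated with the
    sequence responsibility as a weight (full updates if the spec disables
    responsibility weighting).  FLAT treats each press as a choice from one
    merged state with immediate feedback: the stage-1 press was followed by
    nothing, the stage-2 press by the reward.
    """
    if trial.aborted:
        raise ValueError("aborted trials are not learned from")
    new = state.copy()
    a1, si, a2i = A2I[trial.a1], S2I[trial.s2], A2I[trial.a2]
    r = float(trial.outcome)
    if spec.is_flat:
        new.Qflat[a1] += params.alpha1 * (0.0 - new.Qflat[a1])
        new.Qflat[a2i] += params.alpha1 * (r - new.Qflat[a2i])
        return new
    q2_before = float(state.Q2[si, a2i])
    new.Q2[si, a2i] += params.alpha2 * (r - new.Q2[si, a2i])
    if spec.uses_mf:
        delta1 = q2_before - new.Q1mf[a1]
        new.Q1mf[a1] += params.alpha1 * delta1 + params.alpha1 * params.lam * (r - q2_before)
    if spec.uses_mb and spec.learn_transitions:
        new.T[a1, si] += params.alpha_T * (1.0 - new.T[a1, si])
        new.T[a1, 1 - si] = 1.0 - new.T[a1, si]
    if spec.has_sequences:
        k = 0 if trial.a1 == "L" else 1
        weight = resp.p_sequence if spec.resp_weighted_seq else 1.0
        new.Qseq[k] += weight * params.alpha_seq * (r - new.Qseq[k])
    return new


# ---------------------------------------------------------------------------
# Generative wrapper for simulation
# ---------------------------------------------------------------------------

class SimAgent:
    """Generative agent: samples options, executes sequences, learns.

    Learning uses the same responsibility-weighted update as the fitted
    likelihood (credit for sequence values is assigned by the posterior over
    latent modes given the observed trial, not by the agent's private mode),
    so simulation and fitting realise exactly the same model — the premise of
    the recovery studies.  Disabling ``resp_weighted_seq`` on the spec
    switches both to full (unweighted) sequence updates.
    """

    def __init__(self, spec: ModelSpec, params: Params,
                 contingency: Mapping[str, str] = DEFAULT_CONTINGENCY):
        self.spec = spec
        self.params = params
        self.contingency = dict(contingency)
        self.state = AgentState.init(spec, params, contingency)
        self._mode: Optional[str] = None
        self._interrupted = False

    def begin_session(self, config) -> None:
        contingency = getattr(config, "contingency", None) or self.contingency
        self.contingency = dict(contingency)
        self.state = AgentState.init(self.spec, self.params, self.contingency)

    def act_stage1(self, rng: np.random.Generator) -> str:
        pol = stage1_policy(self.spec, self.params, self.state)
        opts = list(pol)
        self._mode = opts[rng.choice(len(opts), p=np.array([pol[o] for o in opts]))]
        self._interrupted = False
        if self._mode in SEQUENCES:
            return self._mode.split("->")[0]
        return self._mode

    def act_stage2(self, s2: str, rng: np.random.Generator) -> str:
        if self._mode in SEQUENCES:
            if rng.random() < self.params.p_int:
                self._interrupted = True
            else:
                return sequence_second(self._mode)
        pol = stage2_policy(s2, self.spec, self.params, self.state)
        return "L" if rng.random() < pol["L"] else "R"

    def abort_trial(self) -> None:
        self._mode = None

    def learn(self, trial: Trial) -> None:
        if self.spec.has_sequences:
            _, resp = trial_loglik(trial, self.spec, self.params, self.state)
        else:
            resp = Responsibilities(0.0, 0.0)
        self.state = update(self.state, trial, resp, self.spec, self.params)
        self._mode = None


class MixtureAgent:
    """Per-trial mixture of two controllers (used by the developmental regime).

    On each trial the acting controller is drawn with probability ``w_first``
    for the first agent; both controllers observe and learn from every trial.
    """

    def __init__(self, first: SimAgent, second: SimAgent, w_first: float):
        if not 0.0 <= w_first <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")
        self.first = first
        self.second = second
        self.w_first = w_first
        self._actor: SimAgent = first

    def begin_session(self, config) -> None:
        self.first.begin_session(config)
        self.second.begin_session(config)

    def act_stage1(self, rng: np.random.Generator) -> str:
        self._actor = self.first if rng.random() < self.w_first else self.second
        a1 = self._actor.act_stage1(rng)
        bystander = self.second if self._actor is self.first else self.first
        # Keep the bystander's latent mode consistent with the observed press.
        bystander._mode = None
        return a1

    def act_stage2(self, s2: str, rng: np.random.Generator) -> str:
        return self._actor.act_stage2(s2, rng)

    def abort_trial(self) -> None:
        self.first.abort_trial()
        self.second.abort_trial()

    def learn(self, trial: Trial) -> None:
        # Both controllers observe every trial; responsibilities are marginal,
        # so the bystander can learn from presses it did not generate.
        for agent in (self.first, self.second):
            try:
                agent.learn(trial)
            except ImpossibleObservation:
                agent.state = update(
                    agent.state, trial, Responsibilities(0.0, 0.0),
                    agent.spec, agent.params,
                )
                agent._mode = None
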