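"""Generative model of the two-stage operant task.

Rats choose between two levers ('L', 'R') at stage 1 (state S0), transition to
one of two light-signalled stage-2 states (S1: constant light, S2: blinking
light), and make a second lever press that may deliver a food pellet.  During
training the stage-1 -> stage-2 mapping is deterministic (L -> S2, R -> S1); in
probe sessions the chosen lever leads to its usual ("common") stage-2 state
only with probability ``p_common`` (0.8, or 0.5 in some probes).  Only one
stage-2 state is rewarding at any moment, and only for its discriminative
action (R in S2, L in S1); after every earned pellet the rewarding state
switches sides with probability ``p_reversal``.

This module holds the task dynamics (:func:`transition`, :func:`outcome`,
:func:`maybe_reverse`), the session driver :func:`run_session`, and the
light-weight record types (:class:`Trial`, :class:`Session`,
:class:`SubjectData`) that the rest of the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

ACTIONS = ("L", "R")
STATES = ("S1", "S2")
PHASES = ("training", "probe", "reversed", "strict")

#: Default stage-1 contingency: each lever's "common" stage-2 state.
DEFAULT_CONTINGENCY: Mapping[str, str] = MappingProxyType({"L": "S2", "R": "S1"})
#: Reversed contingency used in the '#'-marked sessions.
REVERSED_CONTINGENCY: Mapping[str, str] = MappingProxyType({"L": "S1", "R": "S2"})

TRIAL_COLUMNS = (
    "subject",
    "session",
    "phase",
    "trial",
    "a1",
    "s2",
    "a2",
    "outcome",
    "transition",
    "aborted",
    "rt",
)


def discriminative(s2: str) -> str:
    """The only stage-2 action ever rewarded in state ``s2`` (R in S2, L in S1)."""
    if s2 == "S2":
        return "R"
    if s2 == "S1":
        return "L"
    raise ValueError(f"unknown stage-2 state {s2!r}")


def other_action(a: str) -> str:
    if a not in ACTIONS:
        raise ValueError(f"unknown action {a!r}")
    return "R" if a == "L" else "L"


def other_state(s: str) -> str:
    if s not in STATES:
        raise ValueError(f"unknown state {s!r}")
    return "S2" if s == "S1" else "S1"


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of one session of the two-stage task.

    Parameters
    ----------
    contingency
        Mapping from stage-1 action to its common stage-2 state.  Must be a
        bijection between {L, R} and {S1, S2}.
    p_common
        Probability that a stage-1 action leads to its common state
        (1.0 in training, 0.8 or 0.5 in probe sessions).
    p_reversal
        Probability that the rewarding stage-2 state flips after an earned
        outcome (0.14 in the main experiment).
    max_outcomes
        Session ends once this many pellets have been earned.
    max_trials
        Hard safety cap on the number of trials per session.
    strict_sequence
        Label for sessions run under the strict-sequence criterion (a magazine
        entry between the two presses aborts the trial).  The simulator only
        generates aborted trials when ``abort_prob`` > 0.
    abort_prob
        Per-trial probability of an abort between stage 1 and stage 2; used to
        exercise the analysis-side exclusion rules, 0 by default.
    rt
        Constant reaction time (seconds) written on simulated trials, or None
        to leave the field empty.
    phase
        Session phase label: training | probe | reversed | strict.
    """

    contingency: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONTINGENCY)
    )
    p_common: float = 1.0
    p_reversal: float = 0.14
    max_outcomes: int = 60
    max_trials: int = 2000
    strict_sequence: bool = False
    abort_prob: float = 0.0
    rt: Optional[float] = None
    phase: str = "training"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError("p_common must be in [0, 1]")
        if not 0.0 <= self.p_reversal <= 1.0:
            raise ValueError("p_reversal must be in [0, 1]")
        if not 0.0 <= self.abort_prob <= 1.0:
            raise ValueError("abort_prob must be in [0, 1]")
        if self.max_outcomes < 1:
            raise ValueError("max_outcomes must be >= 1")
        if self.max_trials is None:
            raise ValueError("max_trials must be set so sessions terminate")
        if self.max_trials < 0:
            raise ValueError("max_trials must be >= 0")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        cont = dict(self.contingency)
        if sorted(cont) != ["L", "R"] or sorted(cont.values()) != ["S1", "S2"]:
            raise ValueError("contingency must map {L,R} bijectively onto {S1,S2}")
        object.__setattr__(self, "contingency", MappingProxyType(cont))

    def reversed(self) -> "TaskConfig":
        """The same session with the stage-1 contingency flipped."""
        flipped = {a: other_state(s) for a, s in self.contingency.items()}
        return replace(self, contingency=flipped, phase="reversed")


@dataclass
class Trial:
    """One trial of the two-stage task.

    ``a2`` is None only on aborted trials.  ``rewarding`` is the latent
    rewarding stage-2 state at the time of the trial; it is known for
    simulated data and None for observed data.
    """

    subject: str
    session: int
    phase: str
    trial: int
    a1: str
    s2: str
    a2: Optional[str]
    outcome: int
    transition: str
    aborted: bool = False
    rt: Optional[float] = None
    rewarding: Optional[str] = None

    def __post_init__(self) -> None:
        if self.a1 not in ACTIONS:
            raise ValueError(f"trial {self.trial}: unknown stage-1 action {self.a1!r}")
        if self.s2 not in STATES:
            raise ValueError(f"trial {self.trial}: unknown stage-2 state {self.s2!r}")
        if self.transition not in ("common", "rare"):
            raise ValueError(f"trial {self.trial}: bad transition label {self.transition!r}")
        if self.outcome not in (0, 1):
            raise ValueError(f"trial {self.trial}: outcome must be 0 or 1")
        if self.aborted:
            if self.a2 is not None:
                raise ValueError(f"trial {self.trial}: aborted trial cannot have a2")
            if self.outcome == 1:
                raise ValueError(f"trial {self.trial}: aborted trial cannot be rewarded")
        elif self.a2 not in ACTIONS:
            raise ValueError(f"trial {self.trial}: unknown stage-2 action {self.a2!r}")


@dataclass
class Session:
    """Ordered trials of one session plus the config that generated them."""

    trials: list[Trial]
    config: TaskConfig
    subject: str = "sub1"
    session: int = 0
    initial_rewarding: Optional[str] = None

    def __post_init__(self) -> None:
        idx = [t.trial for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trial indices must be strictly increasing")
        if sum(t.outcome for t in self.trials) > self.config.max_outcomes:
            raise ValueError("session exceeds max_outcomes")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_outcomes(self) -> int:
        return sum(t.outcome for t in self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        return trials_to_dataframe(self.trials)


@dataclass
class SubjectData:
    """Ordered sessions for one subject."""

    subject: str
    sessions: list[Session] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return trials_to_dataframe(t for s in self.sessions for t in s.trials)


def trials_to_dataframe(trials: Iterable[Trial]) -> pd.DataFrame:
    rows = []
    any_rewarding = False
    for t in trials:
        rows.append(
            {
                "subject": t.subject,
                "session": t.session,
                "phase": t.phase,
                "trial": t.trial,
                "a1": t.a1,
                "s2": t.s2,
                "a2": t.a2,
                "outcome": t.outcome,
                "transition": t.transition,
                "aborted": int(t.aborted),
                "rt": t.rt,
                "rewarding": t.rewarding,
            }
        )
        any_rewarding = any_rewarding or t.rewarding is not None
    cols = list(TRIAL_COLUMNS) + (["rewarding"] if any_rewarding else [])
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


# ---------------------------------------------------------------------------
# Task dynamics
# ---------------------------------------------------------------------------

def transition(a1: str, config: TaskConfig, rng: np.random.Generator) -> tuple[str, str]:
    """Draw the stage-2 state reached after stage-1 action ``a1``.

    Returns ``(s2, label)`` where label is "common" when the action led to its
    usual state under the session contingency and "rare" otherwise.
    """
    if a1 not in ACTIONS:
        raise ValueError(f"unknown stage-1 action {a1!r}")
    common = config.contingency[a1]
    if rng.random() < config.p_common:
        return common, "common"
    return other_state(common), "rare"


def outcome(s2: str, a2: str, rewarding: str) -> int:
    """Reward rule: 1 iff ``s2`` is the rewarding state and ``a2`` its
    discriminative action (R in S2, L in S1)."""
    if s2 not in STATES or rewarding not in STATES:
        raise ValueError("stage-2 states must be S1 or S2")
    if a2 not in ACTIONS:
        raise ValueError(f"unknown stage-2 action {a2!r}")
    return int(s2 == rewarding and a2 == discriminative(s2))


def maybe_reverse(
    rewarding: str, reward: int, config: TaskConfig, rng: np.random.Generator
) -> str:
    """Flip the rewarding stage-2 state with probability ``p_reversal``, but
    only immediately after an earned outcome."""
    if reward not in (0, 1):
        raise ValueError("reward must be 0 or 1")
    if reward and rng.random() < config.p_reversal:
        return other_state(rewarding)
    return rewarding


# ---------------------------------------------------------------------------
# Session driver and scripted agents
# ---------------------------------------------------------------------------

def run_session(
    agent,
    config: TaskConfig,
    rng: np.random.Generator,
    subject: str = "sub1",
    session: int = 0,
) -> Session:
    """Simulate one session with ``agent``.

    The agent must expose ``act_stage1(rng) -> action`` and
    ``act_stage2(s2, rng) -> action``; optionally ``begin_session(config)``,
    ``begin_trial(rewarding)`` (used by scripted oracle agents),
    ``abort_trial()`` and ``learn(trial)``.
    """
    if hasattr(agent, "begin_session"):
        agent.begin_session(config)
    rewarding = STATES[rng.integers(2)]
    initial_rewarding = rewarding
    trials: list[Trial] = []
    n_outcomes = 0
    t = 0
    while n_outcomes < config.max_outcomes and t < config.max_trials:
        if hasattr(agent, "begin_trial"):
            agent.begin_trial(rewarding)
        a1 = agent.act_stage1(rng)
        s2, label = transition(a1, config, rng)
        aborted = config.abort_prob > 0 and rng.random() < config.abort_prob
        if aborted:
            trial = Trial(
                subject, session, config.phase, t, a1, s2, None, 0, label,
                aborted=True, rt=config.rt, rewarding=rewarding,
            )
            if hasattr(agent, "abort_trial"):
                agent.abort_trial()
        else:
            a2 = agent.act_stage2(s2, rng)
            r = outcome(s2, a2, rewarding)
            trial = Trial(
                subject, session, config.phase, t, a1, s2, a2, r, label,
                aborted=False, rt=config.rt, rewarding=rewarding,
            )
            if hasattr(agent, "learn"):
                agent.learn(trial)
            if r:
                n_outcomes += 1
                rewarding = maybe_reverse(rewarding, r, config, rng)
        trials.append(trial)
        t += 1
    return Session(trials, config, subject=subject, session=session,
                   initial_rewarding=initial_rewarding)


class RandomAgent:
    """Presses levers uniformly at random; never learns."""

    def act_stage1(self, rng: np.random.Generator) -> str:
        return ACTIONS[rng.integers(2)]

    def act_stage2(self, s2: str, rng: np.random.Generator) -> str:
        return ACTIONS[rng.integers(2)]


class OracleAgent:
    """Scripted always-correct agent for simulator checks.

    It is told the current rewarding state (via ``begin_trial``), takes the
    stage-1 action whose common state is rewarding, and the discriminative
    stage-2 action.  Under a deterministic contingency it earns a pellet on
    every trial, so reversal statistics can be read off directly.
    """

    def begin_session(self, config: TaskConfig) -> None:
        self._state_to_action = {s: a for a, s in config.contingency.items()}

    def begin_trial(self, rewarding: str) -> None:
        self._rewarding = rewarding

    def act_stage1(self, rng: np.random.Generator) -> str:
        return self._state_to_action[self._rewarding]

    def act_stage2(self, s2: str, rng: np.random.Generator) -> str:
        return discriminative(s2)
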