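"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the study conditions: 8 subjects, ~40 training
sessions under deterministic stage-1 contingencies with 0.14 reward
reversals and a 60-outcome session cap, and probe sessions with 80/20 (or
50/50) transitions inserted mid- and end-training.  A developmental regime
shifts control from a flat, proximal-action learner early in training to a
hierarchical model-based agent later on, which is what produces the
sign-flip of the per-session reward effect in the stay profile.

Per-subject parameters are drawn from population distributions chosen to
yield discriminating, non-degenerate behaviour (learning rates Beta(3,3),
inverse temperatures log-normal with median 3, interruption probability
Beta(2,8), discrimination bias Normal(1, 0.5), hybrid weight Beta(3,3));
all are overridable.  The ground truth (families, drawn parameters, seeds)
is recorded so a dataset can be regenerated bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .agents import MixtureAgent, ModelSpec, SimAgent, resolve_params
from .task import TaskConfig, run_session


# ---------------------------------------------------------------------------
# Parameter distributions
# ---------------------------------------------------------------------------

def _default_sampler(name: str) -> Callable[[np.random.Generator], float]:
    if name in ("alpha", "alpha1", "alpha2", "alpha_seq", "alpha_T", "lam", "w"):
        return lambda rng: float(rng.beta(3, 3))
    if name in ("beta1", "beta2"):
        return lambda rng: float(np.exp(np.log(3.0) + 0.4 * rng.standard_normal()))
    if name == "p_int":
        return lambda rng: float(rng.beta(2, 8))
    if name == "b_disc":
        return lambda rng: float(rng.normal(1.0, 0.5))
    if name == "eps":
        return lambda rng: float(0.25 * rng.beta(2, 8))
    raise KeyError(name)


def draw_params(
    spec: ModelSpec,
    rng: np.random.Generator,
    dists: Optional[Mapping[str, Callable[[np.random.Generator], float]]] = None,
) -> dict[str, float]:
    """Draw one subject's free-parameter values for ``spec``."""
    dists = dict(dists or {})
    return {
        name: float(dists.get(name, _default_sampler(name))(rng))
        for name in spec.free_params()
    }


# ---------------------------------------------------------------------------
# Schedule and regime
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseSpec:
    """A block of identically configured sessions."""

    n_sessions: int
    task: TaskConfig

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


def training_task(**kw) -> TaskConfig:
    return TaskConfig(p_common=1.0, phase="training", **kw)


def probe_task(p_common: float = 0.8, **kw) -> TaskConfig:
    return TaskConfig(p_common=p_common, phase="probe", **kw)


def default_schedule() -> tuple[PhaseSpec, ...]:
    """40 training sessions with a probe inserted mid-training and two at the
    end (80/20 transitions)."""
    return (
        PhaseSpec(20, training_task()),
        PhaseSpec(1, probe_task()),
        PhaseSpec(20, training_task()),
        PhaseSpec(2, probe_task()),
    )


class Regime:
    """Maps session index to the generating controller mixture.

    ``flat_weight(i)`` is the per-trial probability that the flat controller
    acts on session ``i``; a hard developmental switch is weight 1 before
    ``k_switch`` and 0 after, a gradual regime passes an explicit weight
    schedule.
    """

    def __init__(
        self,
        early_family: str = "FLAT",
        late_family: str = "H-MB",
        k_switch: int = 0,
        weights: Optional[Sequence[float]] = None,
    ):
        if weights is not None and any(not 0.0 <= w <= 1.0 for w in weights):
            raise ValueError("mixture weights must lie in [0, 1]")
        if k_switch < 0:
            raise ValueError("k_switch must be >= 0")
        self.early_family = early_family
        self.late_family = late_family
        self.k_switch = k_switch
        self.weights = None if weights is None else list(weights)

    def flat_weight(self, session_index: int) -> float:
        if self.weights is not None:
            i = min(session_index, len(self.weights) - 1)
            return float(self.weights[i])
        return 1.0 if session_index < self.k_switch else 0.0

    def families(self) -> tuple[str, ...]:
        return (self.early_family, self.late_family)


def developmental_mixture(
    k_switch: Optional[int] = None,
    weights: Optional[Sequence[float]] = None,
    early_family: str = "FLAT",
    late_family: str = "H-MB",
) -> Regime:
    """Developmental regime: hard switch at ``k_switch`` or an explicit
    per-session weight schedule for the flat controller."""
    if (k_switch is None) == (weights is None):
        raise ValueError("give exactly one of k_switch or weights")
    return Regime(early_family, late_family, k_switch=k_switch or 0, weights=weights)


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of a synthetic cohort."""

    n_subjects: int = 8
    schedule: tuple[PhaseSpec, ...] = field(default_factory=default_schedule)
    regime: Regime = field(default_factory=lambda: Regime(k_switch=10))
    dists: Optional[Mapping[str, Callable]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.schedule:
            raise ValueError("schedule must be non-empty")


@dataclass
class GroundTruth:
    """Everything needed (with the config) to regenerate a cohort bit-exactly."""

    seed: int
    subjects: list[dict]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"seed": self.seed, "subjects": self.subjects}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], subjects=d["subjects"])


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _subject_agents(
    regime: Regime, dists, rng: np.random.Generator
) -> tuple[dict, dict[str, SimAgent]]:
    """Draw one subject's parameters for both regime controllers."""
    record: dict = {"families": list(regime.families()), "params": {}}
    agents: dict[str, SimAgent] = {}
    for fam in dict.fromkeys(regime.families()):
        spec = ModelSpec(fam)
        values = draw_params(spec, rng, dists)
        record["params"][fam] = values
        agents[fam] = SimAgent(spec, resolve_params(spec, values))
    return record, agents


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate every subject through the schedule.

    Returns the trial-log DataFrame (with the latent ``rewarding`` column)
    and the ground-truth record.  Determinism: all randomness derives from
    ``config.seed`` via spawned child generators, one per subject.
    """
    master = np.random.SeedSequence(config.seed)
    subject_seeds = master.spawn(config.n_subjects)
    frames = []
    gt_subjects = []
    for i, sseq in enumerate(subject_seeds):
        subj = f"sub{i + 1:02d}"
        rng = np.random.default_rng(sseq)
        record, agents = _subject_agents(config.regime, config.dists, rng)
        record["subject"] = subj
        early = agents[config.regime.early_family]
        late = agents[config.regime.late_family]
        session_index = 0
        for phase in config.schedule:
            for _ in range(phase.n_sessions):
                w = config.regime.flat_weight(session_index)
                if w >= 1.0:
                    agent = early
                elif w <= 0.0:
                    agent = late
                else:
                    agent = MixtureAgent(early, late, w)
                sess = run_session(
                    agent, phase.task, rng, subject=subj, session=session_index
                )
                frames.append(sess.to_dataframe())
                session_index += 1
        gt_subjects.append(record)
    df = pd.concat(frames, ignore_index=True)
    return df, GroundTruth(seed=config.seed, subjects=gt_subjects)


def probe_cohort(
    family: str,
    n_subjects: int = 8,
    n_trials: int = 300,
    p_common: float = 0.8,
    seed: int = 0,
    dists: Optional[Mapping[str, Callable]] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """A recovery-style cohort: each subject runs one long probe session
    generated by ``family``'s base model with subject-level parameter draws.

    The session runs for exactly ``n_trials`` trials (the outcome cap is
    lifted), which is the regime used for model- and parameter-recovery
    studies.
    """
    spec = ModelSpec(family)
    task = TaskConfig(
        p_common=p_common, phase="probe",
        max_outcomes=max(n_trials, 1), max_trials=n_trials,
    )
    master = np.random.SeedSequence(seed)
    frames = []
    gt_subjects = []
    for i, sseq in enumerate(master.spawn(n_subjects)):
        subj = f"sub{i + 1:02d}"
        rng = np.random.default_rng(sseq)
        values = draw_params(spec, rng, dists)
        agent = SimAgent(spec, resolve_params(spec, values))
        sess = run_session(agent, task, rng, subject=subj, session=0)
        frames.append(sess.to_dataframe())
        gt_subjects.append({"subject": subj, "families": [family],
                            "params": {family: values}})
    df = pd.concat(frames, ignore_index=True)
    return df, GroundTruth(seed=seed, subjects=gt_subjects)
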