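"""Stay-probability analyses of two-stage choice data.

The diagnostics of interest are logistic regressions of staying on the same
action, as a function of the previous trial:

* per training session, stage-1 stay on previous reward (the developmental
  sign-flip profile: a flat, proximal-action learner produces a *negative*
  reward coefficient, a state-aware learner a positive one);
* in probe sessions, stage-1 stay on reward x transition type — a reward main
  effect marks sequence/model-free control, a reward-by-transition interaction
  marks control by the true state-space;
* in probe sessions, stage-2 stay (restricted to trials whose stage-2 state
  differs from the previous trial) on reward x stage-1 stay — a positive
  interaction is the signature of replaying the whole rewarded sequence.

Filters follow the source analyses: aborted trials are excluded before any
lagging (the previous trial is the last *non-aborted* one), the first usable
trial per session has no predecessor, and by default only trials whose
predecessor was a correct discrimination (R in S2, L in S1) are kept; a flag
disables that filter for the control analysis that instead adds a "correct
previous stage-1 action" predictor.

The default regression engine is a two-stage summary-statistics analysis:
every fixed effect is estimated per subject (per session within subject when
several sessions are pooled, then averaged within subject) and aggregated
across subjects, with Wald confidence intervals (estimate +/- 1.96 SE).  A
variational mixed-effects logistic engine (statsmodels) is available as
``engine="vb"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .task import other_state

LAG_COLUMNS = (
    "reward_prev", "stay1", "stay2", "transition_prev",
    "same_s2_as_prev", "correct_disc_prev", "correct_prev",
)

TERMS = (
    "intercept", "reward", "transition", "stay", "correct",
    "reward:transition", "reward:stay",
)

_DISC = {"S1": "L", "S2": "R"}


class SeparationWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Annotation and filters
# ---------------------------------------------------------------------------

def annotate(df: pd.DataFrame) -> pd.DataFrame:
    """Add previous-trial (lag) fields to a trial log.

    Lags never cross session boundaries, and aborted trials are dropped
    before lagging, so the "previous trial" of any row is the most recent
    non-aborted trial of the same session.  Derived fields are NaN on rows
    with no usable predecessor (first of session, or aborted rows
    themselves).  ``correct_prev`` (previous stage-1 action led commonly to
    the rewarding state) requires the simulator's ``rewarding`` column and is
    NaN otherwise.
    """
    for col in ("subject", "session", "trial", "a1", "s2", "a2", "outcome",
                "transition", "aborted"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    aborted = df["aborted"].astype(int).astype(bool)
    tr = df["trial"].to_numpy()
    for _, idx in df.groupby(["subject", "session"], sort=False).indices.items():
        t = tr[np.sort(idx)]
        if np.any(np.diff(t) <= 0):
            raise ValueError("trial indices must be strictly increasing within sessions")

    work = df.loc[~aborted].copy()
    grp = work.groupby(["subject", "session"], sort=False)
    prev = grp.shift(1)
    has_prev = prev["a1"].notna()

    def masked(values: pd.Series) -> pd.Series:
        return values.where(has_prev)

    work["reward_prev"] = masked(prev["outcome"].astype(float))
    work["stay1"] = masked((work["a1"] == prev["a1"]).astype(float))
    work["stay2"] = masked((work["a2"] == prev["a2"]).astype(float))
    work["transition_prev"] = prev["transition"].where(has_prev)
    work["same_s2_as_prev"] = masked((work["s2"] == prev["s2"]).astype(float))
    work["correct_disc_prev"] = masked(
        (prev["a2"] == prev["s2"].map(_DISC)).astype(float)
    )
    # Common stage-2 state of the current row's a1, decoded from the label.
    common_now = work["s2"].where(
        work["transition"] == "common", work["s2"].map(other_state)
    )
    if "rewarding" in work.columns and work["rewarding"].notna().any():
        prev_common = common_now.groupby(
            [work["subject"], work["session"]], sort=False
        ).shift(1)
        work["correct_prev"] = masked(
            (prev_common == prev["rewarding"]).astype(float)
        )
    else:
        work["correct_prev"] = np.nan

    out = df.copy()
    for col in LAG_COLUMNS:
        out[col] = np.nan
        out[col] = out[col].astype(object)
        out.loc[work.index, col] = work[col]
    # keep numeric dtype where possible
    for col in LAG_COLUMNS:
        if col != "transition_prev":
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return out


def _is_annotated(df: pd.DataFrame) -> bool:
    return all(c in df.columns for c in LAG_COLUMNS)


def filter_stage1(df: pd.DataFrame, require_correct_disc: bool = True) -> pd.DataFrame:
    """Trials usable for the stage-1 stay analysis.

    Drops aborted trials and trials without a usable predecessor; when
    ``require_correct_disc`` (the default, matching the source analyses) only
    trials whose predecessor was a correct discrimination are kept.
    """
    if not _is_annotated(df):
        df = annotate(df)
    keep = (df["aborted"].astype(int) == 0) & df["reward_prev"].notna()
    if require_correct_disc:
        keep &= df["correct_disc_prev"] == 1
    return df.loc[keep]


def filter_stage2(df: pd.DataFrame, require_correct_disc: bool = True) -> pd.DataFrame:
    """Trials usable for the stage-2 stay analysis: stage-1 rules plus the
    requirement that the stage-2 state differs from the previous trial's."""
    sub = filter_stage1(df, require_correct_disc=require_correct_disc)
    return sub.loc[sub["same_s2_as_prev"] == 0]


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

@dataclass
class RegressionTable:
    """Logistic stay-regression estimates with Wald intervals.

    ``table`` has one row per term: estimate (log-odds), se, ci_lo, ci_hi, p.
    ``converged`` is False when too few groups were estimable or a group
    needed a flagged fallback; details are in ``flags``.
    """

    table: pd.DataFrame
    outcome: str
    n_trials: int
    n_subjects: int
    n_sessions: int
    engine: str
    random_effects: str
    converged: bool
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.set_index("term").loc[term]

    def summary(self) -> str:
        head = (
            f"Stay regression ({self.outcome}); engine={self.engine}; "
            f"random effects: {self.random_effects}\n"
            f"trials={self.n_trials} subjects={self.n_subjects} "
            f"sessions={self.n_sessions} converged={self.converged}"
        )
        if self.flags:
            head += "\nflags: " + "; ".join(self.flags)
        return head + "\n" + self.table.to_string(index=False)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["n"] = self.n_trials
        out["converged"] = self.converged
        out.to_csv(path, index=False)


def _design(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix with centered (+/- 0.5) predictor coding.

    Centering makes each main effect the average effect across the levels of
    the other factors and the intercept the overall stay tendency, which is
    how the diagnostics are read: a reward main effect marks
    sequence/model-free control averaged over transition types, the
    reward-by-transition interaction marks state-space use."""
    base = {
        "intercept": lambda: np.ones(len(df)),
        "reward": lambda: df["reward_prev"].to_numpy(float) - 0.5,
        "transition": lambda: (df["transition_prev"] == "common").to_numpy(float) - 0.5,
        "stay": lambda: df["stay1"].to_numpy(float) - 0.5,
        "correct": lambda: df["correct_prev"].to_numpy(float) - 0.5,
    }
    cols = {}
    for term in terms:
        if term in base:
            cols[term] = base[term]()
        elif term == "reward:transition":
            cols[term] = base["reward"]() * base["transition"]()
        elif term == "reward:stay":
            cols[term] = base["reward"]() * base["stay"]()
        else:
            raise ValueError(f"unknown term {term!r}; terms must be among {TERMS}")
    X = np.column_stack([cols[t] for t in terms])
    return X, list(terms)


def _fit_group_glm(y: np.ndarray, X: np.ndarray, terms: Sequence[str]):
    """Per-group logistic fit; returns (params, bse, flag) or (None, None, reason)."""
    if len(y) < len(terms) + 1 or y.min() == y.max():
        return None, None, "degenerate outcome"
    # every non-intercept regressor must vary within the group
    for j, t in enumerate(terms):
        if t != "intercept" and np.ptp(X[:, j]) == 0:
            return None, None, f"constant predictor {t}"
    flag = None
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params, float)
        bse = np.asarray(res.bse, float)
        if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 15:
            raise ValueError("separation")
    except Exception:
        # quasi-separation: ridge-stabilised point estimate, flagged
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
            params = np.asarray(res.params, float)
            bse = None
            flag = "ridge-stabilised (separation)"
        except Exception:
            return None, None, "fit failed"
    if not np.all(np.isfinite(params)):
        return None, None, "fit failed"
    return params, bse, flag


def _fixed_combine(B: np.ndarray, SE: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance fixed-effect combination along axis 0 (per term)."""
    w = 1.0 / SE**2
    est = np.sum(w * B, axis=0) / np.sum(w, axis=0)
    return est, 1.0 / np.sqrt(np.sum(w, axis=0))


def _dl_combine(B: np.ndarray, SE: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DerSimonian-Laird random-effects combination of per-subject estimates.

    Per term: estimate between-subject variance tau^2 from the Q statistic,
    then combine with weights 1/(se^2 + tau^2).  Under homogeneity this
    reduces to the pooled inverse-variance estimate."""
    k, p = B.shape
    est = np.empty(p)
    se_out = np.empty(p)
    for j in range(p):
        b, se = B[:, j], SE[:, j]
        w = 1.0 / se**2
        bw = np.sum(w * b) / np.sum(w)
        q = np.sum(w * (b - bw) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
        ws = 1.0 / (se**2 + tau2)
        est[j] = np.sum(ws * b) / np.sum(ws)
        se_out[j] = 1.0 / np.sqrt(np.sum(ws))
    return est, se_out


def stay_regression(
    subset: pd.DataFrame,
    outcome: str = "stay1",
    terms: Sequence[str] = ("intercept", "reward", "transition", "reward:transition"),
    engine: str = "summary",
) -> RegressionTable:
    """Mixed logistic regression of staying, with effects varying by subject.

    Parameters
    ----------
    subset
        Output of :func:`filter_stage1` / :func:`filter_stage2` (annotated and
        filtered trials).
    outcome
        "stay1" or "stay2".
    terms
        Fixed-effect terms drawn from {intercept, reward, transition, stay,
        correct, reward:transition, reward:stay}; predictors are coded 0/1
        (transition: common=1).
    engine
        "summary" (default): per-subject estimates — per session within
        subject when the subset pools several sessions (the nested structure)
        — aggregated across subjects; Wald CI = mean +/- 1.96 sd/sqrt(k).
        "vb": statsmodels variational Bayes mixed logistic with subject
        random intercepts.
    """
    if outcome not in ("stay1", "stay2"):
        raise ValueError("outcome must be stay1 or stay2")
    if subset.empty:
        raise ValueError("empty subset; apply filters to a non-empty dataset")
    sub = subset.loc[subset[outcome].notna()]
    y_all = sub[outcome].to_numpy(float)
    X_all, terms = _design(sub, terms)
    n_sessions = int(sub["session"].nunique())
    subjects = list(pd.unique(sub["subject"]))
    flags: list[str] = []

    if engine == "vb":
        est, se, flags_vb = _fit_vb(y_all, X_all, sub["subject"].to_numpy())
        flags.extend(flags_vb)
        k_used = len(subjects)
        random_effects = "subject random intercepts (variational)"
        converged = not flags_vb
    elif engine == "summary":
        nested = n_sessions > 1
        per_subject: list[np.ndarray] = []
        per_subject_se: list[Optional[np.ndarray]] = []
        for subj in subjects:
            m_subj = (sub["subject"] == subj).to_numpy()
            if nested:
                sess_b, sess_se = [], []
                for sess in pd.unique(sub.loc[m_subj, "session"]):
                    m = m_subj & (sub["session"] == sess).to_numpy()
                    params, bse, flag = _fit_group_glm(y_all[m], X_all[m], terms)
                    if params is not None:
                        sess_b.append(params)
                        sess_se.append(bse)
                        if flag:
                            flags.append(f"{subj}/s{sess}: {flag}")
                if sess_b:
                    B = np.vstack(sess_b)
                    if all(s is not None for s in sess_se):
                        b, se_subj = _fixed_combine(B, np.vstack(sess_se))
                    else:
                        b, se_subj = B.mean(axis=0), None
                    per_subject.append(b)
                    per_subject_se.append(se_subj)
                else:
                    flags.append(f"{subj}: no estimable session")
            else:
                params, bse, flag = _fit_group_glm(y_all[m_subj], X_all[m_subj], terms)
                if params is not None:
                    per_subject.append(params)
                    per_subject_se.append(bse)
                    if flag:
                        flags.append(f"{subj}: {flag}")
                else:
                    flags.append(f"{subj}: {flag}")
        k_used = len(per_subject)
        random_effects = (
            "all effects varying across sessions within subjects (nested)"
            if nested else "all effects varying across subjects"
        )
        if k_used < 2:
            est = np.full(len(terms), np.nan)
            se = np.full(len(terms), np.nan)
            converged = False
            flags.append("fewer than 2 estimable subjects")
        else:
            B = np.vstack(per_subject)
            # subjects whose SEs are unavailable (ridge path) borrow the
            # median SE of the others so they still enter the combination
            have = [s for s in per_subject_se if s is not None]
            if have:
                med = np.median(np.vstack(have), axis=0)
                SE = np.vstack([s if s is not None else med for s in per_subject_se])
                est, se = _dl_combine(B, SE)
            else:
                est = B.mean(axis=0)
                se = B.std(axis=0, ddof=1) / np.sqrt(k_used)
                flags.append("no subject-level SEs; unweighted aggregation")
            converged = not any("no estimable" in f or "failed" in f for f in flags)
    else:
        raise ValueError("engine must be 'summary' or 'vb'")

    with np.errstate(divide="ignore", invalid="ignore"):
        zval = est / se
        pvals = 2 * norm.sf(np.abs(zval))
    table = pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "ci_lo": est - 1.96 * se,
            "ci_hi": est + 1.96 * se,
            "p": pvals,
        }
    )
    return RegressionTable(
        table=table,
        outcome=outcome,
        n_trials=int(len(sub)),
        n_subjects=len(subjects),
        n_sessions=n_sessions,
        engine=engine,
        random_effects=random_effects,
        converged=converged,
        flags=flags,
    )


def _fit_vb(y: np.ndarray, X: np.ndarray, subjects: np.ndarray):
    """Variational mixed logistic with subject random intercepts."""
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    flags: list[str] = []
    codes, _ = pd.factorize(subjects)
    n_groups = codes.max() + 1
    Z = np.zeros((len(y), n_groups))
    Z[np.arange(len(y)), codes] = 1.0
    ident = np.zeros(n_groups, dtype=int)
    try:
        md = BinomialBayesMixedGLM(y, X, Z, ident)
        res = md.fit_vb()
        est = np.asarray(res.fe_mean, float)
        se = np.asarray(res.fe_sd, float)
    except Exception as exc:  # pragma: no cover - fallback path
        flags.append(f"vb failed ({type(exc).__name__})")
        est = np.full(X.shape[1], np.nan)
        se = np.full(X.shape[1], np.nan)
    return est, se, flags


def session_stay_profile(
    data: pd.DataFrame, require_correct_disc: bool = True
) -> pd.DataFrame:
    """Per-session stage-1 reward effect (the developmental profile).

    For every session a stage-1 stay regression with terms
    {intercept, reward} and subject-varying effects; returns one row per
    session with the reward log-odds coefficient (the bar height of the
    profile figure), the intercept, their p-values, and a flag for sessions
    that could not be estimated (fewer than 2 usable trials, constant reward
    predictor, or fewer than 2 estimable subjects).
    """
    ann = data if _is_annotated(data) else annotate(data)
    rows = []
    for sess in sorted(pd.unique(ann["session"])):
        sdf = filter_stage1(ann.loc[ann["session"] == sess], require_correct_disc)
        row = {
            "session": sess,
            "phase": sdf["phase"].iloc[0] if len(sdf) else None,
            "n_trials": int(len(sdf)),
            "reward_coef": np.nan,
            "reward_se": np.nan,
            "reward_p": np.nan,
            "intercept": np.nan,
            "intercept_p": np.nan,
            "flagged": True,
        }
        if len(sdf) >= 2 and sdf["reward_prev"].nunique() > 1:
            try:
                reg = stay_regression(sdf, "stay1", terms=("intercept", "reward"))
            except ValueError:
                reg = None
            if reg is not None and reg.converged:
                row.update(
                    reward_coef=reg["reward"]["estimate"],
                    reward_se=reg["reward"]["se"],
                    reward_p=reg["reward"]["p"],
                    intercept=reg["intercept"]["estimate"],
                    intercept_p=reg["intercept"]["p"],
                    flagged=False,
                )
        rows.append(row)
    return pd.DataFrame(rows)
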