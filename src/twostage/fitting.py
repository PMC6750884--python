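"""MAP estimation, Laplace model evidence and model comparison.

The fitting surface follows the statsmodels convention: :class:`AgentModel`
is built from one subject's trial data and a :class:`~twostage.agents.ModelSpec`;
``fit()`` returns an :class:`AgentResults` carrying MAP estimates, curvature,
per-subject log model-evidence and pseudo-r2, with a ``summary()`` table.
:func:`compare` fits a candidate set to every subject and aggregates a
group-level evidence table.

Parameters are estimated on an unconstrained scale (logit for rates and
probabilities, log for inverse temperatures) with independent normal priors,
and the marginal likelihood of each subject's choices is approximated at the
MAP by Laplace's method,

    log p(D|M) ~ -nll + log prior + (d/2) log(2 pi) - (1/2) log |H|,

with H the negative Hessian of the log posterior on the transformed scale.
Group evidence is the sum over subjects; differences between models are log
Bayes factors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _kernel
from .agents import ModelSpec, Params, SpecError, resolve_params
from .task import Session, SubjectData

LN2 = float(np.log(2.0))

#: transform kind per parameter name: unit -> logit, pos -> log,
#: half -> logit scaled to [0, 0.5), real -> identity.
_TRANSFORMS = {
    "alpha": "unit", "alpha1": "unit", "alpha2": "unit", "alpha_seq": "unit",
    "alpha_T": "unit", "lam": "unit", "w": "unit", "p_int": "unit",
    "beta1": "pos", "beta2": "pos", "eps": "half", "b_disc": "real",
}
_DEFAULT_SCALE = {"b_disc": 2.0}


class FitFailure(RuntimeError):
    """The objective was non-finite at every restart."""


def to_natural(name: str, z: float) -> float:
    kind = _TRANSFORMS[name]
    if kind == "unit":
        return float(expit(z))
    if kind == "pos":
        return float(np.exp(z))
    if kind == "half":
        return float(0.5 * expit(z))
    return float(z)


def to_unconstrained(name: str, x: float) -> float:
    kind = _TRANSFORMS[name]
    if kind == "unit":
        return float(logit(x))
    if kind == "pos":
        return float(np.log(x))
    if kind == "half":
        return float(logit(2.0 * x))
    return float(x)


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the transformed (unconstrained) scale."""

    loc: Mapping[str, float] = field(default_factory=dict)
    scale: Mapping[str, float] = field(default_factory=dict)

    def arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        loc = np.array([self.loc.get(n, 0.0) for n in names], float)
        scale = np.array(
            [self.scale.get(n, _DEFAULT_SCALE.get(n, 1.0)) for n in names], float
        )
        if np.any(scale <= 0):
            raise ValueError("prior scales must be positive")
        return loc, scale


# ---------------------------------------------------------------------------
# Generic MAP + Laplace core
# ---------------------------------------------------------------------------

@dataclass
class MAPResult:
    z: np.ndarray
    nll: float
    log_prior: float
    hessian: np.ndarray
    hessian_logdet: Optional[float]
    log_evidence: float
    bic_fallback: bool
    grad_norm: float
    converged: bool
    n_restarts: int
    seed: int


def _normal_logpdf(z: np.ndarray, loc: np.ndarray, scale: np.ndarray) -> float:
    finite = np.isfinite(scale)
    if not np.any(finite):
        return 0.0
    z, loc, scale = z[finite], loc[finite], scale[finite]
    return float(
        -0.5 * np.sum(((z - loc) / scale) ** 2)
        - np.sum(np.log(scale))
        - 0.5 * len(z) * np.log(2 * np.pi)
    )


def _fd_gradient(f: Callable, z: np.ndarray, step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(z)
    for i in range(len(z)):
        e = np.zeros_like(z)
        e[i] = step
        g[i] = (f(z + e) - f(z - e)) / (2 * step)
    return g


def _fd_hessian(f: Callable, z: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-finite-difference Hessian on the transformed scale."""
    d = len(z)
    H = np.empty((d, d))
    f0 = f(z)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(z + ei) - 2 * f0 + f(z - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(z + ei + ej) - f(z + ei - ej) - f(z - ei + ej) + f(z - ei - ej)
            ) / (4 * step**2)
    return H


def laplace_evidence(
    nll: float, log_prior: float, d: int, hessian_logdet: float
) -> float:
    """Per-subject log evidence from MAP quantities (Laplace approximation)."""
    return -nll + log_prior + 0.5 * d * np.log(2 * np.pi) - 0.5 * hessian_logdet


def laplace_fit(
    nll_fn: Callable[[np.ndarray], float],
    prior_loc: np.ndarray,
    prior_scale: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
    hessian_step: float = 1e-4,
    gtol: float = 1e-6,
    n_obs: Optional[int] = None,
    maxiter: int = 300,
) -> MAPResult:
    """Maximise log-likelihood + log-prior on the unconstrained scale with
    random restarts drawn from the prior, then Laplace-approximate the
    marginal likelihood at the optimum.

    A non-positive-definite Hessian triggers a per-subject BIC fallback
    (flagged on the result); ``n_obs`` is required for that path.
    """
    prior_loc = np.asarray(prior_loc, float)
    prior_scale = np.asarray(prior_scale, float)
    d = len(prior_loc)

    def objective(z: np.ndarray) -> float:
        v = nll_fn(z) - _normal_logpdf(z, prior_loc, prior_scale)
        return v if np.isfinite(v) else 1e12

    rng = np.random.default_rng(seed)
    start_scale = np.where(np.isfinite(prior_scale), prior_scale, 1.0)
    start_loc = np.where(np.isfinite(prior_loc), prior_loc, 0.0)
    starts = [start_loc.copy()]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(start_loc + start_scale * rng.standard_normal(d))

    best = None
    for z0 in starts:
        if not np.isfinite(objective(z0)):
            continue
        res = minimize(
            objective, z0, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": min(gtol, 1e-7)},
        )
        if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailure("objective non-finite at every restart")

    z_hat = best.x
    nll = float(nll_fn(z_hat))
    log_prior = _normal_logpdf(z_hat, prior_loc, prior_scale)
    grad_norm = float(np.max(np.abs(_fd_gradient(objective, z_hat))))
    if d == 0:
        return MAPResult(z_hat, nll, log_prior, np.zeros((0, 0)), 0.0,
                         -nll + log_prior, False, 0.0, True, n_restarts, seed)
    H = _fd_hessian(objective, z_hat, step=hessian_step)
    eig = np.linalg.eigvalsh(0.5 * (H + H.T))
    if np.all(eig > 0):
        hess_logdet: Optional[float] = float(np.sum(np.log(eig)))
        log_ev = laplace_evidence(nll, log_prior, d, hess_logdet)
        bic = False
    else:
        if n_obs is None or n_obs <= 0:
            raise FitFailure("non-positive-definite Hessian and no n_obs for BIC fallback")
        hess_logdet = None
        log_ev = -nll - 0.5 * d * np.log(n_obs)
        bic = True
    return MAPResult(
        z_hat, nll, log_prior, H, hess_logdet, float(log_ev), bic,
        grad_norm, grad_norm < max(gtol, 1e-3), n_restarts, seed,
    )


def pseudo_r2(nll: float, n_choices: int) -> float:
    """1 - nll / (n log 2): variance accounted for relative to a random-choice
    model, where n counts modelled binary decisions (two per trial)."""
    if n_choices <= 0:
        raise ValueError("n_choices must be positive")
    return 1.0 - nll / (n_choices * LN2)


# ---------------------------------------------------------------------------
# The agent model proper
# ---------------------------------------------------------------------------

class AgentModel:
    """One subject's trial data paired with a candidate model specification.

    Parameters
    ----------
    data
        A trial-log DataFrame for a single subject (or a
        :class:`~twostage.task.SubjectData` / :class:`~twostage.task.Session`).
        Aborted trials are excluded from the likelihood; learned values reset
        at each session boundary.
    spec
        The model family and toggle set to fit.
    priors
        Optional :class:`PriorSpec` overriding the default standard-normal
        priors on the transformed scale.
    """

    def __init__(self, data, spec: ModelSpec, priors: Optional[PriorSpec] = None):
        if isinstance(data, SubjectData):
            df = data.to_dataframe()
        elif isinstance(data, Session):
            df = data.to_dataframe()
        else:
            df = data
        if not df.empty and df["subject"].nunique() > 1:
            raise ValueError(
                "AgentModel fits one subject; use from_dataframe(subject=...) "
                "or compare() for cohorts"
            )
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.subject = None if df.empty else str(df["subject"].iloc[0])
        self.free_names = list(spec.free_params())
        self.prior_loc, self.prior_scale = self.priors.arrays(self.free_names)
        self.sessions = []
        if not df.empty:
            for _, sdf in df.groupby("session", sort=True):
                arrs = _kernel.session_arrays(sdf)
                if len(arrs["a1"]):
                    self.sessions.append(arrs)
        self.n_trials = int(sum(len(s["a1"]) for s in self.sessions))
        self.n_choices = 2 * self.n_trials

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, spec: ModelSpec,
        subject: Optional[str] = None, priors: Optional[PriorSpec] = None,
    ) -> "AgentModel":
        if subject is not None:
            df = df[df["subject"] == subject]
        return cls(df, spec, priors=priors)

    # -- likelihood ---------------------------------------------------------
    def params_from_z(self, z: np.ndarray) -> Params:
        values = {n: to_natural(n, zi) for n, zi in zip(self.free_names, z)}
        return resolve_params(self.spec, values)

    def z_from_values(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array(
            [to_unconstrained(n, values[n]) for n in self.free_names], float
        )

    def nll(self, values: Mapping[str, float]) -> float:
        """Negative log-likelihood at free-parameter ``values`` (natural scale)."""
        params = resolve_params(self.spec, dict(values))
        return _kernel.dataset_nll(self.spec, params, self.sessions)

    def nll_z(self, z: np.ndarray) -> float:
        return _kernel.dataset_nll(self.spec, self.params_from_z(z), self.sessions)

    def loglike(self, values: Mapping[str, float]) -> float:
        return -self.nll(values)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        n_restarts: int = 10,
        seed: int = 0,
        hessian_step: float = 1e-4,
        gtol: float = 1e-6,
    ) -> "AgentResults":
        if self.n_trials == 0:
            # Degenerate branch: MAP at the prior mode, p(D|M) = 1.
            z = self.prior_loc.copy()
            return AgentResults(
                model=self,
                map_result=MAPResult(
                    z, 0.0, _normal_logpdf(z, self.prior_loc, self.prior_scale),
                    np.zeros((len(z),) * 2), None, 0.0, False, 0.0, True,
                    n_restarts, seed,
                ),
            )
        mr = laplace_fit(
            self.nll_z, self.prior_loc, self.prior_scale,
            n_restarts=n_restarts, seed=seed, hessian_step=hessian_step,
            gtol=gtol, n_obs=self.n_choices,
        )
        return AgentResults(model=self, map_result=mr)


class AgentResults:
    """MAP fit of one :class:`AgentModel`: estimates, curvature, evidence."""

    def __init__(self, model: AgentModel, map_result: MAPResult):
        self.model = model
        self.spec = model.spec
        self._mr = map_result
        self.free_names = model.free_names
        self.z_hat = map_result.z
        self.params = {
            n: to_natural(n, z) for n, z in zip(self.free_names, self.z_hat)
        }
        self.nll = map_result.nll
        self.log_prior = map_result.log_prior
        self.hessian = map_result.hessian
        self.hessian_logdet = map_result.hessian_logdet
        self.log_evidence = map_result.log_evidence
        self.bic_fallback = map_result.bic_fallback
        self.grad_norm = map_result.grad_norm
        self.converged = map_result.converged
        self.seed = map_result.seed
        self.n_restarts = map_result.n_restarts
        self.n_choices = model.n_choices
        self.df_model = len(self.free_names)

    @property
    def pseudo_r2(self) -> float:
        if self.n_choices == 0:
            return float("nan")
        return pseudo_r2(self.nll, self.n_choices)

    def bse_z(self) -> np.ndarray:
        """Posterior standard errors on the transformed scale (inverse
        curvature); NaN under the BIC fallback."""
        d = len(self.free_names)
        if d == 0 or self.hessian_logdet is None or self.n_choices == 0:
            return np.full(d, np.nan)
        cov = np.linalg.inv(0.5 * (self.hessian + self.hessian.T))
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))

    def bse(self) -> dict[str, float]:
        """Delta-method standard errors on the natural scale."""
        out = {}
        for name, z, sz in zip(self.free_names, self.z_hat, self.bse_z()):
            kind = _TRANSFORMS[name]
            if kind == "unit":
                deriv = expit(z) * (1 - expit(z))
            elif kind == "pos":
                deriv = np.exp(z)
            elif kind == "half":
                deriv = 0.5 * expit(z) * (1 - expit(z))
            else:
                deriv = 1.0
            out[name] = float(sz * deriv)
        return out

    def to_dict(self) -> dict:
        return {
            "subject": self.model.subject,
            "spec_id": self.spec.spec_id(),
            "family": self.spec.family,
            "df": self.df_model,
            "params": dict(self.params),
            "nll": self.nll,
            "log_prior": self.log_prior,
            "hessian_logdet": self.hessian_logdet,
            "log_evidence": self.log_evidence,
            "pseudo_r2": self.pseudo_r2,
            "n_choices": self.n_choices,
            "bic_fallback": self.bic_fallback,
            "grad_norm": self.grad_norm,
            "converged": self.converged,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
        }

    def summary(self) -> str:
        bse = self.bse()
        lines = [
            f"Agent model fit: {self.spec.spec_id()}  subject={self.model.subject}",
            f"  trials={self.model.n_trials}  choices={self.n_choices}  df={self.df_model}",
            f"  nll={self.nll:.3f}  log-evidence={self.log_evidence:.3f}  "
            f"pseudo-r2={self.pseudo_r2:.3f}",
            f"  converged={self.converged}  grad_norm={self.grad_norm:.2e}  "
            f"bic_fallback={self.bic_fallback}",
            f"  {'param':<10}{'estimate':>12}{'se':>12}",
        ]
        for n in self.free_names:
            lines.append(f"  {n:<10}{self.params[n]:>12.4f}{bse[n]:>12.4f}")
        return "\n".join(lines)


def fit_map(
    spec: ModelSpec, subject_data, priors: Optional[PriorSpec] = None, **kwargs
) -> AgentResults:
    """Functional wrapper: MAP-fit ``spec`` to one subject's data."""
    return AgentModel(subject_data, spec, priors=priors).fit(**kwargs)


# ---------------------------------------------------------------------------
# Model enumeration and group comparison
# ---------------------------------------------------------------------------

_TOGGLE_APPLICABLE = {
    "separate_alphas": lambda s: s.family != "FLAT",
    "eligibility": lambda s: s.uses_mf,
    "interruption": lambda s: s.has_sequences,
    "disc_bias": lambda s: s.family != "FLAT",
    "lapse": lambda s: True,
    "learn_transitions": lambda s: s.uses_mb,
}


def enumerate_models(
    family: str, toggle_grid: Optional[Mapping[str, Sequence[bool]]] = None
) -> list[ModelSpec]:
    """Cartesian product of toggle settings for one family, deduplicated.

    An empty (or None) grid yields the family's base model.  Requesting a
    toggle the family cannot express raises :class:`SpecError`.
    """
    base = ModelSpec(family)
    grid = dict(toggle_grid or {})
    for key in grid:
        if key not in _TOGGLE_APPLICABLE:
            raise SpecError(f"unknown toggle {key!r}")
        if not _TOGGLE_APPLICABLE[key](base):
            raise SpecError(f"toggle {key!r} is inapplicable to family {family}")
    keys = list(grid)
    specs: list[ModelSpec] = []
    seen = set()
    for combo in itertools.product(*(grid[k] for k in keys)) if keys else [()]:
        spec = ModelSpec(family, **dict(zip(keys, combo)))
        if spec.spec_id() not in seen:
            seen.add(spec.spec_id())
            specs.append(spec)
    return specs


class EvidenceTable:
    """Group-level model comparison: one row per candidate spec, sorted by
    ascending group negative log model-evidence (lower is better)."""

    COLUMNS = (
        "family", "spec_id", "df", "group_neg_log_evidence",
        "mean_pseudo_r2", "best_in_family", "n_failed",
    )

    def __init__(self, table: pd.DataFrame, fits: Optional[dict] = None):
        self.table = table.reset_index(drop=True)
        self.fits = fits or {}

    def best(self, family: Optional[str] = None) -> pd.Series:
        t = self.table if family is None else self.table[self.table["family"] == family]
        return t.iloc[0]

    def top_k(self, k: int = 8) -> pd.DataFrame:
        """Top-k specs per family (the model-evidence figure analog)."""
        return (
            self.table.groupby("family", sort=False, group_keys=False)
            .head(k)
            .reset_index(drop=True)
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __repr__(self) -> str:
        return f"EvidenceTable\n{self.table.to_string(index=False)}"


def compare(
    specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 10,
    seed: int = 0,
    keep_fits: bool = False,
) -> EvidenceTable:
    """Fit every spec to every subject and aggregate group evidence.

    Subject-level fit failures are recorded in ``n_failed`` (and drop the
    subject from that spec's sums) rather than raising.
    """
    subjects = list(pd.unique(data["subject"]))
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[tuple[str, str], AgentResults] = {}
    for spec in specs:
        group_ev = 0.0
        r2s = []
        n_failed = 0
        for subj in subjects:
            fit_seed = int(rng.integers(2**31))
            model = AgentModel.from_dataframe(data, spec, subject=subj, priors=priors)
            try:
                res = model.fit(n_restarts=n_restarts, seed=fit_seed)
            except FitFailure:
                n_failed += 1
                continue
            group_ev += res.log_evidence
            if res.n_choices > 0:
                r2s.append(res.pseudo_r2)
            if keep_fits:
                fits[(spec.spec_id(), subj)] = res
        rows.append(
            {
                "family": spec.family,
                "spec_id": spec.spec_id(),
                "df": spec.df,
                "group_neg_log_evidence": -group_ev if n_failed < len(subjects) else np.nan,
                "mean_pseudo_r2": float(np.mean(r2s)) if r2s else np.nan,
                "n_failed": n_failed,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "group_neg_log_evidence", na_position="last", kind="mergesort"
    )
    best_rows = table.groupby("family")["group_neg_log_evidence"].idxmin()
    table["best_in_family"] = False
    table.loc[best_rows.dropna(), "best_in_family"] = True
    table = table[list(EvidenceTable.COLUMNS)]
    return EvidenceTable(table, fits)
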