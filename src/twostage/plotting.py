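"""Small figure helpers for the stay analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_session_profile(profile: pd.DataFrame, ax=None):
    """Bar plot of the per-session stage-1 reward log-odds coefficient.

    Positive bars mean the subject repeats the rewarded stage-1 action;
    negative bars (early training) mean it repeats the action most proximal
    to the reward instead.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ok = profile[~profile["flagged"]]
    ax.bar(ok["session"], ok["reward_coef"],
           yerr=1.96 * ok["reward_se"], color="steelblue")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("session")
    ax.set_ylabel("reward log-odds on stage-1 stay")
    return ax


def plot_stay_probabilities(subset: pd.DataFrame, outcome: str = "stay1",
                            by: str = "transition_prev", ax=None):
    """Mean stay probability split by previous reward and a second factor
    (transition type for stage 1, stage-1 stay for stage 2)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    if by == "stay1":
        factor = subset["stay1"].map({1.0: "stay", 0.0: "switch"})
    else:
        factor = subset[by]
    tab = (
        subset.assign(_f=factor)
        .groupby(["reward_prev", "_f"])[outcome]
        .mean()
        .unstack("_f")
    )
    x = np.arange(len(tab.columns))
    width = 0.35
    for i, rew in enumerate(sorted(tab.index)):
        label = "reward" if rew == 1 else "no reward"
        ax.bar(x + (i - 0.5) * width, tab.loc[rew], width, label=label)
    ax.set_xticks(x, tab.columns)
    ax.set_ylabel(f"P({outcome})")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    return ax
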