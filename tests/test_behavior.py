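import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import twostage as ts
from twostage import behavior
from twostage.behavior import annotate, filter_stage1, filter_stage2, stay_regression


class TestAnnotate:
    def test_hand_walked_three_trial_toy(self, toy_trials):
        ann = annotate(toy_trials).set_index("trial")
        t1 = ann.loc[1]
        assert t1["stay1"] == 1
        assert t1["reward_prev"] == 1
        assert t1["same_s2_as_prev"] == 0
        assert t1["correct_disc_prev"] == 1
        assert t1["transition_prev"] == "common"
        assert ann.loc[2, "stay1"] == 0

    def test_first_trial_has_no_derived_fields(self, toy_trials):
        ann = annotate(toy_trials)
        first = ann.iloc[0]
        assert np.isnan(first["reward_prev"]) and np.isnan(first["stay1"])

    def test_lag_skips_aborted_trials(self, toy_trials):
        rows = toy_trials.to_dict("records")
        aborted = dict(rows[1], trial=1, a2=None, aborted=1, outcome=0)
        df = pd.DataFrame([rows[0], aborted, dict(rows[2], trial=2)])
        ann = annotate(df).set_index("trial")
        # trial 2's previous trial is trial 0 (the aborted trial is skipped)
        assert ann.loc[2, "reward_prev"] == 1
        assert ann.loc[2, "stay1"] == 0      # R vs L on trial 0
        assert np.isnan(ann.loc[1, "reward_prev"])  # aborted rows get no lags

    def test_session_boundary_breaks_lag_chain(self, toy_trials):
        df2 = toy_trials.copy()
        df2["session"] = [0, 1, 1]
        ann = annotate(df2)
        assert np.isnan(ann.iloc[1]["reward_prev"])
        assert not np.isnan(ann.iloc[2]["reward_prev"])

    def test_unordered_trials_rejected(self, toy_trials):
        df = toy_trials.iloc[[1, 0, 2]].reset_index(drop=True)
        with pytest.raises(ValueError):
            annotate(df)

    def test_correct_prev_uses_rewarding_column(self, toy_trials):
        df = toy_trials.assign(rewarding=["S2", "S2", "S1"])
        ann = annotate(df).set_index("trial")
        # trial 0: a1=L, common state S2 == rewarding S2 -> trial 1 correct_prev=1
        assert ann.loc[1, "correct_prev"] == 1
        # trial 1: a1=L common state S2 (rare to S1), rewarding S2 -> correct
        assert ann.loc[2, "correct_prev"] == 1
        assert np.isnan(annotate(toy_trials).iloc[1]["correct_prev"])


class TestFilters:
    def test_correct_discrimination_flag_contract(self, toy_trials):
        ann = annotate(toy_trials)
        # trial 2's predecessor (trial 1: a2=R in S1) was an incorrect discrimination
        strict = filter_stage1(ann, require_correct_disc=True)
        loose = filter_stage1(ann, require_correct_disc=False)
        assert 2 not in strict["trial"].values
        assert 2 in loose["trial"].values

    def test_all_correct_dataset_only_loses_first_of_session(self):
        rows = []
        for t in range(4):
            a1 = "LR"[t % 2]
            s2 = {"L": "S2", "R": "S1"}[a1]
            rows.append(dict(subject="r", session=0, phase="training", trial=t,
                             a1=a1, s2=s2, a2=ts.discriminative(s2),
                             outcome=t % 2, transition="common", aborted=0,
                             rt=np.nan))
        ann = annotate(pd.DataFrame(rows))
        assert len(filter_stage1(ann)) == 3

    def test_stage2_filter_requires_different_stage2_state(self, toy_trials):
        ann = annotate(toy_trials)
        sub = filter_stage2(ann, require_correct_disc=False)
        assert set(sub["trial"]) == {1}   # trial 2 has same_s2_as_prev == 1

    def test_deterministic_stay_session_gives_empty_stage2_subset(self):
        # staying on the same action under a deterministic contingency always
        # reproduces the same stage-2 state
        rows = [dict(subject="r", session=0, phase="training", trial=t,
                     a1="L", s2="S2", a2="R", outcome=1, transition="common",
                     aborted=0, rt=np.nan) for t in range(5)]
        sub = filter_stage2(annotate(pd.DataFrame(rows)))
        assert sub.empty

    def test_filters_idempotent_and_commute(self):
        df, _ = ts.probe_cohort("MB", n_subjects=2, n_trials=80, seed=3)
        ann = annotate(df)
        f1 = filter_stage1(ann)
        assert f1.equals(filter_stage1(f1))
        a = filter_stage2(ann)
        b = filter_stage1(ann)
        b = b.loc[b["same_s2_as_prev"] == 0]
        assert a.equals(b)

    def test_hmb_cohort_retains_between_half_and_all(self):
        df, _ = ts.probe_cohort("H-MB", n_subjects=4, n_trials=200, seed=3)
        ann = annotate(df)
        loose = filter_stage1(ann, require_correct_disc=False)
        strict = filter_stage1(ann, require_correct_disc=True)
        frac = len(strict) / len(loose)
        assert 0.5 < frac < 1.0


class TestStayRegression:
    def _null_data(self, seed, n=4000, k=8):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(dict(
            subject=np.repeat([f"s{i}" for i in range(k)], n // k),
            session=0,
            reward_prev=rng.integers(0, 2, n).astype(float),
            transition_prev=np.where(rng.integers(0, 2, n) == 1, "common", "rare"),
            stay1=rng.integers(0, 2, n).astype(float),
        ))

    def test_null_data_yields_small_nonsignificant_estimates(self):
        reg = stay_regression(
            self._null_data(0), "stay1",
            terms=("intercept", "reward", "transition", "reward:transition"),
        )
        t = reg.table.set_index("term")
        assert (t["estimate"].abs() < 0.25).all()
        assert (t.drop("intercept")["p"] > 0.05).all()

    def test_wald_interval_is_pm_196_se(self):
        reg = stay_regression(self._null_data(1), "stay1",
                              terms=("intercept", "reward"))
        t = reg.table
        assert np.allclose(t["ci_lo"], t["estimate"] - 1.96 * t["se"])
        assert np.allclose(t["ci_hi"], t["estimate"] + 1.96 * t["se"])

    def test_recovers_known_generating_coefficients(self):
        rng = np.random.default_rng(5)
        n, k = 8000, 8
        r = rng.integers(0, 2, n).astype(float)
        tr = rng.integers(0, 2, n).astype(float)
        eta = -0.2 + 0.6 * (r - 0.5) + 0.9 * (r - 0.5) * (tr - 0.5)
        y = (rng.random(n) < expit(eta)).astype(float)
        df = pd.DataFrame(dict(
            subject=np.repeat([f"s{i}" for i in range(k)], n // k), session=0,
            reward_prev=r, transition_prev=np.where(tr == 1, "common", "rare"),
            stay1=y))
        reg = stay_regression(df, "stay1",
                              terms=("intercept", "reward", "transition",
                                     "reward:transition"))
        t = reg.table.set_index("term")
        for term, truth in [("intercept", -0.2), ("reward", 0.6),
                            ("transition", 0.0), ("reward:transition", 0.9)]:
            assert t.loc[term, "ci_lo"] - 0.1 < truth < t.loc[term, "ci_hi"] + 0.1

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError):
            stay_regression(self._null_data(2), "stay1", terms=("intercept", "age"))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            stay_regression(self._null_data(2).iloc[:0], "stay1")

    def test_single_subject_flagged_inestimable(self):
        df = self._null_data(3, n=400, k=1)
        reg = stay_regression(df, "stay1", terms=("intercept", "reward"))
        assert not reg.converged
        assert any("fewer than 2" in f for f in reg.flags)

    def test_vb_engine_agrees_on_signs(self):
        rng = np.random.default_rng(6)
        n, k = 4000, 4
        r = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(1.0 * (r - 0.5))).astype(float)
        df = pd.DataFrame(dict(
            subject=np.repeat([f"s{i}" for i in range(k)], n // k), session=0,
            reward_prev=r, stay1=y))
        a = stay_regression(df, "stay1", terms=("intercept", "reward"))
        b = stay_regression(df, "stay1", terms=("intercept", "reward"), engine="vb")
        assert a["reward"]["estimate"] > 0
        assert b["reward"]["estimate"] > 0

    def test_csv_export_roundtrip(self, tmp_path):
        reg = stay_regression(self._null_data(4), "stay1",
                              terms=("intercept", "reward"))
        path = tmp_path / "reg.csv"
        reg.to_csv(path)
        back = pd.read_csv(path)
        assert list(back["term"]) == ["intercept", "reward"]
        assert {"estimate", "se", "ci_lo", "ci_hi", "p", "n", "converged"} <= set(back.columns)


class TestSessionStayProfile:
    def test_all_zero_rewards_session_is_flagged(self):
        rows = []
        for t in range(30):
            a1 = "LR"[t % 2]
            s2 = {"L": "S2", "R": "S1"}[a1]
            rows.append(dict(subject="r1", session=0, phase="training", trial=t,
                             a1=a1, s2=s2, a2=ts.discriminative(s2), outcome=0,
                             transition="common", aborted=0, rt=np.nan))
        prof = ts.session_stay_profile(pd.DataFrame(rows))
        assert prof["flagged"].all()

    def test_switch_regime_produces_sign_flip(self):
        cfg = ts.CohortConfig(
            n_subjects=6,
            schedule=(ts.cohort.PhaseSpec(6, ts.cohort.training_task()),),
            regime=ts.developmental_mixture(k_switch=3),
            seed=11,
        )
        df, _ = ts.generate_cohort(cfg)
        prof = ts.session_stay_profile(df).set_index("session")
        assert (prof.loc[:2, "reward_coef"] < 0).all()
        assert (prof.loc[3:, "reward_coef"] > 0).all()
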