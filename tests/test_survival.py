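"""Kaplan-Meier estimation, log-rank testing and maximally selected
rank-statistic cutpoint selection."""

import math

import numpy as np
import pandas as pd
import pytest

from teaccess.survival import (
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    two_group_logrank_z,
)


def records(times, events, samples=None, scores=None):
    df = pd.DataFrame({
        "sample": samples or [f"s{i}" for i in range(len(times))],
        "time": times,
        "event": events,
    })
    if scores is not None:
        df["score"] = scores
    return df


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        out = km_estimate(records([2, 5, 9], [0, 0, 0]))
        assert (out["all"]["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        out = km_estimate(records([1, 2, 3], [1, 1, 1]))["all"]
        by_time = dict(zip(out["time"], out["survival"]))
        assert by_time[1.0] == pytest.approx(2 / 3)
        assert by_time[2.0] == pytest.approx(1 / 3)
        assert by_time[3.0] == pytest.approx(0.0)

    def test_single_subject_event(self):
        out = km_estimate(records([5], [1]))["all"]
        assert out["survival"].iloc[-1] == pytest.approx(0.0)

    def test_monotone_within_unit_interval(self):
        rng = np.random.default_rng(1)
        out = km_estimate(records(rng.exponential(5, 50),
                                  rng.integers(0, 2, 50)))["all"]
        s = out["survival"].values
        assert ((s >= 0) & (s <= 1)).all() and (np.diff(s) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(5, 40), 3)
        out = km_estimate(records(t, np.ones(40, dtype=int)))["all"]
        for time, surv in zip(out["time"], out["survival"]):
            if time > 0:
                assert surv == pytest.approx(np.mean(t > time))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(records([0.0], [1]))


class TestLogrank:
    def test_identical_groups_null(self):
        df = records([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=df["sample"].values)
        chi2, dof, p = logrank_test(df, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 1 and p == pytest.approx(1.0)

    def test_hand_worked_six_subjects(self):
        # A events at 1,3,5; B events at 2,4,6; all observed
        df = records([1, 3, 5, 2, 4, 6], [1] * 6)
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=df["sample"].values)
        o_minus_e = 3 - (3 / 6 + 2 / 5 + 2 / 4 + 1 / 3 + 1 / 2)
        var = (
            (3 / 6) * (3 / 6)
            + (2 / 5) * (3 / 5)
            + (2 / 4) * (2 / 4)
            + (1 / 3) * (2 / 3)
            + (1 / 2) * (1 / 2)
        )
        chi2, _, _ = logrank_test(df, labels)
        assert chi2 == pytest.approx(o_minus_e**2 / var)
        z = two_group_logrank_z(df["time"].values, df["event"].values,
                                np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        assert z == pytest.approx(o_minus_e / math.sqrt(var))

    def test_two_group_z_squares_to_lifelines_chi2(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        grp = rng.integers(0, 2, 80).astype(bool)
        df = records(t, e)
        labels = pd.Series(np.where(grp, "hi", "lo"), index=df["sample"].values)
        chi2, _, _ = logrank_test(df, labels)
        z = two_group_logrank_z(t, e, grp)
        assert z**2 == pytest.approx(chi2, rel=1e-6)

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(4)
        t = np.concatenate([rng.exponential(1.0, 200),
                            rng.exponential(3.0, 200)])
        df = records(t, np.ones(400, dtype=int))
        labels = pd.Series(["fast"] * 200 + ["slow"] * 200,
                           index=df["sample"].values)
        _, _, p = logrank_test(df, labels)
        assert p < 0.001

    def test_time_unit_rescaling_invariant(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 60)
        e = rng.integers(0, 2, 60)
        grp = rng.integers(0, 2, 60).astype(bool)
        assert two_group_logrank_z(t, e, grp) == pytest.approx(
            two_group_logrank_z(t * 30.44, e, grp)
        )

    def test_single_group_rejected(self):
        df = records([1, 2], [1, 1])
        labels = pd.Series(["a", "a"], index=df["sample"].values)
        with pytest.raises(ValueError):
            logrank_test(df, labels)


class TestMaxstat:
    def planted_cohort(self, seed=5, n=300, quantile=0.4, log_hr=math.log(3)):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=n)
        thr = np.quantile(score, quantile)
        rate = 0.1 * np.exp(np.where(score > thr, -log_hr, 0.0))
        t = rng.exponential(1 / rate)
        c = rng.exponential(1 / 0.04, n)
        return records(np.minimum(t, c), (t <= c).astype(int),
                       scores=score), thr

    def test_recovers_planted_threshold(self):
        df, thr = self.planted_cohort()
        res = maxstat_cutpoint(df)
        pct = np.mean(df["score"] <= res.cutpoint)
        assert abs(pct - 0.4) <= 0.05

    def test_rank_invariance_under_monotone_transform(self):
        df, _ = self.planted_cohort(seed=6, n=120)
        r1 = maxstat_cutpoint(df)
        df2 = df.copy()
        df2["score"] = np.exp(df2["score"] / 2.0)
        r2 = maxstat_cutpoint(df2)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert (r1.n_high, r1.n_low) == (r2.n_high, r2.n_low)

    def test_equals_brute_force_split_search(self):
        df, _ = self.planted_cohort(seed=7, n=80)
        res = maxstat_cutpoint(df, q_low=0.1, q_high=0.9)
        score = df["score"].values
        lo, hi = np.quantile(score, [0.1, 0.9])
        best = 0.0
        for cut in np.unique(score[(score >= lo) & (score < hi)]):
            if cut >= score.max():
                continue
            z = two_group_logrank_z(df["time"].values, df["event"].values,
                                    score > cut)
            best = max(best, abs(z))
        assert res.statistic == pytest.approx(best)

    def test_identical_scores_rejected(self):
        df = records([1, 2, 3, 4], [1, 1, 1, 1], scores=[2.0] * 4)
        with pytest.raises(ValueError):
            maxstat_cutpoint(df)

    def test_naive_p_is_anticonservative_under_null(self):
        """The selected split's unadjusted log-rank p overstates
        significance when the score is independent of survival."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            n = 60
            t = rng.exponential(5, n)
            e = (rng.random(n) < 0.7).astype(int)
            df = records(t, e, scores=rng.normal(size=n))
            res = maxstat_cutpoint(df)
            hits += res.logrank_p < 0.05
        assert hits / n_rep > 0.05

    def test_permutation_p_better_calibrated(self):
        df, _ = self.planted_cohort(seed=8, n=60, log_hr=0.0)
        res = maxstat_cutpoint(df, n_permutations=200, seed=3)
        assert res.permutation_p >= res.logrank_p
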