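"""Signal quantification and the dual specificity tests (conserved-marker
rank-sum consensus and the empirical-Bayes moderated linear model)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from teaccess.intervals import GenomicInterval
from teaccess.te_discovery import (
    SignalMatrix,
    consensus_calls,
    conserved_marker_test,
    fit_variance_prior,
    log_transform,
    moderated_lm_test,
    quantify_signal,
    trigamma_inverse,
)


def track_from_runs(runs):
    arr = np.asarray(runs, dtype=float)
    return {"chr1": (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64),
                     arr[:, 2])}


class TestQuantifySignal:
    def test_partial_coverage_mean(self):
        tracks = {"s1": track_from_runs([(0, 5, 2.0)])}
        m = quantify_signal(tracks, [GenomicInterval("chr1", 0, 10, name="r")])
        assert m.values.loc["r", "s1"] == pytest.approx(1.0)

    def test_constant_track_identity(self):
        tracks = {"s1": track_from_runs([(0, 1000, 3.5)])}
        m = quantify_signal(tracks, [GenomicInterval("chr1", 37, 912, name="r")])
        assert m.values.loc["r", "s1"] == pytest.approx(3.5)

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(4)
        edges = np.sort(rng.choice(np.arange(1, 2000), 60, replace=False))
        edges = np.concatenate([[0], edges, [2000]])
        vals = rng.random(len(edges) - 1) * 5
        runs = [(s, e, v) for s, e, v in zip(edges[:-1], edges[1:], vals)]
        base = np.zeros(2000)
        for s, e, v in runs:
            base[s:e] = v
        tracks = {"s1": track_from_runs(runs)}
        region = GenomicInterval("chr1", 37, 912, name="r")
        m = quantify_signal(tracks, [region])
        assert m.values.loc["r", "s1"] == pytest.approx(base[37:912].mean())

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)


class TestLogTransform:
    def test_values(self):
        m = SignalMatrix(pd.DataFrame({"s1": [0.0, 1.0, 7.0]},
                                      index=["a", "b", "c"]),
                         pd.Series({"s1": "g"}))
        out = log_transform(m, 1.0)
        assert out.values["s1"].tolist() == pytest.approx([0.0, 1.0, 3.0])

    def test_negative_rejected(self):
        m = SignalMatrix(pd.DataFrame({"s1": [-1.0]}, index=["a"]),
                         pd.Series({"s1": "g"}))
        with pytest.raises(ValueError):
            log_transform(m)


def two_group_matrix(target, other, n_elements=1, element_noise=None):
    samples = [f"t{i}" for i in range(len(target))] + \
              [f"o{i}" for i in range(len(other))]
    groups = pd.Series(["liver"] * len(target) + ["lung"] * len(other),
                       index=samples)
    row = list(target) + list(other)
    values = pd.DataFrame([row] * n_elements, columns=samples,
                          index=[f"e{i}" for i in range(n_elements)])
    return SignalMatrix(values, groups)


class TestConservedMarker:
    def test_exact_small_sample_p(self):
        m = two_group_matrix([3, 4], [1, 2])
        out = conserved_marker_test(m, "liver", alpha=0.5, min_log2fc=0)
        assert out["cm_p"].iloc[0] == pytest.approx(1 / 6)

    def test_huge_effect_flagged_at_published_defaults(self):
        rng = np.random.default_rng(0)
        samples = {}
        groups = {}
        for g in ["liver", "lung", "brain"]:
            for i in range(8):
                sid = f"{g}{i}"
                groups[sid] = g
        values = {}
        for sid, g in groups.items():
            col = rng.random(30)  # background ~ U(0,1)
            if g == "liver":
                col = col + 2**12
            values[sid] = col
        m = SignalMatrix(pd.DataFrame(values, index=[f"e{i}" for i in range(30)]),
                         pd.Series(groups))
        # with 30 elements all shifted, BH leaves the exact floor intact
        out = conserved_marker_test(m, "liver", alpha=1e-3, min_log2fc=10)
        assert out["cm_log2fc"].min() > 10
        assert out["pass_cm"].all()

    def test_combined_p_is_max_over_groups(self):
        rng = np.random.default_rng(1)
        groups = pd.Series(
            ["liver"] * 4 + ["lung"] * 4 + ["brain"] * 4,
            index=[f"s{i}" for i in range(12)],
        )
        row = np.concatenate([rng.normal(5, 1, 4), rng.normal(0, 1, 4),
                              rng.normal(4, 1, 4)])
        m = SignalMatrix(pd.DataFrame([row], columns=groups.index, index=["e"]),
                         groups)
        out = conserved_marker_test(m, "liver", alpha=0.5, min_log2fc=0)
        from teaccess.stats import rank_sum_test

        p_lung = rank_sum_test(row[:4], row[4:8], "greater")[1]
        p_brain = rank_sum_test(row[:4], row[8:], "greater")[1]
        assert out["cm_p"].iloc[0] == pytest.approx(max(p_lung, p_brain))

    def test_missing_target_group_rejected(self):
        m = two_group_matrix([1, 2], [3, 4])
        with pytest.raises(ValueError):
            conserved_marker_test(m, "kidney")

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        n_el = 1000
        samples = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
        groups = pd.Series(["liver"] * 8 + ["lung"] * 8, index=samples)
        values = pd.DataFrame(rng.normal(size=(n_el, 16)), columns=samples,
                              index=[f"e{i}" for i in range(n_el)])
        out = conserved_marker_test(SignalMatrix(values, groups), "liver",
                                    alpha=0.05, min_log2fc=0)
        frac = float((out["cm_p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestModeratedModel:
    def make_matrix(self, seed=0, n_el=200, shift=0.0):
        rng = np.random.default_rng(seed)
        samples = [f"t{i}" for i in range(6)] + [f"o{i}" for i in range(10)]
        groups = pd.Series(["liver"] * 6 + ["lung"] * 10, index=samples)
        x = rng.normal(size=(n_el, 16))
        x[:, :6] += shift
        values = pd.DataFrame(x, columns=samples,
                              index=[f"e{i}" for i in range(n_el)])
        return SignalMatrix(values, groups)

    def test_zero_prior_df_recovers_ordinary_t(self):
        m = self.make_matrix(seed=2)
        out = moderated_lm_test(m, "liver", prior_df_override=0.0)
        x = m.values.values[:, :6]
        y = m.values.values[:, 6:]
        t_ref, p_ref = sps.ttest_ind(x, y, axis=1, equal_var=True)
        assert out["lm_t"].values == pytest.approx(t_ref, rel=1e-9)
        assert out["lm_p"].values == pytest.approx(p_ref, rel=1e-9)

    def test_infinite_prior_df_fixes_posterior_variance(self):
        m = self.make_matrix(seed=3)
        out = moderated_lm_test(m, "liver", prior_df_override=np.inf,
                                prior_var_override=2.0)
        beta = out["lm_logfc"].values
        c_beta = 1 / 6 + 1 / 10
        assert out["lm_t"].values == pytest.approx(
            beta / np.sqrt(2.0 * c_beta), rel=1e-9
        )

    def test_prior_hyperparameter_recovery(self):
        rng = np.random.default_rng(3)
        d0, s02, d = 4.0, 2.0, 10
        sigma2 = s02 * d0 / rng.chisquare(d0, size=2000)
        s2 = sigma2 * rng.chisquare(d, size=2000) / d
        d0_hat, s02_hat = fit_variance_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s02_hat - s02) / s02 < 0.15

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in [0.05, 0.5, 2.0, 25.0]:
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_strong_shift_passes_thresholds(self):
        m = self.make_matrix(seed=4, shift=4.0)
        out = moderated_lm_test(m, "liver", alpha=1e-4, min_logfc=2, min_B=3)
        assert out["pass_lm"].mean() > 0.95

    def test_degenerate_variance_ensemble_rejected(self):
        samples = [f"t{i}" for i in range(3)] + [f"o{i}" for i in range(3)]
        groups = pd.Series(["liver"] * 3 + ["lung"] * 3, index=samples)
        values = pd.DataFrame(np.ones((5, 6)), columns=samples,
                              index=[f"e{i}" for i in range(5)])
        with pytest.raises(ValueError):
            moderated_lm_test(SignalMatrix(values, groups), "liver")


class TestConsensus:
    def frame(self, idx, flag, prefix):
        df = pd.DataFrame(index=idx)
        df[f"pass_{prefix}"] = flag
        df[f"{prefix}_q"] = np.linspace(0.001, 0.01, len(idx))
        return df

    def test_requires_both_tests(self):
        cm = self.frame(["a", "b"], [True, True], "cm")
        lm = self.frame(["a", "b"], [True, False], "lm")
        out = consensus_calls(cm, lm)
        assert out["pass_consensus"].tolist() == [True, False]

    def test_mismatched_universes_rejected(self):
        cm = self.frame(["a"], [True], "cm")
        lm = self.frame(["b"], [True], "lm")
        with pytest.raises(ValueError):
            consensus_calls(cm, lm)

    def test_empty_inputs(self):
        cm = self.frame([], [], "cm")
        lm = self.frame([], [], "lm")
        assert consensus_calls(cm, lm).empty
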