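"""Lesion SUV quantitation and the repeatability/statistics battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petac.lesionstats import (
    RC_FACTOR,
    RepeatabilityResult,
    clustered_wilcoxon,
    covariate_model,
    icc_agreement,
    lesion_suv,
    lesion_table,
    rc_from_stdev,
    relative_diff,
    repeatability,
)
from petac.volume import PETVolume


class TestLesionSuv:
    def test_constant_lesion(self):
        vol = np.full((1, 4, 4), 7.0)
        mask = np.zeros((1, 4, 4), bool)
        mask[0, 1:3, 1:3] = True
        assert lesion_suv(vol, mask) == (7.0, 7.0)

    def test_max_and_mean_arithmetic(self):
        vol = np.zeros((1, 1, 3))
        vol[0, 0] = [2.0, 4.0, 9.0]
        mask = np.ones((1, 1, 3), bool)
        assert lesion_suv(vol, mask) == (9.0, 5.0)

    def test_single_voxel_max_equals_mean(self, rng):
        vol = PETVolume(rng.uniform(1, 9, (2, 5, 5)))
        mask = np.zeros(vol.shape, bool)
        mask[1, 2, 3] = True
        mx, mn = lesion_suv(vol, mask)
        assert mx == mn

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lesion_suv(np.ones((1, 2, 2)), np.zeros((1, 2, 2), bool))


class TestRelativeDiff:
    @pytest.mark.parametrize("ac,gen,expected", [
        (10.0, 8.0, 20.0), (5.0, 5.0, 0.0), (10.0, 12.0, -20.0),
    ])
    def test_sign_convention(self, ac, gen, expected):
        assert relative_diff(ac, gen) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_diff(0.0, 1.0)


def simulate_records(rng, n_patients=20, lesions_per=4, bias=10.0, sd=8.0,
                     method="v1"):
    rows = []
    for p in range(n_patients):
        for l in range(lesions_per):
            ac = rng.uniform(3, 30)
            rd = bias + rng.normal(0, sd)
            rows.append({
                "patient_id": f"p{p}", "lesion_id": f"p{p}l{l}",
                "method": method,
                "suv_max_ac": ac * 1.4, "suv_mean_ac": ac,
                "suv_max_gen": ac * 1.4 * (1 - rd / 100),
                "suv_mean_gen": ac * (1 - rd / 100),
                "hu_mean": rng.normal(20, 100), "hu_max": rng.normal(300, 150),
                "volume": rng.uniform(0.5, 8), "location": "lymph_node",
                "psma_rads": 4,
            })
    return pd.DataFrame(rows)


class TestRepeatability:
    def test_rc_is_fixed_multiple_of_stdev(self, rng):
        df = simulate_records(rng)
        r = repeatability(df, "v1", "suv_mean")
        assert r.rc / r.stdev == pytest.approx(RC_FACTOR)
        assert r.bias == pytest.approx(10.0, abs=3.0)
        assert r.stdev == pytest.approx(8.0, abs=3.0)

    def test_identical_diffs_zero_spread(self):
        rows = []
        for p in range(3):
            for l in range(2):
                rows.append({"patient_id": f"p{p}", "lesion_id": f"{p}{l}",
                             "method": "v1",
                             "suv_mean_ac": 10.0 + p + l, "suv_max_ac": 12.0,
                             "suv_mean_gen": (10.0 + p + l) * 0.9,
                             "suv_max_gen": 11.0})
        r = repeatability(pd.DataFrame(rows), "v1", "suv_mean")
        assert r.stdev == pytest.approx(0.0, abs=1e-12)
        assert r.rc == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_patients(self, rng):
        df = simulate_records(rng, n_patients=1)
        with pytest.raises(ValueError, match="2 patients"):
            repeatability(df, "v1")

    def test_result_invariant_enforced(self):
        with pytest.raises(ValueError, match="1.96"):
            RepeatabilityResult(bias=0.0, stdev=10.0, rc=10.0, icc=0.5)


class TestIcc:
    def simulate_paired(self, rng, n, icc_true, total_var=25.0):
        var_b = icc_true * total_var
        var_w = total_var - var_b
        truth = 10.0 + rng.normal(0, np.sqrt(var_b), n)
        x = truth + rng.normal(0, np.sqrt(var_w), n)
        y = truth + rng.normal(0, np.sqrt(var_w), n)
        return x, y

    @pytest.mark.parametrize("icc_true", [0.5, 0.9])
    def test_recovers_known_variance_components(self, icc_true):
        rng = np.random.default_rng(777)
        # 50 patients x 5 lesions worth of paired values
        x, y = self.simulate_paired(rng, 250, icc_true)
        assert icc_agreement(x, y) == pytest.approx(icc_true, abs=0.05)

    def test_perfect_agreement_reaches_one(self, rng):
        x = rng.normal(10, 5, 100)
        assert icc_agreement(x, x.copy()) == pytest.approx(1.0)

    def test_matches_pingouin_icc2(self, rng):
        import pingouin as pg

        x, y = self.simulate_paired(rng, 60, 0.7)
        df = pd.DataFrame({
            "target": np.repeat(np.arange(60), 2),
            "rater": ["ac", "gen"] * 60,
            "value": np.column_stack([x, y]).ravel(),
        })
        ref = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="value")
        # single-rater absolute agreement: labelled ICC2 (Shrout-Fleiss)
        # or ICC(A,1) (McGraw-Wong) depending on the pingouin version
        row = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[row, "ICC"].iloc[0]
        assert icc_agreement(x, y) == pytest.approx(icc2, abs=1e-9)


class TestClusteredWilcoxon:
    def test_single_lesion_per_patient_matches_plain_wilcoxon(self, rng):
        d = rng.normal(0.4, 1.0, 12)
        clusters = np.arange(12)
        ours = clustered_wilcoxon(d, clusters)
        ref = stats.wilcoxon(d, method="exact", alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_all_zero_differences(self):
        assert clustered_wilcoxon(np.zeros(6), np.repeat([0, 1, 2], 2)) == 1.0

    def test_three_cluster_toy_matches_permutation_oracle(self, rng):
        d = rng.normal(0.5, 1.0, 9)
        clusters = np.repeat([0, 1, 2], 3)
        ours = clustered_wilcoxon(d, clusters)
        # independent oracle: Monte-Carlo sign flips of whole clusters
        ranks = stats.rankdata(np.abs(d))
        signed = np.sign(d) * ranks
        s = np.array([signed[clusters == c].sum() for c in range(3)])
        t_obs = abs(s.sum())
        flips = rng.choice([-1.0, 1.0], size=(100_000, 3))
        t_null = np.abs(flips @ s)
        p_mc = float(np.mean(t_null >= t_obs - 1e-9))
        assert ours == pytest.approx(p_mc, abs=0.01)

    def test_normal_approximation_for_many_clusters(self, rng):
        d = rng.normal(0.8, 1.0, 60)
        clusters = np.repeat(np.arange(20), 3)
        p = clustered_wilcoxon(d, clusters, exact_limit=5)
        assert 0.0 < p < 0.05  # strong signal should be detected


class TestCovariateModel:
    def test_recovers_planted_slope(self):
        rng = np.random.default_rng(99)
        df = simulate_records(rng, n_patients=50, lesions_per=4, bias=0.0, sd=4.0)
        # plant rel_diff = -0.6 * suv_mean_ac + patient effect + noise
        patient_fx = {f"p{p}": rng.normal(0, 3) for p in range(50)}
        planted = (-0.6 * df["suv_mean_ac"]
                   + df["patient_id"].map(patient_fx)
                   + rng.normal(0, 4, len(df)))
        df["suv_mean_gen"] = df["suv_mean_ac"] * (1 - planted / 100)
        res = covariate_model(df, "v1", "suv_mean", ["suv_ac"])
        row = res.table.iloc[0]
        assert abs(row["beta"] - (-0.6)) < 2 * row["std_error"]
        assert res.comparison_p < 0.01

    def test_null_comparison_p_is_calibrated(self):
        # response independent of the covariate: the likelihood-ratio
        # p-value should be uniform; KS test at alpha = 0.01
        rng = np.random.default_rng(4242)
        pvals = []
        for _ in range(120):
            df = simulate_records(rng, n_patients=25, lesions_per=4,
                                  bias=5.0, sd=6.0)
            res = covariate_model(df, "v1", "suv_mean", ["hu_mean"])
            pvals.append(res.comparison_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_shift_moves_intercept_only(self):
        rng = np.random.default_rng(7)
        df = simulate_records(rng, n_patients=30, lesions_per=3)
        res1 = covariate_model(df, "v1", "suv_mean", ["hu_mean"])
        df2 = df.copy()
        # shift every relative difference by a constant: scale gen values
        rd = 100 * (df2["suv_mean_ac"] - df2["suv_mean_gen"]) / df2["suv_mean_ac"]
        df2["suv_mean_gen"] = df2["suv_mean_ac"] * (1 - (rd + 15.0) / 100)
        res2 = covariate_model(df2, "v1", "suv_mean", ["hu_mean"])
        assert res2.table.iloc[0]["beta"] == pytest.approx(
            res1.table.iloc[0]["beta"], abs=1e-6
        )

    def test_single_level_categorical_named(self, rng):
        df = simulate_records(rng)
        with pytest.raises(ValueError, match="location"):
            covariate_model(df, "v1", "suv_mean", ["location"])


class TestLesionTable:
    def test_counts_by_location(self, rng):
        df = simulate_records(rng, n_patients=2, lesions_per=2)
        df.loc[df.index[:1], "location"] = "bone"
        out = lesion_table(df)
        loc = out[out["variable"] == "location"].set_index("level")["value"]
        assert loc["bone"] == 1 and loc["lymph_node"] == 3

    def test_lesions_per_patient_median(self, rng):
        df = simulate_records(rng, n_patients=1, lesions_per=5)
        out = lesion_table(df)
        row = out[out["variable"] == "n_lesions_per_patient"]["value"].iloc[0]
        assert row.startswith("5")

    def test_empty_input_no_crash(self):
        out = lesion_table(pd.DataFrame())
        assert len(out) == 0


class TestRcArithmetic:
    def test_rc_factor_value(self):
        assert RC_FACTOR == pytest.approx(2.7719, abs=1e-4)

    @pytest.mark.parametrize("stdev,rc", [
        (22.02, 61.04), (23.20, 64.31), (24.02, 66.58), (26.84, 74.40),
    ])
    def test_published_stdev_rc_pairs(self, stdev, rc):
        # the four repeatability rows of the reference clinical analysis
        assert rc_from_stdev(stdev) == pytest.approx(rc, abs=0.01)
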