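"""Covariate adjustment, pooled t-tests, and Bonferroni control."""

import numpy as np
import pandas as pd
import pytest

from brainstates import bonferroni, regress_out, run_group_analysis, two_sample_t
from brainstates.temporal import cohort_metrics


def textbook_pooled_t(x, y):
    """Hand formula: t = (mean_x - mean_y) / sqrt(s_p^2 (1/n + 1/m))."""
    n, m = len(x), len(y)
    sp2 = ((n - 1) * np.var(x, ddof=1) + (m - 1) * np.var(y, ddof=1)) / (n + m - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / n + 1 / m))


def _table(n, rng=None, site_levels=2):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "age": rng.uniform(8, 30, n),
        "fiq": rng.normal(100, 15, n),
        "site": [f"site{i % site_levels:02d}" for i in range(n)],
    })


class TestRegressOut:
    def test_perfectly_linear_in_age_leaves_zero_residuals(self):
        tab = _table(30)
        values = 2.0 + 0.5 * tab["age"].to_numpy()
        res = regress_out(values, tab, ["age"])
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_empty_covariate_set_centers(self, rng):
        tab = _table(20)
        values = rng.normal(5, 2, 20)
        res = regress_out(values, tab, [])
        np.testing.assert_allclose(res, values - values.mean(), atol=1e-10)

    def test_uncorrelated_covariate_changes_little(self):
        rng = np.random.default_rng(1)
        n = 10_000
        tab = _table(n, rng)
        values = rng.normal(size=n)
        res = regress_out(values, tab, ["age"])
        centered = values - values.mean()
        assert np.corrcoef(res, centered)[0, 1] > 0.999

    def test_residuals_orthogonal_to_covariates(self, rng):
        tab = _table(50, rng)
        values = rng.normal(size=50) + 0.3 * tab["age"].to_numpy()
        res = regress_out(values, tab, ["age", "site", "fiq"])
        assert abs(res @ tab["age"].to_numpy()) < 1e-7
        assert abs(res @ tab["fiq"].to_numpy()) < 1e-7

    def test_rank_deficient_design_names_columns(self, rng):
        tab = _table(20, rng)
        tab["fiq"] = 2.0 * tab["age"] + 1.0
        with pytest.raises(ValueError, match="collinear.*fiq"):
            regress_out(rng.normal(size=20), tab, ["age", "fiq"])


class TestTwoSampleT:
    def test_identical_groups_give_null_result(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["case"] * 3 + ["control"] * 3)
        t, p, df = two_sample_t(v, g, "case", "control")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_textbook_example(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array(["case"] * 3 + ["control"] * 3)
        t, p, df = two_sample_t(v, g, "case", "control")
        assert df == 4
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert t == pytest.approx(textbook_pooled_t(v[:3], v[3:]), abs=1e-12)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_zero_variance_with_unequal_means_rejected(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        g = np.array(["case", "case", "control", "control"])
        with pytest.raises(ValueError, match="zero pooled variance"):
            two_sample_t(v, g, "case", "control")

    def test_sign_convention_is_case_minus_control(self, rng):
        v = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        g = np.array(["case"] * 20 + ["control"] * 20)
        t, _, _ = two_sample_t(v, g, "case", "control")
        assert t > 0

    def test_null_type_one_rate(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 2000
        g = np.array(["case"] * 30 + ["control"] * 30)
        for _ in range(reps):
            v = rng.standard_normal(60)
            _, p, _ = two_sample_t(v, g, "case", "control")
            rejections += p < 0.05
        assert 0.035 < rejections / reps < 0.065


class TestBonferroni:
    def test_single_test_uses_raw_alpha(self):
        assert bonferroni([0.04]).tolist() == [True]

    def test_nineteen_tests_threshold(self):
        p = [0.0027] + [0.5] * 18
        assert bonferroni(p).tolist() == [False] + [False] * 18
        p = [0.0026] + [0.5] * 18
        assert bonferroni(p)[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bonferroni([])


class TestGroupAnalysis:
    def _cohort_metrics(self, rng, effect=0.0, n=20, k=3):
        rows = []
        manifest = []
        for g, off in (("case", effect), ("control", 0.0)):
            for i in range(n):
                sid = f"{g}{i}"
                manifest.append({"subject_id": sid, "group": g,
                                 "site": f"site{i % 2}", "age": rng.uniform(8, 30),
                                 "fiq": rng.normal(100, 15), "mean_fd": 0.1,
                                 "path": "x"})
                base = rng.normal(1.0 / k, 0.05, k)
                base[1] += off
                for s in range(k):
                    rows.append({"subject_id": sid, "group": g, "state": s,
                                 "fractional_occupancy": base[s],
                                 "mean_lifetime": rng.normal(5, 1),
                                 "n_visits": 10,
                                 "mean_interval": rng.normal(10, 2)})
        return pd.DataFrame(rows), pd.DataFrame(manifest)

    def test_copied_relabeled_groups_nothing_significant(self, small_cohort):
        """Duplicating every subject into both groups nulls every contrast."""
        _, _, cohort = small_cohort
        metrics = cohort_metrics(cohort.true_paths, 3, manifest=cohort.manifest)
        copies, manifests = [], []
        for tag, group in (("a", "case"), ("b", "control")):
            m = metrics.copy()
            m["subject_id"] = tag + m["subject_id"]
            copies.append(m)
            man = cohort.manifest.copy()
            man["subject_id"] = tag + man["subject_id"]
            man["group"] = group
            manifests.append(man)
        res = run_group_analysis(pd.concat(copies, ignore_index=True),
                                 pd.concat(manifests, ignore_index=True))
        assert not res["significant"].any()
        fo = res[res["metric"] == "fractional_occupancy"]
        np.testing.assert_allclose(fo["t"], 0.0, atol=1e-8)

    def test_planted_effect_detected_and_sign_correct(self):
        detected, null_flags = 0, 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            metrics, manifest = self._cohort_metrics(rng, effect=0.08, n=30)
            res = run_group_analysis(metrics, manifest, covariate_sets=[["age"]])
            fo = res[res["metric"] == "fractional_occupancy"].set_index("state")
            detected += bool(fo.loc[1, "significant"] and fo.loc[1, "t"] > 0)
            null_flags += int(fo.drop(index=1)["significant"].sum())
        assert detected == 5
        assert null_flags <= 2  # Bonferroni keeps false positives rare

    def test_both_covariate_sets_emitted(self):
        rng = np.random.default_rng(5)
        metrics, manifest = self._cohort_metrics(rng)
        res = run_group_analysis(metrics, manifest)
        assert set(res["covariate_set"]) == {"age", "age+site+fiq"}
        assert len(res) == 2 * 3 * 3  # sets x metrics x states

    def test_affine_covariate_rescaling_leaves_t_unchanged(self):
        rng = np.random.default_rng(6)
        metrics, manifest = self._cohort_metrics(rng, effect=0.05)
        res1 = run_group_analysis(metrics, manifest, covariate_sets=[["age"]])
        manifest2 = manifest.copy()
        manifest2["age"] = manifest2["age"] * 12.0 + 7.0
        res2 = run_group_analysis(metrics, manifest2, covariate_sets=[["age"]])
        np.testing.assert_allclose(res1["t"], res2["t"], atol=1e-8)

    def test_no_covariates_equals_plain_pooled_t(self):
        rng = np.random.default_rng(7)
        metrics, manifest = self._cohort_metrics(rng, effect=0.05)
        res = run_group_analysis(metrics, manifest, covariate_sets=[[]])
        fo = res[res["metric"] == "fractional_occupancy"].set_index("state")
        sub = metrics[metrics["state"] == 1]
        case = sub[sub["group"] == "case"]["fractional_occupancy"].to_numpy()
        ctrl = sub[sub["group"] == "control"]["fractional_occupancy"].to_numpy()
        assert fo.loc[1, "t"] == pytest.approx(textbook_pooled_t(case, ctrl), abs=1e-10)
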