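"""Group-statistics tests: cluster permutation, Mantel, regressions."""

import numpy as np
import pandas as pd
import pytest

from sleepprint.containers import DataError
from sleepprint.groupstats import (
    age_groups,
    artifact_age_regression,
    auc_age_regression,
    cluster_permutation_test,
    differentiability_regression,
    emg_noise_covariate,
    mantel_test,
)

FREQS = np.arange(171) * 0.244140625 + 1.0


def _cohort(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": rng.uniform(0.1, 19.0, n),
            "sex": rng.choice(["F", "M"], n),
            "cap": rng.choice(["small", "FT"], n),
            "emg_rms_N2a": rng.lognormal(0.0, 0.3, n),
            "emg_rms_N2b": rng.lognormal(0.0, 0.3, n),
        }
    )


class TestClusterPermutation:
    def test_identical_segments_yield_no_clusters(self):
        one = np.random.default_rng(0).random((10, 171)) + 1.0
        data = np.stack([np.stack([s, s.copy(), s.copy()]) for s in one])
        res = cluster_permutation_test(data, FREQS, n_perm=100, seed=0)
        assert res.clusters == []

    def test_injected_spindle_shift_recovered(self, rng):
        data = rng.standard_normal((30, 4, 171)) * 0.3 + 10.0
        shift = np.where((FREQS >= 12) & (FREQS <= 15), 1.0, 0.0)
        data[:, 2:, :] += shift
        res = cluster_permutation_test(data, FREQS, n_perm=500, seed=1)
        best = min(res.clusters, key=lambda c: c["p"])
        lo, hi = best["freqs_hz"]
        assert lo <= 15.0 and hi >= 12.0  # overlaps the spindle band
        assert best["p"] < 0.01

    def test_type_i_error_calibrated_small(self, rng):
        hits = 0
        reps = 60
        for rep in range(reps):
            data = rng.standard_normal((20, 4, 80)) + 5.0
            res = cluster_permutation_test(data, FREQS[:80], n_perm=200, seed=rep)
            hits += res.min_p() < 0.01
        se = np.sqrt(0.01 * 0.99 / reps)
        assert hits / reps <= 0.01 + 3 * se

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation_test(np.zeros((5, 1, 10)), FREQS[:10])


class TestMantel:
    def test_identical_matrices(self, rng):
        d = rng.random((12, 12))
        r, p = mantel_test(d, d.copy(), n_perm=999, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_affine_invariance(self, rng):
        d = rng.random((10, 10))
        r, _ = mantel_test(d, 2.0 * d + 3.0, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mantel_test(np.ones((5, 5)), np.ones((5, 5)))

    def test_matches_skbio_oracle(self, rng):
        """Observed statistic agrees exactly with scikit-bio's Mantel; the
        permutation p-values agree within Monte-Carlo error."""
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        a = rng.random((15, 15))
        a = 0.5 * (a + a.T)
        np.fill_diagonal(a, 0.0)
        b = a + 0.3 * rng.random((15, 15))
        b = 0.5 * (b + b.T)
        np.fill_diagonal(b, 0.0)
        r, p = mantel_test(a, b, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=999, alternative="greater",
        )
        assert r == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(p - float(p_sk)) < 0.05

    def test_reproducible_given_seed(self, rng):
        a, b = rng.random((10, 10)), rng.random((10, 10))
        assert mantel_test(a, b, seed=7) == mantel_test(a, b, seed=7)


class TestEmgCovariate:
    def test_equal_rms_gives_zero(self):
        cohort = _cohort(4)
        cohort["emg_rms_N2b"] = cohort["emg_rms_N2a"]
        cov = emg_noise_covariate(cohort, "N2a", "N2b")
        np.testing.assert_allclose(cov.values, 0.0, atol=1e-12)

    def test_e_fold_ratio_gives_one(self):
        cohort = _cohort(4)
        cohort["emg_rms_N2b"] = np.e * cohort["emg_rms_N2a"]
        cov = emg_noise_covariate(cohort, "N2a", "N2b")
        np.testing.assert_allclose(cov.values, 1.0, atol=1e-12)

    def test_matches_loop_oracle(self):
        cohort = _cohort(20, seed=5)
        cov = emg_noise_covariate(cohort, "N2a", "N2b")
        for _, row in cohort.iterrows():
            expected = abs(np.log(row["emg_rms_N2a"]) - np.log(row["emg_rms_N2b"]))
            assert cov.values[row["subject_id"]] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rms_named(self):
        cohort = _cohort(3)
        cohort.loc[1, "emg_rms_N2a"] = 0.0
        with pytest.raises(DataError, match="S001"):
            emg_noise_covariate(cohort, "N2a", "N2b")


class TestDifferentiabilityRegression:
    def test_constant_scores_land_in_intercept(self):
        cohort = _cohort(40, seed=2)
        noise = emg_noise_covariate(cohort, "N2a", "N2b")
        scores = pd.Series(2.5, index=cohort["subject_id"])
        res = differentiability_regression(scores, cohort, noise)
        assert res.coefficients.loc["Intercept", "estimate"] == pytest.approx(2.5, abs=1e-10)
        others = res.coefficients.drop("Intercept")["estimate"]
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_recovers_age_effect(self):
        cohort = _cohort(500, seed=3)
        noise = emg_noise_covariate(cohort, "N2a", "N2b")
        rng = np.random.default_rng(1)
        scores = pd.Series(
            2.0 + 0.1 * cohort["age"].to_numpy() + rng.normal(0, 0.5, len(cohort)),
            index=cohort["subject_id"],
        )
        res = differentiability_regression(scores, cohort, noise)
        row = res.coefficients.loc["age"]
        assert row["ci_low"] < 0.1 < row["ci_high"]

    def test_matches_normal_equations_oracle(self):
        cohort = _cohort(60, seed=4)
        noise = emg_noise_covariate(cohort, "N2a", "N2b")
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(1.0, 0.8, len(cohort)), index=cohort["subject_id"])
        res = differentiability_regression(scores, cohort, noise)
        male = (cohort["sex"] == "M").to_numpy(float)
        ft = (cohort["cap"] == "FT").to_numpy(float)
        nz = noise.values.to_numpy()
        design = np.column_stack(
            [np.ones(len(cohort)), nz, male, cohort["age"], ft, nz * male]
        )
        beta = np.linalg.solve(design.T @ design, design.T @ scores.to_numpy())
        got = res.coefficients["estimate"]
        expected = dict(
            zip(["Intercept", "noise", "sex[M]", "age", "cap[FT]", "noise:sex[M]"], beta)
        )
        for term, val in expected.items():
            assert got[term] == pytest.approx(val, abs=1e-8)

    def test_single_sex_cohort_detected_as_aliased(self):
        cohort = _cohort(30, seed=5)
        cohort["sex"] = "F"
        noise = emg_noise_covariate(cohort, "N2a", "N2b")
        scores = pd.Series(1.0 + 0 * cohort["age"].to_numpy(), index=cohort["subject_id"])
        with pytest.raises(ValueError, match="aliased"):
            differentiability_regression(scores, cohort, noise)


class TestAucAgeRegression:
    def test_exact_cubic_recovered(self):
        age = np.linspace(0.5, 19.0, 40)
        auc = 2.0 + 3.0 * age - 0.5 * age**2 + 0.01 * age**3
        res = auc_age_regression(auc, age)
        got = res.coefficients["estimate"]
        assert got["Intercept"] == pytest.approx(2.0, abs=1e-8)
        assert got["age"] == pytest.approx(3.0, abs=1e-8)
        assert got["I(age ** 2)"] == pytest.approx(-0.5, abs=1e-8)
        assert got["I(age ** 3)"] == pytest.approx(0.01, abs=1e-8)

    def test_inverted_u_gives_negative_quadratic(self, rng):
        age = rng.uniform(0.1, 19.0, 300)
        auc = 50 + 30 * age - 2.0 * age**2 + rng.normal(0, 5, 300)
        res = auc_age_regression(auc, age)
        row = res.coefficients.loc["I(age ** 2)"]
        assert row["estimate"] < 0 and row["ci_high"] < 0

    def test_constant_auc_gives_zero_terms(self):
        age = np.linspace(1, 10, 30)
        res = auc_age_regression(np.full(30, 7.0), age)
        np.testing.assert_allclose(
            res.coefficients.drop("Intercept")["estimate"], 0.0, atol=1e-8
        )

    def test_degenerate_age_rejected(self):
        with pytest.raises(ValueError):
            auc_age_regression(np.arange(10.0), np.ones(10))


class TestArtifactAgeRegression:
    def test_two_points_exact_line(self):
        noise = emg_noise_covariate(
            pd.DataFrame(
                {
                    "subject_id": ["a", "b"],
                    "emg_rms_N2a": [1.0, 1.0],
                    "emg_rms_N2b": [np.e, np.e**2],
                }
            ),
            "N2a",
            "N2b",
        )
        res = artifact_age_regression(noise, np.array([1.0, 2.0]))
        assert res.fit_stats["r_squared"] == pytest.approx(1.0)
        assert res.coefficients.loc["age", "estimate"] == pytest.approx(1.0, abs=1e-10)

    def test_negative_slope_recovered_at_scale(self, rng):
        n = 700
        cohort = _cohort(n, seed=8)
        age = cohort["age"].to_numpy()
        vals = np.maximum(-0.005 * age + rng.normal(0.05, 0.01, n), 1e-4)
        noise = emg_noise_covariate(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "emg_rms_N2a": np.exp(vals),
                    "emg_rms_N2b": np.ones(n),
                }
            ),
            "N2a",
            "N2b",
        )
        res = artifact_age_regression(noise, age)
        row = res.coefficients.loc["age"]
        assert row["estimate"] < 0 and row["ci_high"] < 0


class TestAgeGroups:
    def test_equal_group_sizes(self):
        ages = pd.Series(np.random.default_rng(0).uniform(0, 19, 100))
        groups = age_groups(ages, 10)
        assert sorted(groups.value_counts()) == [10] * 10
        # groups ordered by age
        assert ages[groups == 0].max() <= ages[groups == 9].min()
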