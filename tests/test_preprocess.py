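"""Imputation, deconfounding, standardization, classification, matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from morphlink import (
    SyntheticCohortSpec,
    classify_mets,
    gen_cohort,
    group_difference_map,
    harmonize_across_cohorts,
    impute_knn,
    match_cases_controls,
    residualize_confounds,
    zscore_columns,
)


class TestImputeKnn:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                          columns=list("abcd"))
        out = impute_knn(df, {c: "g" for c in df.columns})
        pd.testing.assert_frame_equal(out, df)

    def test_hand_example_mean_of_four_neighbours(self):
        """5 subjects, one missing HDL; the 4 nearest by lipid-block
        distance carry HDL {40,50,60,70} -> imputed value 55."""
        df = pd.DataFrame(
            {
                "hdl": [np.nan, 40.0, 50.0, 60.0, 70.0],
                "ldl": [120.0, 118.0, 122.0, 121.0, 119.0],
                "tg": [150.0, 149.0, 151.0, 150.0, 152.0],
            }
        )
        groups = {"hdl": "lipids", "ldl": "lipids", "tg": "lipids"}
        out = impute_knn(df, groups, k=4)
        assert out.loc[0, "hdl"] == pytest.approx(55.0)
        # observed cells untouched
        assert out.loc[1:, "hdl"].tolist() == [40, 50, 60, 70]

    def test_group_restriction(self):
        """Neighbours are found within the same variable group only: an
        identical-lipids twin dictates the imputed value even though the
        obesity block would pick a different neighbour."""
        df = pd.DataFrame(
            {
                "hdl": [np.nan, 80.0, 20.0],
                "ldl": [100.0, 100.0, 250.0],
                "bmi": [40.0, 20.0, 40.0],
            }
        )
        groups = {"hdl": "lipids", "ldl": "lipids", "bmi": "obesity"}
        out = impute_knn(df, groups, k=1)
        assert out.loc[0, "hdl"] == pytest.approx(80.0)

    def test_beats_mean_imputation(self):
        """On MCAR-masked correlated data, k-NN RMSE < mean-imputation RMSE."""
        rng = np.random.default_rng(4)
        wins = 0
        for s in range(10):
            t = rng.standard_normal(300)
            full = pd.DataFrame(
                {f"v{j}": 0.9 * t + 0.4 * rng.standard_normal(300) for j in range(5)}
            )
            mask = rng.random(full.shape) < 0.1
            masked = full.mask(mask)
            imputed = impute_knn(masked, {c: "g" for c in full.columns}, k=4)
            knn_rmse = np.sqrt(((imputed - full) ** 2).to_numpy()[mask].mean())
            mean_rmse = np.sqrt(
                ((masked.fillna(masked.mean()) - full) ** 2).to_numpy()[mask].mean()
            )
            wins += knn_rmse < mean_rmse
        assert wins == 10

    def test_whole_group_missing_falls_back_with_warning(self):
        df = pd.DataFrame(
            {
                "hdl": [np.nan, 40.0, 50.0, 60.0, 55.0],
                "bmi": [30.0, 29.0, 31.0, 30.5, 29.5],
            }
        )
        groups = {"hdl": "lipids", "bmi": "obesity"}
        with pytest.warns(RuntimeWarning):
            out = impute_knn(df, groups, k=2)
        assert np.isfinite(out.loc[0, "hdl"])


class TestResidualize:
    @pytest.fixture
    def confounds(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {"age": rng.uniform(40, 80, 50), "sex": rng.integers(0, 2, 50)}
        )

    def test_pure_confound_column_vanishes(self, confounds):
        y = (2.0 * confounds["age"]).to_frame("y")
        out = residualize_confounds(y, confounds)
        assert np.allclose(out["y"], 0, atol=1e-8)

    def test_orthogonal_column_unchanged(self, confounds):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), confounds.to_numpy()])
        v -= X @ np.linalg.lstsq(X, v, rcond=None)[0]  # orthogonalize
        out = residualize_confounds(v[:, None], confounds)
        assert np.allclose(out[:, 0], v, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        conf = pd.DataFrame({"age": [1.0, 2, 3, 4, 5]})
        y = np.array([2.0, 1, 4, 3, 6])
        X = np.column_stack([np.ones(5), conf["age"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X @ beta
        out = residualize_confounds(y[:, None], conf)
        assert np.allclose(out[:, 0], expected, atol=1e-12)

    def test_idempotent_and_orthogonal(self, confounds):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal((50, 6)) + confounds[["age"]].to_numpy() * 0.1
        once = residualize_confounds(Y, confounds)
        twice = residualize_confounds(once, confounds)
        assert np.allclose(once, twice, atol=1e-10)
        for c in confounds.columns:
            dots = np.abs(confounds[c].to_numpy() @ once) / len(confounds)
            assert np.all(dots < 1e-8)

    def test_deconfounding_efficacy_on_cohort(self):
        """Post-residualization correlation of every confound with every
        variable is negligible on a contaminated synthetic cohort."""
        coh = gen_cohort(
            SyntheticCohortSpec(n_subjects=2000, n_regions=30, n_clinical=8,
                                confound_strength=0.5, missing_rate=0.0, seed=8)
        )
        resid = residualize_confounds(coh.clinical, coh.confounds)
        for c in coh.confounds.columns:
            r = np.corrcoef(
                coh.confounds[c], resid.to_numpy(), rowvar=False
            )[0, 1:]
            assert np.all(np.abs(r) < 0.02)

    def test_collinear_confounds_rejected(self):
        conf = pd.DataFrame({"a": [1.0, 2, 3, 4, 5, 6], "b": [2.0, 4, 6, 8, 10, 12]})
        with pytest.raises(ValueError, match="collinear"):
            residualize_confounds(np.random.default_rng(0).normal(size=(6, 2)), conf)


class TestZscore:
    def test_hand_values(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(out[:, 0], [-1, 0, 1])
        x = np.array([2.0, 4, 4, 4, 5, 5, 7, 9])
        expected = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(zscore_columns(x[:, None])[:, 0], expected, atol=1e-12)

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore_columns(rng.standard_normal((100, 3)))
        assert np.allclose(zscore_columns(z), z, atol=1e-10)

    def test_constant_column_named(self):
        df = pd.DataFrame({"ok": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            zscore_columns(df)


class TestHarmonize:
    def test_single_cohort_equals_plain_zscore(self):
        v = np.array([3.0, 1, 4, 1, 5, 9])
        out = harmonize_across_cohorts(v, np.zeros(6))
        assert np.allclose(out, (v - v.mean()) / v.std(ddof=1))

    def test_invariant_to_cohort_scale(self):
        a = np.array([10.0, 20, 30])
        b = np.array([100.0, 200, 300])
        v1 = harmonize_across_cohorts(np.r_[a, b], np.r_[0, 0, 0, 1, 1, 1])
        v2 = harmonize_across_cohorts(np.r_[a, 7 * b + 3], np.r_[0, 0, 0, 1, 1, 1])
        assert np.allclose(v1, v2, atol=1e-10)

    def test_within_cohort_means_zero_after_first_stage(self):
        v = np.r_[np.array([1.0, 2, 3]), np.array([10.0, 30, 50])]
        lab = np.r_[0, 0, 0, 1, 1, 1]
        out = harmonize_across_cohorts(v, lab)
        # pooled z-scoring preserves within-cohort mean equality
        assert abs(out[:3].mean() - out[3:].mean()) < 1e-10

    def test_constant_cohort_rejected(self):
        with pytest.raises(ValueError):
            harmonize_across_cohorts(np.r_[1.0, 1, 1, 2, 3, 4], np.r_[0, 0, 0, 1, 1, 1])


def _brute_force_mets(row, thr):
    central = row["waist"] >= (thr["waist_female"] if row["sex"] else thr["waist_male"])
    crit = [
        row["triglycerides"] >= thr["triglycerides"],
        row["hdl"] < (thr["hdl_female"] if row["sex"] else thr["hdl_male"]),
        row["bp_systolic"] >= thr["bp_systolic"]
        or row["bp_diastolic"] >= thr["bp_diastolic"]
        or row["antihypertensive"],
        row["glucose"] >= thr["glucose"] or row["antidiabetic"],
    ]
    return int(central and sum(crit) >= 2)


class TestClassifyMets:
    def test_exhaustive_truth_table(self):
        """All 2^5 on/off patterns of the five criteria match a brute-force
        rule evaluator, for both sexes."""
        from morphlink.preprocess import DEFAULT_METS_THRESHOLDS as thr

        rows = []
        for sex, bits in itertools.product([0, 1], itertools.product([0, 1], repeat=5)):
            central, tg, hdl, bp, glc = bits
            waist_cut = thr["waist_female"] if sex else thr["waist_male"]
            hdl_cut = thr["hdl_female"] if sex else thr["hdl_male"]
            rows.append(
                {
                    "sex": sex,
                    "waist": waist_cut + (5 if central else -5),
                    "triglycerides": thr["triglycerides"] + (10 if tg else -10),
                    "hdl": hdl_cut + (-5 if hdl else 5),
                    "bp_systolic": thr["bp_systolic"] + (5 if bp else -5),
                    "bp_diastolic": thr["bp_diastolic"] - 10,
                    "glucose": thr["glucose"] + (5 if glc else -5),
                    "antihypertensive": 0,
                    "antidiabetic": 0,
                }
            )
        df = pd.DataFrame(rows)
        got = classify_mets(df)
        expected = df.apply(lambda r: _brute_force_mets(r, thr), axis=1)
        assert (got == expected).all()

    def test_treatment_flags_count_as_criteria(self):
        from morphlink.preprocess import DEFAULT_METS_THRESHOLDS as thr

        row = {
            "sex": 0, "waist": thr["waist_male"] + 1,
            "triglycerides": 0.0, "hdl": 99.0,
            "bp_systolic": 100.0, "bp_diastolic": 60.0, "glucose": 80.0,
            "antihypertensive": 1, "antidiabetic": 1,
        }
        assert classify_mets(pd.DataFrame([row])).iloc[0] == 1

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError):
            classify_mets(pd.DataFrame({"waist": [100.0]}))


class TestMatching:
    def test_exact_copies_match_perfectly(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(
            {"age": rng.uniform(40, 80, 20), "sex": rng.integers(0, 2, 20),
             "education": rng.integers(1, 5, 20)},
            index=[f"s{i}" for i in range(20)],
        )
        cases = cov.index[:10]
        copies = cov.loc[cases].rename(index=lambda s: "c" + s)
        full = pd.concat([cov, copies])
        pairs, balance = match_cases_controls(cases, copies.index, full, seed=0)
        assert (pairs["control"] == "c" + pairs["case"]).all()
        assert np.allclose(balance["smd_after"], 0.0)

    def test_matches_brute_force_greedy_oracle(self):
        cov = pd.DataFrame({"age": [50.0, 60, 70, 51, 61, 71]},
                           index=["a", "b", "c", "x", "y", "z"])
        pairs, _ = match_cases_controls(["a", "b", "c"], ["x", "y", "z"], cov, seed=0)
        got = dict(zip(pairs["case"], pairs["control"]))
        assert got == {"a": "x", "b": "y", "c": "z"}

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame({"age": rng.uniform(40, 80, 30)})
        p1, _ = match_cases_controls(range(10), range(10, 30), cov, seed=7)
        p2, _ = match_cases_controls(range(10), range(10, 30), cov, seed=7)
        pd.testing.assert_frame_equal(p1, p2)

    def test_small_pool_rejected(self):
        cov = pd.DataFrame({"age": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            match_cases_controls([0, 1], [2], cov)


class TestGroupDifferenceMap:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        morph = pd.DataFrame(rng.standard_normal((200, 20)))
        conf = pd.DataFrame({"age": rng.uniform(40, 80, 200)})
        labels = rng.integers(0, 2, 200)
        out = group_difference_map(morph, labels, conf)
        assert (out["q"] >= 0.05).all()
        assert np.abs(out["t"]).max() < 4

    def test_single_parcel_matches_ols_oracle(self):
        rng = np.random.default_rng(1)
        n = 40
        g = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(40, 80, n)
        y = 0.8 * g + 0.02 * age + rng.standard_normal(n)
        morph = pd.DataFrame({"p0": y})
        conf = pd.DataFrame({"age": age})
        out = group_difference_map(morph, g, conf)
        X = np.column_stack([np.ones(n), g, age])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert out.loc["p0", "t"] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_planted_shift_detected(self):
        """+1 SD shift planted in 10 of 100 parcels is flagged at q<0.05."""
        hits = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            labels = np.r_[np.ones(200), np.zeros(200)]
            morph = rng.standard_normal((400, 100))
            morph[labels == 1, :10] += 1.0
            conf = pd.DataFrame({"age": rng.uniform(40, 80, 400)})
            out = group_difference_map(pd.DataFrame(morph), labels, conf)
            hits += (out["q"].to_numpy()[:10] < 0.05).sum() >= 8
        assert hits >= 4
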