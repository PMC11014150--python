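"""Group assignment, age-sex weighting, partial Spearman and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from apekit.cohort import (
    assign_groups,
    compute_weights,
    crf_tertile_cuts,
    group_compare,
    partial_spearman,
)
from apekit.errors import ConfigError, DataError
from apekit.synthetic import generate_cohort

from oracles import partial_spearman_oracle


def small_cohort(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "age": rng.uniform(20, 69, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "bmi": rng.uniform(18, 40, n),
            "vo2max": rng.uniform(15, 55, n),
        }
    )


class TestAssignGroups:
    @pytest.mark.parametrize("bmi,expected", [(24.9, "low"), (25.0, "mid"), (30.0, "mid"), (30.1, "high")])
    def test_bmi_category_boundaries(self, bmi, expected):
        df = small_cohort(12)
        df.loc[0, "bmi"] = bmi
        out = assign_groups(df)
        assert out.loc[0, "bmi_category"] == expected

    def test_nine_distinct_values_give_exact_thirds(self):
        df = small_cohort(9)
        df["sex"] = "female"
        df["vo2max"] = np.arange(20.0, 29.0)
        out = assign_groups(df)
        assert out["crf_third"].value_counts().tolist() == [3, 3, 3]
        assert (out.loc[df["vo2max"] < 23, "crf_third"] == "low").all()
        assert (out.loc[df["vo2max"] > 26, "crf_third"] == "high").all()

    def test_tertile_cuts_reproduced_from_constructed_quantiles(self):
        # a sample built to have tertile boundaries at 31.2 and 36.3 (women's cuts)
        v = np.concatenate(
            [np.linspace(20.0, 31.2, 7), np.linspace(31.2, 36.3, 7)[1:], np.linspace(36.3, 48.0, 7)[1:]]
        )
        q1, q2 = crf_tertile_cuts(v)
        assert q1 == pytest.approx(31.2, abs=1e-9)
        assert q2 == pytest.approx(36.3, abs=1e-9)

    def test_missing_vo2max_flagged_na(self):
        df = small_cohort(12)
        df.loc[3, "vo2max"] = np.nan
        out = assign_groups(df)
        assert pd.isna(out.loc[3, "crf_third"])
        assert out["crf_third"].notna().sum() == len(df) - 1


class TestComputeWeights:
    def test_two_cell_share_arithmetic(self):
        # counts 10 and 30 with equal targets -> weights 2.0 and 0.6667
        df = pd.DataFrame(
            {
                "sex": ["female"] * 10 + ["male"] * 30,
                "age": [25.0] * 40,
            }
        )
        with pytest.warns(UserWarning, match="empty age-sex cell"):
            w = compute_weights(df)
        assert w.iloc[0] == pytest.approx(2.0)
        assert w.iloc[-1] == pytest.approx(2.0 / 3.0)

    def test_balanced_cohort_has_unit_weights(self):
        ages = [25, 35, 45, 55, 65]
        df = pd.DataFrame(
            {
                "sex": ["female"] * 5 + ["male"] * 5,
                "age": [float(a) for a in ages] * 2,
            }
        )
        np.testing.assert_allclose(compute_weights(df), 1.0)

    def test_weighted_shares_equalize(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"sex": rng.choice(["female", "male"], 400), "age": rng.uniform(20, 70, 400)})
        w = compute_weights(df)
        cells = df["sex"] + "|" + (df["age"] // 10).astype(int).astype(str)
        shares = w.groupby(cells).sum() / w.sum()
        np.testing.assert_allclose(shares, shares.iloc[0], rtol=1e-9)

    def test_age_70_belongs_to_last_group(self):
        df = pd.DataFrame({"sex": ["female"] * 10, "age": [70.0] + [25.0] * 9})
        with pytest.warns(UserWarning):
            w = compute_weights(df)
        assert np.isfinite(w).all()


class TestPartialSpearman:
    def test_perfect_monotone_association(self, rng):
        n = 200
        age = rng.uniform(20, 69, n)
        sex = rng.integers(0, 2, n)
        x = rng.normal(size=n)
        res = partial_spearman(x, x.copy(), age, sex)
        assert res.r == pytest.approx(1.0)

    def test_null_simulation(self):
        rng = np.random.default_rng(99)
        n = 5000
        age = rng.uniform(20, 69, n)
        sex = rng.integers(0, 2, n)
        res = partial_spearman(rng.normal(size=n), rng.normal(size=n), age, sex)
        assert abs(res.r) < 0.05

    def test_toy_table_matches_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        age = [25.0, 34.0, 47.0, 52.0, 63.0, 68.0]
        sex = [0, 1, 0, 1, 0, 1]
        res = partial_spearman(x, y, age, sex)
        assert res.r == pytest.approx(partial_spearman_oracle(x, y, age, sex), abs=1e-10)

    def test_weighted_matches_oracle(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        age = rng.uniform(20, 69, n)
        sex = rng.integers(0, 2, n)
        w = rng.uniform(0.5, 2.0, n)
        res = partial_spearman(x, y, age, sex, weights=w)
        assert res.r == pytest.approx(partial_spearman_oracle(x, y, age, sex, w), abs=1e-10)

    def test_unweighted_close_to_pingouin(self, rng):
        # pingouin ranks the covariates as well, whereas this implementation
        # residualizes the ranks on the raw covariate design; the estimators
        # differ slightly, so this is an approximate independent cross-check.
        pingouin = pytest.importorskip("pingouin")
        n = 300
        age = rng.uniform(20, 69, n)
        sex = rng.integers(0, 2, n).astype(float)
        x = rng.normal(size=n) + 0.02 * age
        y = rng.normal(size=n) + 0.6 * x - 0.01 * age
        age_c = age - age.mean()
        df = pd.DataFrame({"x": x, "y": y, "age": age_c, "age2": age_c**2, "sex": sex})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "age2", "sex"], method="spearman")
        res = partial_spearman(x, y, age, sex)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=0.02)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**20), power=st.sampled_from([1.0, 3.0]), scale=st.floats(0.1, 5.0))
    def test_invariant_to_strictly_monotone_transforms(self, seed, power, scale):
        rng = np.random.default_rng(seed)
        n = 30
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        age = rng.uniform(20, 69, n)
        sex = rng.integers(0, 2, n)
        base = partial_spearman(x, y, age, sex).r
        transformed = partial_spearman(scale * np.sign(x) * np.abs(x) ** power, np.exp(y), age, sex).r
        assert transformed == pytest.approx(base, abs=1e-10)

    def test_constant_input_flagged(self):
        with pytest.raises(DataError, match="constant"):
            partial_spearman([1.0] * 10, list(range(10)), list(range(20, 30)), [0, 1] * 5)


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        vals = np.tile(np.arange(10.0), 3)
        groups = np.repeat(["a", "b", "c"], 10)
        res = group_compare(vals, groups)
        assert res.h == pytest.approx(0.0, abs=1e-9)
        assert (res.pairwise["p_adj"] == 1.0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 120), rng.normal(0, 1, 120), rng.normal(1.0, 1, 120)])
        groups = np.repeat(["a", "b", "c"], 120)
        res = group_compare(vals, groups)
        assert res.p < 0.05
        shifted = res.pairwise[(res.pairwise["group1"] == "a") & (res.pairwise["group2"] == "c")]
        assert shifted["p_adj"].iloc[0] < 0.05

    def test_hand_computed_two_groups_of_three(self):
        # values with ranks 1,2,3 vs 4,5,6: H = 12/(6*7) * 3*((2-3.5)^2 + (5-3.5)^2)
        vals = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = group_compare(vals, groups)
        assert res.h == pytest.approx(12 / 42 * (3 * 1.5**2 + 3 * 1.5**2))
        # Dunn z = (2 - 5) / sqrt((6*7/12) * (1/3 + 1/3))
        z = res.pairwise["z"].iloc[0]
        assert abs(z) == pytest.approx(3.0 / np.sqrt(3.5 * (2 / 3)))

    def test_h_matches_scipy_with_ties(self, rng):
        vals = rng.integers(0, 5, 60).astype(float)
        groups = rng.choice(["a", "b", "c"], 60)
        res = group_compare(vals, groups)
        h, p = stats.kruskal(*[vals[groups == g] for g in ["a", "b", "c"]])
        assert res.h == pytest.approx(h)
        assert res.p == pytest.approx(p)

    def test_single_group_is_config_error(self):
        with pytest.raises(ConfigError):
            group_compare([1.0, 2.0, 3.0], ["a", "a", "a"])


class TestSignRecovery:
    def test_planted_effects_recover_expected_signs(self):
        df = generate_cohort(300, seed=42)
        w = compute_weights(df).to_numpy()
        low = partial_spearman(df["ape_min_05_10"], df["vo2max"], df["age"], df["sex"], weights=w)
        high = partial_spearman(df["ape_min_60_65"], df["vo2max"], df["age"], df["sex"], weights=w)
        low_bmi = partial_spearman(df["ape_min_05_10"], df["bmi"], df["age"], df["sex"], weights=w)
        high_bmi = partial_spearman(df["ape_min_60_65"], df["bmi"], df["age"], df["sex"], weights=w)
        assert low.r > 0 and high.r < 0  # fitness: up at standing angles, down when reclined
        assert low_bmi.r < 0 and high_bmi.r > 0  # BMI mirrors it
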