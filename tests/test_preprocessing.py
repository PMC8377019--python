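"""Exclusion cascade, winsorisation, standardisation and effect coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import facepref as fp
from facepref.preprocessing import Winsorizer


class TestExclusions:
    def test_cascade_counts_reconcile(self, participants_frame):
        retained, report = fp.apply_exclusions(participants_frame)
        assert report.n_input == len(participants_frame)
        assert report.n_removed_kinsey == 2
        assert report.n_removed_sex_other == 1
        # country B had 9 left after the first two rules -> all dropped
        assert report.n_removed_small_country == 9
        assert report.n_retained == len(retained)
        assert (
            report.n_removed_kinsey
            + report.n_removed_sex_other
            + report.n_removed_small_country
            + report.n_retained
            == report.n_input
        )
        assert report.retained_country_list == ["A", "C"]

    def test_kinsey_high_removed_missing_kept(self, participants_frame):
        retained, _ = fp.apply_exclusions(participants_frame)
        assert not retained["kinsey"].isin([4, 5, 6]).any()
        assert retained["kinsey"].isna().sum() == 1  # missing kinsey retained

    def test_sex_other_removed(self, participants_frame):
        retained, _ = fp.apply_exclusions(participants_frame)
        assert set(retained["sex"]) <= {"female", "male"}

    def test_exactly_ten_retained_country_kept(self, participants_frame):
        retained, _ = fp.apply_exclusions(participants_frame)
        assert (retained["country_id"] == "C").sum() == 10

    def test_idempotent(self, participants_frame):
        once, _ = fp.apply_exclusions(participants_frame)
        twice, report = fp.apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_retained == report.n_input

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fp.apply_exclusions(pd.DataFrame(columns=["kinsey", "sex", "country_id"]))


class TestWinsorise:
    def test_outlier_inside_three_sds_untouched(self):
        vals = np.array([0.0, 0, 0, 0, 100])
        # sample SD ~ 44.7 * sqrt(5/4); 100 < mean + 3 SD either way
        out = fp.winsorise(vals)
        np.testing.assert_array_equal(out, vals)

    def test_constant_vector_unchanged(self):
        vals = np.array([2.0, 2, 2, 2])
        np.testing.assert_array_equal(fp.winsorise(vals), vals)

    def test_value_exactly_at_bound_not_clipped(self):
        vals = np.array([-1.0, 0, 1])
        sd = np.std(vals, ddof=1)
        boundary = float(np.mean(vals) + 3 * sd)
        arr = np.append(vals, boundary)
        # recompute bound on the 4-vector; append a value exactly at it
        m, s = arr.mean(), arr.std(ddof=1)
        arr2 = np.append(arr, m + 3 * s)
        out = fp.winsorise(arr2)
        assert out[-1] == arr2[-1]

    def test_extreme_value_clipped_to_bound(self):
        # a lone outlier among n=10 caps at z=(n-1)/sqrt(n)~2.85, below 3,
        # so the 3-SD rule leaves it; a 2-SD rule must clip it
        vals = np.array([0.0, 0, 0, 0, 0, 0, 0, 0, 0, 1000])
        np.testing.assert_array_equal(fp.winsorise(vals, k=3), vals)
        out = fp.winsorise(vals, k=2)
        m, s = vals.mean(), vals.std(ddof=1)
        assert out[-1] == pytest.approx(m + 2 * s)

    def test_missing_passes_through(self):
        vals = pd.Series([1.0, np.nan, 3.0, 2.0])
        out = fp.winsorise(vals)
        assert out.isna().tolist() == [False, True, False, False]

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(
            lambda v: np.std(v) > 0
        )
    )
    def test_never_increases_distance_from_mean(self, vals):
        arr = np.array(vals)
        out = fp.winsorise(arr)
        m = arr.mean()
        assert np.all(np.abs(out - m) <= np.abs(arr - m) + 1e-9)
        s = arr.std(ddof=1)
        assert np.all(out >= m - 3 * s - 1e-9) and np.all(out <= m + 3 * s + 1e-9)

    def test_transformer_applies_training_bounds_to_new_data(self):
        train = np.array([0.0, 1, 2, 3, 4])
        w = Winsorizer(k=1.0).fit(train)
        out = w.transform(np.array([100.0, -100.0, 2.0]))
        assert out[0] == pytest.approx(train.mean() + train.std(ddof=1))
        assert out[1] == pytest.approx(train.mean() - train.std(ddof=1))
        assert out[2] == 2.0


class TestStandardise:
    def test_unit_spacing(self):
        np.testing.assert_allclose(fp.standardise([1.0, 2.0, 3.0]), [-1, 0, 1])

    def test_mean_zero(self):
        rng = np.random.default_rng(0)
        z = fp.standardise(rng.normal(5, 3, 500))
        assert abs(z.mean()) < 1e-12

    def test_country_level_unit_of_analysis(self):
        # 12 countries, unequal row counts; country-level z must ignore row
        # multiplicity
        rng = np.random.default_rng(1)
        country_vals = rng.normal(size=12)
        rows_per = rng.integers(1, 30, size=12)
        by = np.repeat(np.arange(12), rows_per)
        vals = np.repeat(country_vals, rows_per)
        z = fp.standardise(vals, by=by)
        firsts = pd.DataFrame({"by": by, "z": z}).groupby("by")["z"].first()
        assert len(firsts) == 12
        assert firsts.mean() == pytest.approx(0.0, abs=1e-12)
        assert firsts.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero variance"):
            z = fp.standardise([4.0, 4.0, 4.0])
        np.testing.assert_array_equal(z, [0, 0, 0])


class TestEffectCode:
    @pytest.mark.parametrize(
        "value,variable,expected",
        [
            ("female", "sex", -1.0),
            ("male", "sex", 1.0),
            ("low", "level", -1.0),
            ("high", "level", 1.0),
            ("low", "chosen_level", -1.0),
            ("medium", "chosen_level", 0.0),
            ("high", "chosen_level", 1.0),
        ],
    )
    def test_declared_conventions(self, value, variable, expected):
        assert fp.effect_code([value], variable)[0] == expected

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError, match="categories"):
            fp.effect_code(["unknown"], "sex")


class TestStandardizer:
    def test_training_scale_applied_to_new_data(self):
        from facepref.preprocessing import Standardizer

        train = np.array([[0.0, 10.0], [2.0, 10.0], [4.0, 10.0]])
        sc = Standardizer().fit(train)
        out = sc.transform(np.array([[6.0, 10.0]]))
        assert out[0, 0] == pytest.approx((6.0 - 2.0) / 2.0)
        assert out[0, 1] == 0.0  # zero-variance column maps to zero
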