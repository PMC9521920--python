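"""Composition filtering, ratio pooling, interpolation, trends, standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elkdemog import elk


def _comp(rows):
    return pd.DataFrame(rows, columns=["year", "herd", "cows", "calves", "bulls"])


class TestFiltering:
    def test_reason_codes(self):
        rec = _comp([
            (2000, "a", 10, 12, 3),      # calves > cows
            (2000, "b", 50, 20, 10),     # retained
            (2001, "a", 40, 0, 5),       # zero calves
            (2002, "a", np.nan, 8, np.nan),  # adults unknown
        ])
        res = elk.filter_composition_counts(rec)
        assert len(res.retained) == 1
        reasons = set(res.exclusions["reason"])
        assert reasons == {elk.REASON_CALVES_EXCEED_COWS, elk.REASON_ZERO_CALVES,
                           elk.REASON_ADULTS_UNKNOWN}

    def test_small_group_year_dropped_whole(self):
        rec = _comp([
            (2006, "a", 2, 1, 1),
            (2006, "b", 1, 0, 0),   # dropped first for zero calves
            (2007, "a", 40, 12, 9),
        ])
        res = elk.filter_composition_counts(rec, min_group_total=5)
        assert set(res.retained["year"]) == {2007}
        assert (res.exclusions["reason"] == elk.REASON_GROUP_TOTAL).sum() == 1

    def test_blocklisted_herd_dropped(self):
        rec = _comp([(2000, "dense", 30, 10, 5), (2000, "open", 30, 10, 5)])
        res = elk.filter_composition_counts(rec, herd_blocklist=("dense",))
        assert list(res.retained["herd"]) == ["open"]

    def test_idempotent_and_conserves_records(self):
        rng = np.random.default_rng(0)
        rec = _comp([(2000 + i % 10, f"h{i % 3}", rng.integers(0, 50),
                      rng.integers(0, 30), rng.integers(0, 20))
                     for i in range(60)])
        res = elk.filter_composition_counts(rec)
        assert len(res.retained) + len(res.exclusions) == len(rec)
        res2 = elk.filter_composition_counts(res.retained)
        assert len(res2.retained) == len(res.retained)
        assert len(res2.exclusions) == 0


class TestAgeRatios:
    def test_single_herd_ratio(self):
        rec = _comp([(2000, "a", 100, 33, 0)])
        assert elk.aggregate_age_ratios(rec)[2000] == pytest.approx(33.0)

    def test_pooled_not_averaged(self):
        rec = _comp([(2000, "a", 50, 10, 0), (2000, "b", 50, 23, 0)])
        assert elk.aggregate_age_ratios(rec)[2000] == pytest.approx(33.0)

    @given(st.lists(
        st.tuples(st.integers(1, 200), st.integers(0, 150)),
        min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_pooled_ratio_matches_oracle_and_bounds(self, herds):
        rec = _comp([(2000, f"h{i}", c, k, 0) for i, (c, k) in enumerate(herds)])
        ratio = elk.aggregate_age_ratios(rec)[2000]
        total_c = sum(c for c, _ in herds)
        total_k = sum(k for _, k in herds)
        assert ratio == pytest.approx(100.0 * total_k / total_c)
        per_herd = [100.0 * k / c for c, k in herds]
        assert min(per_herd) - 1e-9 <= ratio <= max(per_herd) + 1e-9


class TestInterpolation:
    def test_linear_fill(self):
        s = pd.Series({2000: 90.0, 2003: 120.0})
        out = elk.interpolate_missing_counts(s)
        assert out.counts[2001] == pytest.approx(100.0)
        assert out.counts[2002] == pytest.approx(110.0)
        assert list(out.imputed[out.imputed].index) == [2001, 2002]

    def test_identity_when_complete(self):
        s = pd.Series({2000: 5.0, 2001: 7.0, 2002: 6.0})
        out = elk.interpolate_missing_counts(s)
        pd.testing.assert_series_equal(out.counts, s, check_names=False)
        assert not out.imputed.any()

    def test_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(3)
        years = np.arange(1960, 2000)
        vals = rng.uniform(50, 200, len(years))
        keep = np.sort(rng.choice(len(years), size=25, replace=False))
        keep = np.unique(np.concatenate([[0, len(years) - 1], keep]))
        s = pd.Series(vals[keep], index=years[keep])
        out = elk.interpolate_missing_counts(s)
        oracle = np.interp(years, years[keep], vals[keep])
        np.testing.assert_allclose(out.counts.to_numpy(), oracle)
        pd.testing.assert_series_equal(out.counts[s.index], s,
                                       check_names=False)

    def test_trailing_gap_errors(self):
        s = pd.Series({2000: 90.0, 2001: np.nan}).astype(float)
        with pytest.raises(ValueError, match="observed"):
            elk.interpolate_missing_counts(s)


class TestStandardize:
    def test_unit_variance_example(self):
        z, scaling = elk.standardize_predictors(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["x"], [-1.0, 0.0, 1.0])
        assert scaling.loc["x", "sd"] == pytest.approx(1.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(10, 5, (30, 3)), columns=list("abc"))
        z, scaling = elk.standardize_predictors(df)
        back = z * scaling["sd"] + scaling["mean"]
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), rtol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            elk.standardize_predictors(df)


class TestLinearTrend:
    def test_exact_line(self):
        years = np.arange(1990, 2000)
        s = pd.Series(2.0 * years + 1.0, index=years)
        out = elk.linear_trend(s)
        assert out["slope"] == pytest.approx(2.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        years = np.arange(1960, 2010)
        s = pd.Series(0.5 * years + rng.normal(0, 8, len(years)), index=years)
        out = elk.linear_trend(s)
        # oracle: solve X'X beta = X'y directly
        X = np.column_stack([np.ones(len(years)), years])
        beta = np.linalg.solve(X.T @ X, X.T @ s.to_numpy())
        assert out["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert out["slope"] == pytest.approx(beta[1], abs=1e-10)
        resid = s.to_numpy() - X @ beta
        r2 = 1 - resid @ resid / np.sum((s - s.mean()) ** 2)
        assert out["r2"] == pytest.approx(r2, abs=1e-10)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            elk.linear_trend(pd.Series({2000: 1.0, 2001: 2.0}))
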