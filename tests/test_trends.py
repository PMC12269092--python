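"""Seasonal Mann-Kendall, Sen slopes, and browning clustering.

The brute-force oracle below enumerates every within-season pair directly
and is kept free of any vectorisation shared with the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from lakephotochem import synthio, trends
from lakephotochem.exceptions import DegenerateClusteringWarning, InsufficientDataError


def smk_oracle(values, month_index, period=12):
    """Plain-loop seasonal Mann-Kendall: S, tie-corrected Var(S), Sen slope."""
    s_total, var_total, slopes = 0, 0.0, []
    for season in range(period):
        xs = [(t, v) for t, v in zip(month_index, values)
              if t % period == season and np.isfinite(v)]
        n = len(xs)
        if n < 2:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                (ti, vi), (tj, vj) = xs[i], xs[j]
                s_total += int(np.sign(vj - vi))
                if tj != ti:
                    slopes.append((vj - vi) / (tj - ti))
        ties = {}
        for _, v in xs:
            ties[v] = ties.get(v, 0) + 1
        tie_term = sum(c * (c - 1) * (2 * c + 5) for c in ties.values())
        var_total += (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    sen = float(np.median(slopes) * 12.0) if slopes else 0.0
    return s_total, var_total, sen


class TestSeasonalMannKendall:
    def test_constant_increment_slope_exact(self):
        # +0.1/month over 60 months -> Sen slope exactly 1.2/yr, tiny p
        v = 0.1 * np.arange(60.0)
        r = trends.seasonal_mann_kendall(v)
        assert r.sen_slope == pytest.approx(1.2, abs=1e-12)
        assert r.p < 1e-3
        assert r.significant and r.slope_for_clustering == r.sen_slope

    def test_three_season_toy_matches_enumeration(self):
        # 4 years x 3 seasons with ties, frozen values
        values = np.array([2.1, 0.5, 3.3, 2.1, 0.7, 3.0, 2.6, 0.7, 2.8, 2.4, 1.1, 3.6])
        month_index = np.arange(12)
        exp_s, exp_var, exp_sen = smk_oracle(values, month_index, period=3)
        r = trends.seasonal_mann_kendall(values, month_index, period=3)
        assert r.s_stat == exp_s
        assert r.var_s == pytest.approx(exp_var, rel=1e-12)
        assert r.sen_slope == pytest.approx(exp_sen, rel=1e-12)

    def test_constant_series_degenerate_not_error(self):
        r = trends.seasonal_mann_kendall(np.full(48, 7.0))
        assert r.s_stat == 0 and r.p == 1.0 and r.sen_slope == 0.0
        assert not r.significant and r.slope_for_clustering == 0.0

    def test_too_few_seasons_raises(self):
        with pytest.raises(InsufficientDataError):
            trends.seasonal_mann_kendall(np.array([1.0, 2.0, 3.0]), np.array([0, 1, 2]))

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(24, 200))
        # round to force ties; random gaps in the month index
        t = np.sort(rng.choice(np.arange(int(n * 1.3)), size=n, replace=False))
        v = np.round(rng.normal(0, 1, n) + 0.01 * t, 1)
        exp_s, exp_var, exp_sen = smk_oracle(v, t)
        r = trends.seasonal_mann_kendall(v, t)
        assert r.s_stat == exp_s
        assert r.var_s == pytest.approx(exp_var, rel=1e-12)
        assert r.sen_slope == pytest.approx(exp_sen, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_monotone_transform_invariance_of_s_and_p(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(5, 1, 96)
        r1 = trends.seasonal_mann_kendall(v)
        r2 = trends.seasonal_mann_kendall(np.exp(v))
        assert r1.s_stat == r2.s_stat
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_dates_interface_matches_month_index(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, 72)
        dates = pd.date_range("2000-01-01", periods=72, freq="MS")
        r1 = trends.seasonal_mann_kendall(v, dates)
        r2 = trends.seasonal_mann_kendall(v, np.arange(72))
        assert r1.s_stat == r2.s_stat
        assert r1.sen_slope == pytest.approx(r2.sen_slope)


class TestTrendTable:
    def test_noise_free_planted_slopes_recovered_exactly(self, drainage_spec):
        chem = synthio.gen_chemistry(
            drainage_spec, months=120, seed=0, seasonal_amp=0.0,
            noise_sd=0.0, missing_frac=0.0,
        )
        tt = trends.trend_table([chem])
        doc_row = tt[tt.parameter == "doc"].iloc[0]
        assert doc_row.sen_slope == pytest.approx(drainage_spec.doc_trend, rel=1e-9)
        suva_row = tt[tt.parameter == "suva254"].iloc[0]
        assert suva_row.sen_slope == pytest.approx(drainage_spec.suva_trend, rel=1e-9)

    def test_missing_parameter_flagged_not_fatal(self, drainage_spec):
        chem = synthio.gen_chemistry(drainage_spec, months=60, seed=0, missing_frac=0.0)
        chem.data["color"] = np.nan
        tt = trends.trend_table([chem])
        color = tt[tt.parameter == "color"].iloc[0]
        assert bool(color.missing) and np.isnan(color.sen_slope)
        assert not tt[tt.parameter == "doc"].iloc[0].missing

    def test_mostly_significant_positive_doc_trends_on_strong_planting(self):
        # 33 strong positive planted trends out of 37 -> at least 33 significant
        lakes = synthio.gen_lakes(37, seed=5)
        planted = []
        for i, spec in enumerate(lakes):
            trend = 0.08 if i < 33 else 0.0
            planted.append(
                synthio.LakeSpec(**{**spec.__dict__, "doc_trend": trend})
            )
        chems = [
            synthio.gen_chemistry(s, months=240, seed=100 + i, noise_sd=0.08,
                                  missing_frac=0.0)
            for i, s in enumerate(planted)
        ]
        tt = trends.trend_table(chems)
        doc = tt[tt.parameter == "doc"]
        n_sig_pos = int(((doc.p < 0.05) & (doc.sen_slope > 0)).sum())
        assert n_sig_pos >= 33


def test_type_one_error_inflation_under_strong_autocorrelation_documented():
    """SMK size inflates under serial correlation; documented, loosely bounded.

    The test's variance formula assumes serial independence.  Month-to-month
    AR(1) correlation of 0.5 inflates the empirical alpha=0.05 rejection
    rate several-fold (to roughly 0.2); this check documents that behaviour
    without asserting a tight value.
    """
    def ar1(rng, n, phi):
        e = np.empty(n)
        e[0] = rng.normal()
        for t in range(1, n):
            e[t] = phi * e[t - 1] + rng.normal(0, np.sqrt(1 - phi**2))
        return e

    rejections = 0
    for seed in range(150):
        rng = np.random.default_rng(seed)
        r = trends.seasonal_mann_kendall(ar1(rng, 120, 0.5))
        rejections += r.significant
    rate = rejections / 150
    assert 0.05 < rate < 0.45  # inflated above nominal, but bounded


def make_planted_trend_df(rng, centers, per_cluster=12, spread=0.01):
    rows = []
    truth = []
    k = 0
    for ci, center in enumerate(centers):
        for _ in range(per_cluster):
            lake = f"L{k:03d}"
            vals = np.asarray(center) + spread * rng.standard_normal(3)
            for par, v in zip(trends.CLUSTER_PARAMETERS, vals):
                rows.append({"lake_id": lake, "parameter": par,
                             "slope_for_clustering": v})
            truth.append((lake, ci))
            k += 1
    return pd.DataFrame(rows), dict(truth)


class TestClassifyBrowning:
    def test_planted_partition_fully_recovered(self, rng):
        # well-separated mild/moderate/intense centroids, 12 lakes each
        centers = [(0.005, 0.05, -0.05), (0.05, 0.5, -0.04), (0.10, 1.0, -0.15)]
        df, truth = make_planted_trend_df(rng, centers)
        out = trends.classify_browning(df, seed=0)
        grouping = out.groupby("cluster")["lake_id"].apply(set)
        # the mapping rule must put the mildest centroid in A, intense in C
        assert grouping["A"] == {l for l, c in truth.items() if c == 0}
        assert grouping["B"] == {l for l, c in truth.items() if c == 1}
        assert grouping["C"] == {l for l, c in truth.items() if c == 2}

    def test_identical_slopes_degenerate_all_a(self):
        rows = [
            {"lake_id": f"L{i}", "parameter": p, "slope_for_clustering": 0.1}
            for i in range(5)
            for p in trends.CLUSTER_PARAMETERS
        ]
        with pytest.warns(DegenerateClusteringWarning):
            out = trends.classify_browning(pd.DataFrame(rows), seed=0)
        assert set(out.cluster) == {"A"}

    def test_input_order_invariance(self, rng):
        centers = [(0.0, 0.0, 0.0), (0.05, 0.5, -0.05), (0.1, 1.0, -0.2)]
        df, _ = make_planted_trend_df(rng, centers)
        out1 = trends.classify_browning(df, seed=7)
        shuffled = df.sample(frac=1.0, random_state=99).reset_index(drop=True)
        out2 = trends.classify_browning(shuffled, seed=7)
        m1 = dict(zip(out1.lake_id, out1.cluster))
        m2 = dict(zip(out2.lake_id, out2.cluster))
        assert m1 == m2

    def test_too_few_lakes_rejected(self):
        rows = [
            {"lake_id": f"L{i}", "parameter": p, "slope_for_clustering": float(i)}
            for i in range(2)
            for p in trends.CLUSTER_PARAMETERS
        ]
        with pytest.raises(InsufficientDataError):
            trends.classify_browning(pd.DataFrame(rows))
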