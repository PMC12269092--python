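"""Seasonal Mann-Kendall trend tests, Sen's slopes, and browning clustering.

The seasonal Mann-Kendall test (Hirsch-Slack form) restricts the pairwise
sign comparisons of the classic test to observations in the same season
(calendar month here), summing the statistic S and its tie-corrected
variance over seasons and applying the usual +/-1 continuity correction
before the normal approximation.  The accompanying Sen slope is the median
of all within-season pairwise slopes, converted to per-year units.

For browning classification, slopes that fail the 5% significance test are
replaced by zero, the (DOC, color, SUVA254) slope triples are z-scored per
dimension, and k-means with k=3 partitions the lakes.  Cluster labels are
mapped deterministically: A is the cluster with the lowest mean standardized
DOC+color slope (mildest browning); of the remaining two, C has the most
negative standardized SUVA254 slope (intense browning) and B the other
(moderate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .exceptions import DegenerateClusteringWarning, InsufficientDataError

PARAMETERS = ("doc", "color", "suva254", "ph", "so4_no3")
CLUSTER_PARAMETERS = ("doc", "color", "suva254")


@dataclass(frozen=True)
class SenTrendResult:
    """Seasonal Mann-Kendall outcome for one series."""

    parameter: str
    s_stat: int
    var_s: float
    z: float
    p: float
    sen_slope: float  # parameter units per year
    significant: bool
    slope_for_clustering: float
    n: int
    lake_id: str | None = None
    missing: bool = False


def _month_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Months elapsed since the first observation."""
    return (dates.year - dates.year[0]) * 12 + (dates.month - dates.month[0])


def seasonal_mann_kendall(
    values: np.ndarray,
    dates: pd.DatetimeIndex | np.ndarray | None = None,
    period: int = 12,
    parameter: str = "value",
    alpha: float = 0.05,
) -> SenTrendResult:
    """Seasonal Mann-Kendall test with tie-corrected variance and Sen slope.

    ``dates`` may be a DatetimeIndex (seasons = calendar months) or an
    integer month index (seasons = index modulo ``period``); if omitted the
    values are taken as consecutive months.  NaNs are dropped.  Requires at
    least two seasons containing two or more observations.
    """
    v = np.asarray(values, dtype=float)
    if dates is None:
        t = np.arange(v.size)
        season = t % period
    elif isinstance(dates, pd.DatetimeIndex):
        t = np.asarray(_month_index(dates), dtype=float)
        season = dates.month.to_numpy()
    else:
        t = np.asarray(dates, dtype=float)
        season = (t.astype(int)) % period
    keep = np.isfinite(v)
    v, t, season = v[keep], t[keep], season[keep]

    s_total = 0
    var_total = 0.0
    slopes: list[np.ndarray] = []
    usable_seasons = 0
    for g in np.unique(season):
        sel = season == g
        order = np.argsort(t[sel], kind="stable")
        x = v[sel][order]
        tt = t[sel][order]
        ng = x.size
        if ng < 2:
            continue
        usable_seasons += 1
        dx = x[None, :] - x[:, None]  # dx[i, j] = x_j - x_i (later minus earlier)
        dt = tt[None, :] - tt[:, None]
        iu = np.triu_indices(ng, k=1)
        s_total += int(np.sign(dx[iu]).sum())
        # tie correction over repeated values within the season
        _, counts = np.unique(x, return_counts=True)
        tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
        var_total += (ng * (ng - 1) * (2 * ng + 5) - tie_term) / 18.0
        ok = dt[iu] != 0  # pairs at identical times have undefined slope
        if ok.any():
            slopes.append(dx[iu][ok] / dt[iu][ok])
    if usable_seasons < 2:
        raise InsufficientDataError(
            f"need >= 2 seasons with >= 2 observations (got {usable_seasons})"
        )

    if var_total > 0:
        if s_total > 0:
            z = (s_total - 1) / np.sqrt(var_total)
        elif s_total < 0:
            z = (s_total + 1) / np.sqrt(var_total)
        else:
            z = 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    else:  # all values tied in every season
        z, p = 0.0, 1.0
    sen = float(np.median(np.concatenate(slopes)) * 12.0) if slopes else 0.0
    significant = bool(p < alpha)
    return SenTrendResult(
        parameter=parameter,
        s_stat=int(s_total),
        var_s=float(var_total),
        z=float(z),
        p=float(p),
        sen_slope=sen,
        significant=significant,
        slope_for_clustering=sen if significant else 0.0,
        n=int(v.size),
    )


def trend_table(
    lakes,
    parameters=PARAMETERS,
    min_months: int = 24,
) -> pd.DataFrame:
    """Per-(lake, parameter) trend results over the full record available.

    Each parameter is tested on its own record window, so early-terminating
    and late-starting records are honoured.  Parameters absent (or with
    fewer than ``min_months`` observations) are flagged ``missing`` rather
    than failing the table.
    """
    rows = []
    for lake in lakes:
        for par in parameters:
            if par not in lake.data.columns:
                res = _missing_result(par, lake.lake_id)
            else:
                s = lake.series(par).dropna()
                if s.size < min_months:
                    res = _missing_result(par, lake.lake_id)
                else:
                    r = seasonal_mann_kendall(s.to_numpy(), s.index, parameter=par)
                    res = SenTrendResult(**{**r.__dict__, "lake_id": lake.lake_id})
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def _missing_result(parameter: str, lake_id: str) -> SenTrendResult:
    return SenTrendResult(
        parameter=parameter, s_stat=0, var_s=np.nan, z=np.nan, p=np.nan,
        sen_slope=np.nan, significant=False, slope_for_clustering=np.nan,
        n=0, lake_id=lake_id, missing=True,
    )


def classify_browning(trend_df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """K-means (k=3) browning classification from zero-replaced Sen slopes.

    Input is the :func:`trend_table` output; lakes missing any of the DOC,
    color or SUVA254 slopes are dropped with a warning.  Returns one row per
    lake with the cluster label (A/B/C per the ordering rule in the module
    docstring) and the standardized slopes used.
    """
    wide = (
        trend_df[trend_df["parameter"].isin(CLUSTER_PARAMETERS)]
        .pivot(index="lake_id", columns="parameter", values="slope_for_clustering")
        .reindex(columns=CLUSTER_PARAMETERS)
    )
    complete = wide.dropna()
    if len(complete) < len(wide):
        dropped = sorted(set(wide.index) - set(complete.index))
        warnings.warn(
            f"{len(dropped)} lakes lack complete slope triples and were "
            f"excluded from clustering: {dropped}",
            UserWarning,
            stacklevel=2,
        )
    if len(complete) < 3:
        raise InsufficientDataError("need >= 3 lakes with all three slopes")
    complete = complete.sort_index()  # order invariance under input permutation

    x = complete.to_numpy(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if np.allclose(z, z[0]):
        warnings.warn(
            "all lakes have identical slopes; assigning every lake to cluster A",
            DegenerateClusteringWarning,
            stacklevel=2,
        )
        labels = np.zeros(len(complete), dtype=int)
        order = [0, 1, 2]
    else:
        km = KMeans(n_clusters=3, n_init=100, random_state=seed)
        labels = km.fit_predict(z)
        order = _label_order(z, labels)
    name_of = {cl: nm for cl, nm in zip(order, ("A", "B", "C"))}
    out = pd.DataFrame(
        {
            "lake_id": complete.index,
            "cluster": [name_of[l] for l in labels],
            "z_doc": z[:, 0],
            "z_color": z[:, 1],
            "z_suva254": z[:, 2],
        }
    ).reset_index(drop=True)
    return out


def _label_order(z: np.ndarray, labels: np.ndarray) -> list[int]:
    """Map raw k-means labels to (A, B, C) per the browning-intensity rule."""
    ids = sorted(set(labels))
    doc_color = {c: z[labels == c, :2].mean() for c in ids}
    a = min(ids, key=lambda c: doc_color[c])
    rest = [c for c in ids if c != a]
    suva = {c: z[labels == c, 2].mean() for c in rest}
    c_label = min(rest, key=lambda c: suva[c])
    b_label = next(c for c in rest if c != c_label)
    return [a, b_label, c_label]
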