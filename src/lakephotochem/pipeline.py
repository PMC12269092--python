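"""Orchestration, group-comparison statistics, and run configuration.

This module strings the stages together the way the analysis scripts use
them: simulate inputs -> trend table -> browning clusters -> driver
coherence -> quantum yields -> steady-state singlet oxygen -> contaminant
screening -> group comparisons.  Group differences follow the two-step
protocol used throughout the figures: a Kruskal-Wallis test first, then
pairwise two-sided Mann-Whitney U tests only when the omnibus test is
significant, with raw p-values tiered as * (<0.05), ** (<0.01),
*** (<0.001), **** (<0.0001).  No multiple-testing correction is applied to
the pairwise p-values — faithful to that protocol rather than statistically
recommended.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import synthio, trends, synchrony, photochem
from .exceptions import (
    InsufficientDataError,
    InvalidArgumentError,
    UndefinedMetricError,
)
from .photochem import LakeOpticalModel, PhotoConstants

STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mw_p: float
    stars: str


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis omnibus plus conditional pairwise Mann-Whitney tests."""

    grouping: str
    kw_p: float
    pairwise: tuple[PairwiseComparison, ...]
    group_sizes: dict
    excluded: tuple[str, ...] = ()


def stars(p: float) -> str:
    for cut, mark in STAR_TIERS:
        if p < cut:
            return mark
    return ""


def compare_groups(
    values,
    labels,
    grouping: str = "group",
    alpha: float = 0.05,
    min_per_group: int = 3,
    exact_max: int = 8,
) -> GroupComparison:
    """Kruskal-Wallis, then pairwise Mann-Whitney U on omnibus significance.

    Groups with fewer than ``min_per_group`` samples are excluded with a
    warning.  Pairwise p-values are exact when both groups have at most
    ``exact_max`` samples, otherwise the normal approximation with tie
    correction is used.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if v.shape != lab.shape:
        raise InvalidArgumentError("values and labels must have the same length")
    keep = np.isfinite(v)
    v, lab = v[keep], lab[keep]
    groups = {}
    excluded = []
    for g in pd.unique(lab):
        xs = v[lab == g]
        if xs.size < min_per_group:
            excluded.append(str(g))
            continue
        groups[str(g)] = xs
    if excluded:
        warnings.warn(
            f"excluded groups with < {min_per_group} samples: {sorted(excluded)}",
            UserWarning,
            stacklevel=2,
        )
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups with enough samples")

    samples = list(groups.values())
    if all(np.all(s == samples[0][0]) for s in samples):
        kw_p = 1.0  # identical constant groups: no evidence of difference
    else:
        kw_p = float(stats.kruskal(*samples).pvalue)
    pairwise = []
    if kw_p < alpha:
        names = sorted(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                xa, xb = groups[a], groups[b]
                method = "exact" if max(xa.size, xb.size) <= exact_max else "asymptotic"
                p = float(
                    stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue
                )
                pairwise.append(PairwiseComparison(a, b, p, stars(p)))
    return GroupComparison(
        grouping=grouping,
        kw_p=kw_p,
        pairwise=tuple(pairwise),
        group_sizes={g: int(x.size) for g, x in groups.items()},
        excluded=tuple(sorted(excluded)),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise InsufficientDataError("need >= 5 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMetricError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full simulated run needs; round-trips losslessly to YAML."""

    seed: int = 0
    n_lakes: int = 37
    months: int = 240
    start: str = "1992-06-01"
    seasonal_amp: float = 0.5
    noise_sd: float = 0.15
    missing_frac: float = 0.05
    color_fraction: float = 0.8  # fraction of the record with color data
    regional_sd: float = 0.4  # shared interannual DOC anomaly, mg C/L
    kinetics_noise_cv: float = 0.02
    phi_srnom: float = 0.0214
    n_surrogates: int = 199
    n_compounds: int = 106
    kd_units: str = "m"
    bands: dict = field(
        default_factory=lambda: {k: list(v) for k, v in synchrony.BANDS.items()}
    )
    couplings: dict = field(
        default_factory=lambda: {
            # defaults emulate the study's driver phase structure: positive
            # phase = DOC leads the driver (see synchrony module docstring)
            "deposition": {"band": [12, 24], "magnitude": 0.5, "phase": 1.35},
            "precipitation": {"band": [3, 6], "magnitude": 0.5, "phase": 1.91},
            "soil_wetness": {"band": [12, 24], "magnitude": 0.5, "phase": -1.31},
            "irradiance": {"band": [12, 24], "magnitude": 0.6, "phase": 3.06},
        }
    )
    constants: dict = field(default_factory=dict)  # PhotoConstants overrides
    light: dict = field(default_factory=dict)  # gen_solar_spectrum overrides
    outdir: str | None = None

    def photo_constants(self) -> PhotoConstants:
        return PhotoConstants(**self.constants)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def simulate_inputs(config: RunConfig) -> dict:
    """Generate every input table a run consumes (stage: simulate)."""
    s_lakes, s_chem, s_drv, s_kin, s_cmp, s_reg = _subseeds(config.seed, 6)
    lakes = synthio.gen_lakes(config.n_lakes, s_lakes)
    regional = (
        synthio.gen_regional_forcing(config.months, s_reg, sd=config.regional_sd)
        if config.regional_sd > 0
        else None
    )
    chem = [
        synthio.gen_chemistry(
            spec,
            start=config.start,
            months=config.months,
            seed=s_chem + i,
            seasonal_amp=config.seasonal_amp,
            noise_sd=config.noise_sd,
            missing_frac=config.missing_frac,
            color_months=int(config.months * config.color_fraction),
            regional=regional,
        )
        for i, spec in enumerate(lakes)
    ]
    mean_doc = pd.concat([c.series("doc") for c in chem], axis=1).mean(axis=1)
    mean_chem = synthio.MonthlyChemistrySeries(
        lake_id="__mean__", data=mean_doc.to_frame("doc")
    )
    couplings = {
        name: synthio.BandCoupling(tuple(c["band"]), c["magnitude"], c["phase"])
        for name, c in config.couplings.items()
    }
    drivers = synthio.gen_drivers(mean_chem, couplings, seed=s_drv)
    field_ = synthio.gen_solar_spectrum(**config.light)
    compounds = synthio.gen_compounds(config.n_compounds, seed=s_cmp)
    return {
        "lakes": lakes,
        "chemistry": chem,
        "drivers": drivers,
        "light_field": field_,
        "compounds": compounds,
        "kinetics_seed": s_kin,
    }


def stage_trends(sim: dict, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    tt = trends.trend_table(sim["chemistry"])
    clusters = trends.classify_browning(tt, seed=config.seed)
    return tt, clusters


def stage_synchrony(sim: dict, config: RunConfig) -> pd.DataFrame:
    """Coherence of per-lake DOC with color and with each regional driver.

    Color is paired lake-by-lake over the window where color was still
    collected; every external driver is paired with each lake's DOC.
    """
    pre_doc = [
        synchrony.preprocess(c.series("doc").to_numpy(), max_missing=0.25)
        for c in sim["chemistry"]
    ]
    pair_sets: dict[str, list] = {}

    def last_color_month(c) -> int:
        has = c.series("color").notna().to_numpy().nonzero()[0]
        return int(has.max()) + 1 if has.size else 0

    color_n = min(last_color_month(c) for c in sim["chemistry"])
    if color_n >= 48:
        pair_sets["color"] = [
            (
                synchrony.preprocess(
                    c.series("doc").to_numpy()[:color_n], max_missing=0.25
                ).values,
                synchrony.preprocess(
                    c.series("color").to_numpy()[:color_n], max_missing=0.25
                ).values,
            )
            for c in sim["chemistry"]
        ]
    for name in sim["drivers"].data.columns:
        y = synchrony.preprocess(sim["drivers"].data[name].to_numpy())
        pair_sets[name] = [(x.values, y.values) for x in pre_doc]

    rows = []
    for name, pairs in pair_sets.items():
        n_months = len(pairs[0][0])
        for band_name, band in config.bands.items():
            if band[1] > n_months / 2:
                warnings.warn(
                    f"band {band_name} {band} exceeds half the {name} record "
                    f"length ({n_months} months); skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            p, res = synchrony.band_significance(
                pairs, tuple(band), n_surrogates=config.n_surrogates, seed=config.seed
            )
            rows.append(
                {
                    "driver": name,
                    "band": band_name,
                    "band_lo": band[0],
                    "band_hi": band[1],
                    "magnitude": res.magnitude,
                    "mean_phase": res.mean_phase,
                    "phase_class": res.phase_class,
                    "p_band": p,
                }
            )
    return pd.DataFrame(rows)


def stage_quantum_yield(sim: dict, config: RunConfig) -> pd.DataFrame:
    """Simulated FFA photolysis and quantum-yield recovery per lake."""
    constants = config.photo_constants()
    lamp = synthio.gen_solar_spectrum(z_scale=2e-9, **config.light)
    rows = []
    for i, spec in enumerate(sim["lakes"]):
        sample_spec = synthio.gen_spectrum(a440=0.5 * spec.doc_baseline, s_slope=0.018)
        ra = photochem.rate_light_absorption(sample_spec, lamp)
        trace = synthio.gen_kinetics(
            spec.phi_true,
            ra,
            species="FFA",
            noise_cv=config.kinetics_noise_cv,
            seed=sim["kinetics_seed"] + i,
            constants=constants,
        )
        fit = photochem.fit_first_order(trace)
        qy = photochem.apparent_quantum_yield(
            fit.k_obs, ra, constants, phi_srnom=config.phi_srnom
        )
        rows.append(
            {
                "lake_id": spec.lake_id,
                "hydro_class": spec.hydro_class,
                "till_class": spec.till_class,
                "phi_true": spec.phi_true,
                "phi_app": qy.phi_app,
                "phi_ratio_srnom": qy.phi_ratio_srnom,
                "one_o2_ss_exp": qy.one_o2_ss_exp,
                "ra_vial": ra,
                "k_obs_ffa": fit.k_obs,
            }
        )
    return pd.DataFrame(rows)


def stage_steady_state(
    sim: dict, qy_table: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Field steady-state singlet oxygen per lake from the light-field model."""
    constants = config.photo_constants()
    field_ = sim["light_field"]
    rows = []
    for spec, (_, qrow) in zip(sim["lakes"], qy_table.iterrows()):
        doc = float(
            np.nanmean(
                next(c for c in sim["chemistry"] if c.lake_id == spec.lake_id)
                .series("doc")
                .to_numpy()
            )
        )
        lake = LakeOpticalModel.from_doc(doc, field_.wavelengths, kd_units=config.kd_units)
        ss = photochem.steady_state_1o2(qrow["phi_app"], field_, lake, constants)
        rows.append(
            {
                "lake_id": spec.lake_id,
                "doc_mean": doc,
                "tau_years": spec.tau_years,
                "z_euphotic_cm": lake.z_euphotic_cm,
                "c_euphotic": ss.c_euphotic,
                "c_near_surface": ss.c_near_surface,
                "ra_vol": ss.ra_vol,
                "depth_average_pct": 100.0 * ss.c_euphotic / ss.c_near_surface,
            }
        )
    return pd.DataFrame(rows)


def stage_screening(
    sim: dict, ss_table: pd.DataFrame, clusters: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster contaminant screening against lake flushing."""
    merged = ss_table.merge(clusters[["lake_id", "cluster"]], on="lake_id")
    rows = []
    for cluster_name, grp in merged.groupby("cluster"):
        for cmp_ in sim["compounds"]:
            per_lake = [
                photochem.screen_compounds([cmp_], row["c_euphotic"], row["tau_years"])[0]
                for _, row in grp.iterrows()
            ]
            mean_log = float(np.mean([r.log10_ratio for r in per_lake]))
            rows.append(
                {
                    "cluster": cluster_name,
                    "compound": cmp_.name,
                    "k_rxn": cmp_.k_rxn,
                    "mean_log10_ratio": mean_log,
                    "fate_class": photochem.classify_fate(mean_log),
                }
            )
    return pd.DataFrame(rows)


def stage_comparisons(
    qy_table: pd.DataFrame, clusters: pd.DataFrame
) -> pd.DataFrame:
    """Quantum-yield group comparisons by watershed class and cluster."""
    merged = qy_table.merge(clusters[["lake_id", "cluster"]], on="lake_id", how="left")
    rows = []
    for grouping in ("hydro_class", "till_class", "cluster"):
        sub = merged.dropna(subset=[grouping])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = compare_groups(
                    sub["phi_app"].to_numpy(), sub[grouping].to_numpy(), grouping=grouping
                )
        except InsufficientDataError:
            continue
        if not res.pairwise:
            rows.append({"grouping": grouping, "kw_p": res.kw_p, "group_a": None,
                         "group_b": None, "mw_p": None, "stars": None})
        for pw in res.pairwise:
            rows.append({"grouping": grouping, "kw_p": res.kw_p, "group_a": pw.group_a,
                         "group_b": pw.group_b, "mw_p": pw.mw_p, "stars": pw.stars})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on simulated inputs; optionally write CSV tables.

    Returns a dict of DataFrames plus a machine-readable manifest; writing
    is triggered by ``config.outdir``.  Deterministic: identical config and
    seed give identical tables and manifest hash.
    """
    sim = simulate_inputs(config)
    tt, clusters = stage_trends(sim, config)
    coh = stage_synchrony(sim, config)
    qy = stage_quantum_yield(sim, config)
    ss = stage_steady_state(sim, qy, config)
    screen = stage_screening(sim, ss, clusters)
    comparisons = stage_comparisons(qy, clusters)

    tables = {
        "trend_table": tt,
        "clusters": clusters,
        "coherence": coh,
        "quantum_yield": qy,
        "steady_state": ss,
        "screening": screen,
        "comparisons": comparisons,
    }
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "tables": {
            name: hashlib.sha256(
                df.to_csv(index=False, float_format="%.12g").encode()
            ).hexdigest()[:16]
            for name, df in tables.items()
        },
    }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"tables": tables, "manifest": manifest}
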