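"""G_T x G_M x M_P x site x year factorial runs and sensitivity scans.

The factorial crosses trait (non-LT against LT at a given hourly cap),
maturity group (short / medium / full season), planting date (May 01,
May 15, June 01), synthetic sites along the precipitation/VPD gradient and
years.  Paired trait runs share the same weather draw, soil and
management, so the LT effect is a within-pair contrast.  Failed seasons
are flagged, never dropped; yield summaries treat them as missing (with a
switch for zero imputation).

Water-stress environment labels (E_W) are attached by clustering the
non-LT waterSD trajectories (the envirotyping module); when too few
non-failed seasons are available for clustering, the generating weather
archetype is used as the label, which is exact by construction for
synthetic weather.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARCHETYPE_ORDER
from .cropmodel import Management, make_cultivar, run_season
from .envirotyping import (
    cluster_trajectories,
    name_environments,
    season_trajectory,
)
from .weathergen import SiteSpec, generate_gradient_sites, generate_season, make_soil, season_rain

logger = logging.getLogger(__name__)

MATURITIES = ("short", "medium", "full")
PLANTINGS = ("May-01", "May-15", "Jun-01")
_PLANTING_RANK = {p: i for i, p in enumerate(PLANTINGS)}
_MATURITY_RANK = {m: i for i, m in enumerate(MATURITIES)}


@dataclass(frozen=True)
class FactorialDesign:
    """The full crossing to enumerate, plus the master seed."""

    sites: tuple[SiteSpec, ...]
    n_years: int = 5
    caps: tuple[float, ...] = (0.9,)        # LT cap levels; non-LT always runs
    maturities: tuple[str, ...] = MATURITIES
    plantings: tuple[str, ...] = PLANTINGS
    master_seed: int = 0
    initial_fraction: float = 0.60
    label_by: str = "auto"                  # auto | cluster | archetype

    def weather_seed(self, site_id: int) -> int:
        # distinct, reproducible sub-seed per site; kept below 2^31
        return (self.master_seed * 131 + 10007 * site_id + 17) % (2**31 - 1)


def default_design(n_sites: int = 2, n_years: int = 5, master_seed: int = 0,
                   **kwargs) -> FactorialDesign:
    sites = tuple(generate_gradient_sites(max(n_sites, 2)))
    return FactorialDesign(sites=sites, n_years=n_years,
                           master_seed=master_seed, **kwargs)


def _trait_label(cap: float | None) -> str:
    return "nonLT" if cap is None else f"LT{cap:g}"


def run_factorial(design: FactorialDesign) -> pd.DataFrame:
    """Run the full crossing; one row per design cell x year x trait.

    Paired LT / non-LT rows share identical weather, soil initialisation
    and management.  An error inside one cell aborts only that cell (a
    logged diagnostic plus a failed row), never the batch.  The whole
    table is reproducible from the master seed.
    """
    rows: list[dict] = []
    trajectories: dict[str, object] = {}
    for site in design.sites:
        soil = make_soil(site.texture, site.depth_cm)
        for year in range(design.n_years):
            rng = np.random.default_rng(
                [design.master_seed, site.site_id, year, 0xFAC7])
            arch = site.draw_archetype(rng)
            weather = generate_season(
                arch, year_index=year, seed=design.weather_seed(site.site_id))
            rain = season_rain(weather)
            for maturity in design.maturities:
                for planting in design.plantings:
                    mgmt = Management(
                        sowing=planting, density=site.density,
                        initial_fraction=design.initial_fraction)
                    for cap in (None, *design.caps):
                        cultivar = make_cultivar(maturity, cap)
                        key = f"{site.site_id}/{year}/{maturity}/{planting}"
                        try:
                            res = run_season(weather, soil, cultivar, mgmt)
                        except Exception:
                            logger.exception("cell %s/%s failed", key, _trait_label(cap))
                            rows.append(dict(
                                site=site.site_id, site_name=site.name,
                                year=year, archetype=arch,
                                trait=_trait_label(cap), cap=cap,
                                maturity=maturity, planting=planting,
                                failed=True, fail_reason="simulator error",
                                season_rain=rain,
                            ))
                            continue
                        wp = (res.yield_mg_ha / res.total_transpiration
                              if not res.failed and res.total_transpiration > 0
                              else np.nan)
                        rows.append(dict(
                            site=site.site_id, site_name=site.name,
                            year=year, archetype=arch,
                            trait=_trait_label(cap), cap=cap,
                            maturity=maturity, planting=planting,
                            failed=res.failed, fail_reason=res.fail_reason,
                            anthesis_doy=res.anthesis_doy,
                            maturity_doy=res.maturity_doy,
                            grain_number=res.grain_number_m2,
                            dry_yield=res.dry_yield,
                            yield_mg_ha=res.yield_mg_ha,
                            total_transp=res.total_transpiration,
                            biomass_flowering=res.biomass_at_flowering,
                            transp_flowering=res.transp_at_flowering,
                            pasw_flowering=res.pasw_at_flowering,
                            water_productivity=wp,
                            season_rain=rain,
                        ))
                        if cap is None and not res.failed:
                            trajectories[key] = season_trajectory(res, key)
    table = pd.DataFrame(rows)
    return attach_env_labels(table, trajectories, design)


def attach_env_labels(table: pd.DataFrame, trajectories: dict,
                      design: FactorialDesign) -> pd.DataFrame:
    """Attach the E_W column by clustering non-LT trajectories.

    Falls back to the generating archetype when clustering is infeasible
    (too few non-failed seasons) or when the design requests it.
    """
    table = table.copy()
    mode = design.label_by
    if mode == "auto":
        mode = "cluster" if len(trajectories) >= 24 else "archetype"
    if mode == "archetype" or not trajectories:
        table["env"] = table["archetype"]
        return table
    trajs = list(trajectories.values())
    kmax = min(8, len(trajs) // 3, len(trajs) - 1)
    classification = name_environments(cluster_trajectories(
        trajs, range(2, kmax + 1), seed=design.master_seed))
    env_by_key = dict(zip(trajectories.keys(), classification.named_labels))
    keys = (table.site.astype(str) + "/" + table.year.astype(str) + "/"
            + table.maturity + "/" + table.planting)
    table["env"] = [env_by_key.get(k) for k in keys]
    # failed cells have no trajectory; fall back to the archetype label
    table["env"] = table["env"].fillna(table["archetype"])
    return table


# ---------------------------------------------------------------------------
# Relative change
# ---------------------------------------------------------------------------

PAIR_KEYS = ["site", "year", "maturity", "planting"]
OUTCOMES = ["yield_mg_ha", "total_transp", "water_productivity",
            "biomass_flowering", "pasw_flowering"]


def relative_change(
    table: pd.DataFrame,
    outcome: str = "yield_mg_ha",
    baseline: str = "nonLT",
) -> pd.DataFrame:
    """Per-pair percent change of each LT trait against the baseline.

    Pairs are matched on (site, year, maturity, planting).  Pairs whose
    baseline failed or is zero are excluded and counted in the
    ``excluded`` attribute of the returned frame.
    """
    base = table[table.trait == baseline].set_index(PAIR_KEYS)
    out_rows = []
    excluded = 0
    for trait, grp in table[table.trait != baseline].groupby("trait"):
        grp = grp.set_index(PAIR_KEYS)
        joined = grp.join(base, rsuffix="_base")
        for idx, row in joined.iterrows():
            b = row[f"{outcome}_base"]
            v = row[outcome]
            if row.failed or row.failed_base or not np.isfinite(b) or b == 0:
                excluded += 1
                continue
            out_rows.append(dict(
                zip(PAIR_KEYS, idx),
                trait=trait, cap=row.cap, env=row.env,
                archetype=row.archetype, baseline=b, value=v,
                pct_change=100.0 * (v - b) / b,
            ))
    result = pd.DataFrame(out_rows)
    result.attrs["excluded"] = excluded
    return result


def summarize_relative(pairs: pd.DataFrame,
                       by: list[str] = ["env"]) -> pd.DataFrame:
    """Mean / sd / n of percent change grouped by the given columns."""
    if pairs.empty:
        return pd.DataFrame(columns=by + ["mean_pct", "sd_pct", "n"])
    g = pairs.groupby(by)["pct_change"]
    out = g.agg(mean_pct="mean", sd_pct="std", n="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# Sensitivity scans
# ---------------------------------------------------------------------------


def sensitivity_initial_moisture(
    site: SiteSpec,
    levels: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_years: int = 10,
    cap: float = 0.9,
    maturity: str = "short",
    planting: str = "May-15",
    master_seed: int = 0,
) -> pd.DataFrame:
    """Relative LT yield change across initial soil moisture levels.

    LT stays at the given cap while the January-1 initial available-water
    fraction scans the levels; each level reports the across-year mean and
    sd of the paired percent yield change.
    """
    if any(not 0.0 <= l <= 1.0 for l in levels):
        raise ValueError("moisture levels must lie in [0, 1]")
    soil = make_soil(site.texture, site.depth_cm)
    rows = []
    for level in levels:
        changes = []
        for year in range(n_years):
            rng = np.random.default_rng([master_seed, site.site_id, year, 0xFAC7])
            arch = site.draw_archetype(rng)
            weather = generate_season(arch, year_index=year,
                                      seed=(master_seed * 131 + 10007 * site.site_id + 17) % (2**31 - 1))
            mgmt = Management(sowing=planting, density=site.density,
                              initial_fraction=level)
            base = run_season(weather, soil, make_cultivar(maturity, None), mgmt)
            lt = run_season(weather, soil, make_cultivar(maturity, cap), mgmt)
            if base.failed or lt.failed or not np.isfinite(base.yield_mg_ha) \
                    or base.yield_mg_ha == 0:
                continue
            changes.append(100.0 * (lt.yield_mg_ha - base.yield_mg_ha)
                           / base.yield_mg_ha)
        rows.append(dict(
            initial_fraction=level,
            mean_pct=float(np.mean(changes)) if changes else np.nan,
            sd_pct=float(np.std(changes, ddof=1)) if len(changes) > 1 else np.nan,
            n=len(changes),
        ))
    return pd.DataFrame(rows)


def sensitivity_lt_threshold(
    archetypes: tuple[str, ...] = ARCHETYPE_ORDER,
    caps: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_years: int = 10,
    initial_fraction: float = 0.60,
    texture: str = "sandy loam",
    depth_cm: float = 150.0,
    density: float = 8.0,
    maturity: str = "short",
    planting: str = "May-15",
    master_seed: int = 0,
) -> pd.DataFrame:
    """Relative LT yield change per cap per environment class.

    Years are drawn from each archetype in turn (so every class is
    represented), initial moisture stays fixed, and each (cap, class) cell
    reports the across-year mean and sd of the paired percent change.
    """
    if any(not 0.2 <= c <= 0.9 for c in caps):
        raise ValueError("caps must lie in [0.2, 0.9]")
    soil = make_soil(texture, depth_cm)
    mgmt = Management(sowing=planting, density=density,
                      initial_fraction=initial_fraction)
    changes: dict[tuple[float, str], list[float]] = {
        (c, a): [] for c in caps for a in archetypes}
    for arch in archetypes:
        for year in range(n_years):
            weather = generate_season(arch, year_index=year, seed=master_seed)
            base = run_season(weather, soil, make_cultivar(maturity, None), mgmt)
            if base.failed or not np.isfinite(base.yield_mg_ha) \
                    or base.yield_mg_ha == 0:
                continue
            for cap in caps:
                lt = run_season(weather, soil, make_cultivar(maturity, cap), mgmt)
                if lt.failed:
                    continue
                changes[(cap, arch)].append(
                    100.0 * (lt.yield_mg_ha - base.yield_mg_ha) / base.yield_mg_ha)
    rows = []
    for (cap, arch), vals in changes.items():
        rows.append(dict(
            cap=cap, env=arch,
            mean_pct=float(np.mean(vals)) if vals else np.nan,
            sd_pct=float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            n=len(vals),
        ))
    return pd.DataFrame(rows).sort_values(["env", "cap"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Best G_M x M_P combination
# ---------------------------------------------------------------------------


def best_combination(
    table: pd.DataFrame,
    impute_failed_zero: bool = False,
) -> pd.DataFrame:
    """Per site and trait, the (maturity, planting) cell with top mean yield.

    Failed seasons are treated as missing by default (the usual
    convention), or imputed as zero yield with the switch.  Ties break
    toward earlier planting, then shorter maturity.  Sites where every
    cell failed are flagged.
    """
    t = table.copy()
    if impute_failed_zero:
        t.loc[t.failed, "yield_mg_ha"] = 0.0
    else:
        t = t[~t.failed]
    rows = []
    for (site, trait), grp in table.groupby(["site", "trait"]):
        sub = t[(t.site == site) & (t.trait == trait)]
        if sub.empty or sub.yield_mg_ha.isna().all():
            rows.append(dict(site=site, trait=trait, maturity=None,
                             planting=None, mean_yield=np.nan, all_failed=True))
            continue
        means = sub.groupby(["maturity", "planting"])["yield_mg_ha"].mean()
        best = min(
            means.items(),
            key=lambda kv: (-round(kv[1], 12), _PLANTING_RANK[kv[0][1]],
                            _MATURITY_RANK[kv[0][0]]),
        )
        rows.append(dict(site=site, trait=trait, maturity=best[0][0],
                         planting=best[0][1], mean_yield=float(best[1]),
                         all_failed=False))
    return pd.DataFrame(rows)


__all__ = [
    "FactorialDesign", "default_design", "run_factorial", "attach_env_labels",
    "relative_change", "summarize_relative", "sensitivity_initial_moisture",
    "sensitivity_lt_threshold", "best_combination",
    "MATURITIES", "PLANTINGS", "OUTCOMES", "PAIR_KEYS",
]
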