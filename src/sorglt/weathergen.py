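"""Synthetic weather, site and soil generation for the US sorghum belt.

The generator emulates the statistical structure of the study system rather
than any particular station: four seasonal water-deficit archetypes (WW, LD,
MD, ED) whose mean May-October precipitation is calibrated to 400 / 300 /
244 / 230 mm, an east-to-west gradient of declining precipitation and rising
VPD across sites, and a pedotransfer lookup that turns a texture class into
a layered soil profile.

Rain occurrence is a first-order two-state Markov chain with monthly
parameters; intensity on wet days is gamma distributed.  Each archetype
carries a drought window (a fraction-of-season interval during which wet-day
probabilities are multiplied by a suppression factor), which is what makes
LD / MD / ED dry spells land late / mid / early in the season.  The gamma
intensity mean is calibrated analytically: the exact day-by-day expectation
of the Markov wet state is propagated through the year and the intensity is
scaled so the expected May-October total equals the archetype target.

All dates use a 365-day no-leap calendar, the usual climate-modelling
convention, so every season is exactly 365 days long.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    ARCHETYPES,
    ARCHETYPE_ORDER,
    ArchetypeParams,
    KL_BY_THIRD,
    SEASON_END_DOY,
    SEASON_RAIN_TARGETS,
    SEASON_START_DOY,
    TEXTURE_TABLE,
)
from .soilwater import SoilLayer, SoilProfile

# ---------------------------------------------------------------------------
# No-leap calendar helpers
# ---------------------------------------------------------------------------

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_START_DOY = np.concatenate([[1], 1 + np.cumsum(_MONTH_LENGTHS)])[:12]


def doy_to_month(doy: np.ndarray | int) -> np.ndarray | int:
    """Month (1-12) of a no-leap day-of-year (1-365)."""
    return np.searchsorted(_MONTH_START_DOY, np.asarray(doy), side="right")


def doy_to_month_day(doy: int) -> tuple[int, int]:
    month = int(doy_to_month(doy))
    return month, int(doy - _MONTH_START_DOY[month - 1] + 1)


def month_day_to_doy(month: int, day: int) -> int:
    if month == 2 and day == 29:
        raise WeatherValidationError("Feb 29 is not representable (no-leap calendar)")
    return int(_MONTH_START_DOY[month - 1] + day - 1)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

WEATHER_COLUMNS = ["year", "doy", "tmax", "tmin", "radn", "rain"]


class WeatherValidationError(ValueError):
    """A weather series violates its physical or structural invariants."""


class ConfigurationError(ValueError):
    """An archetype or site specification is invalid."""


def validate_weather(series: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a weather series; return it unchanged if valid.

    Raises :class:`WeatherValidationError` naming the first offending row.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in series.columns]
    if missing:
        raise WeatherValidationError(f"missing weather columns: {missing}")
    bad = series.index[series.tmax < series.tmin]
    if len(bad):
        i = bad[0]
        raise WeatherValidationError(
            f"tmax < tmin at year {series.at[i, 'year']:.0f} doy {series.at[i, 'doy']:.0f}"
        )
    for col in ("radn", "rain"):
        bad = series.index[series[col] < 0]
        if len(bad):
            i = bad[0]
            raise WeatherValidationError(
                f"negative {col} at year {series.at[i, 'year']:.0f} doy {series.at[i, 'doy']:.0f}"
            )
    years = series["year"].to_numpy()
    doys = series["doy"].to_numpy()
    for j in range(1, len(series)):
        same_year = years[j] == years[j - 1] and doys[j] == doys[j - 1] + 1
        rollover = years[j] == years[j - 1] + 1 and doys[j - 1] == 365 and doys[j] == 1
        if not (same_year or rollover):
            raise WeatherValidationError(
                f"non-contiguous dates: year {years[j-1]:.0f} doy {doys[j-1]:.0f} "
                f"followed by year {years[j]:.0f} doy {doys[j]:.0f}"
            )
    return series


def _validate_archetype(arch: ArchetypeParams) -> None:
    for name, probs in (("p01", arch.p01), ("p11", arch.p11)):
        if len(probs) != 12:
            raise ConfigurationError(f"{arch.name}: {name} needs 12 monthly values")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError(f"{arch.name}: {name} outside [0, 1]")
    if not 0.0 <= arch.drought_factor <= 1.0:
        raise ConfigurationError(f"{arch.name}: drought_factor outside [0, 1]")


# ---------------------------------------------------------------------------
# Occurrence schedule and analytic calibration
# ---------------------------------------------------------------------------

_DOYS = np.arange(1, 366)
_SEASON_LEN = SEASON_END_DOY - SEASON_START_DOY  # 183


def _daily_occurrence(arch: ArchetypeParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-day (p01, p11) after applying the archetype's drought window."""
    months = doy_to_month(_DOYS)
    p01 = np.asarray(arch.p01)[months - 1].astype(float)
    p11 = np.asarray(arch.p11)[months - 1].astype(float)
    p01 = np.minimum(0.90, p01 * arch.occurrence_scale)
    p11 = np.minimum(0.95, p11 * arch.occurrence_scale)
    frac = (_DOYS - SEASON_START_DOY) / _SEASON_LEN
    lo, hi = arch.drought_window
    in_window = (frac >= lo) & (frac <= hi) & (frac >= 0) & (frac <= 1)
    p01[in_window] *= arch.drought_factor
    p11[in_window] *= arch.drought_factor
    return p01, p11


@lru_cache(maxsize=32)
def _calibrated_intensity(arch: ArchetypeParams) -> float:
    """Gamma intensity mean (mm) making E[May-Oct rain] hit the target.

    The expected wet-state probability is propagated exactly through the
    Markov chain; the expected seasonal total with unit intensity is then
    the sum of wet probabilities over May-Oct.
    """
    _validate_archetype(arch)
    p01, p11 = _daily_occurrence(arch)
    p_wet = np.empty(365)
    p0 = p01[0] / max(1e-12, 1.0 + p01[0] - p11[0])  # January stationary start
    for d in range(365):
        p0 = p0 * p11[d] + (1.0 - p0) * p01[d]
        p_wet[d] = p0
    in_season = (_DOYS >= SEASON_START_DOY) & (_DOYS <= SEASON_END_DOY)
    expected_wet_days = float(p_wet[in_season].sum())
    target = SEASON_RAIN_TARGETS.get(arch.name)
    if target is None or expected_wet_days <= 0:
        return arch.rain_mean_mm
    return target / expected_wet_days


def expected_season_rain(arch: ArchetypeParams) -> float:
    """Analytic expected May-Oct precipitation (mm) for an archetype."""
    p01, p11 = _daily_occurrence(arch)
    mean = _calibrated_intensity(arch)
    p_wet = np.empty(365)
    p0 = p01[0] / max(1e-12, 1.0 + p01[0] - p11[0])
    for d in range(365):
        p0 = p0 * p11[d] + (1.0 - p0) * p01[d]
        p_wet[d] = p0
    in_season = (_DOYS >= SEASON_START_DOY) & (_DOYS <= SEASON_END_DOY)
    return float(p_wet[in_season].sum() * mean)


# ---------------------------------------------------------------------------
# Season generation
# ---------------------------------------------------------------------------

_ARCH_INDEX = {name: i for i, name in enumerate(ARCHETYPE_ORDER)}
_TMEAN_PEAK_DOY = 201  # warmest day, ~July 20


def generate_season(
    arch: ArchetypeParams | str,
    year_index: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate one 365-day synthetic weather season.

    Reproducible: identical ``(archetype, year_index, seed)`` give a
    bit-identical series.  The returned frame has columns
    ``year, doy, tmax, tmin, radn, rain``.
    """
    if isinstance(arch, str):
        arch = ARCHETYPES[arch]
    _validate_archetype(arch)
    rng = np.random.default_rng(
        [seed, year_index, _ARCH_INDEX.get(arch.name, 99), 0x5EA50])

    p01, p11 = _daily_occurrence(arch)
    u = rng.random(365)
    wet = np.zeros(365, dtype=bool)
    prev = u[0] < p01[0] / max(1e-12, 1.0 + p01[0] - p11[0])
    for d in range(365):
        p = p11[d] if prev else p01[d]
        prev = u[d] < p
        wet[d] = prev

    mean = _calibrated_intensity(arch)
    shape = arch.rain_shape
    rain = np.zeros(365)
    n_wet = int(wet.sum())
    if n_wet and mean > 0:
        rain[wet] = rng.gamma(shape, mean / shape, size=n_wet)

    tmean = (arch.temp_mean
             + arch.temp_amplitude * np.cos(2 * np.pi * (_DOYS - _TMEAN_PEAK_DOY) / 365)
             + rng.normal(0.0, arch.temp_noise_sd, 365))
    dr = np.where(wet, 0.8 * arch.diurnal_range, arch.diurnal_range)
    tmax = tmean + dr / 2
    tmin = tmean - dr / 2

    radn = (arch.radn_mean
            + arch.radn_amplitude * np.cos(2 * np.pi * (_DOYS - 172) / 365))
    radn = np.where(wet, radn * arch.wet_radn_factor, radn)
    radn = np.maximum(radn, 0.1)

    series = pd.DataFrame({
        "year": np.full(365, 2001 + year_index, dtype=int),
        "doy": _DOYS,
        "tmax": tmax,
        "tmin": tmin,
        "radn": radn,
        "rain": rain,
    })
    return validate_weather(series)


def season_rain(series: pd.DataFrame) -> float:
    """Total May-Oct precipitation (mm) of a season."""
    m = (series.doy >= SEASON_START_DOY) & (series.doy <= SEASON_END_DOY)
    return float(series.loc[m, "rain"].sum())


# ---------------------------------------------------------------------------
# Sites along the east-west gradient
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSpec:
    """A synthetic site: archetype mixture, soil texture and plant density.

    ``weights`` gives the long-run frequency of each archetype
    (WW, LD, MD, ED order) across years at the site.  Sites further west
    have drier mixtures, coarser soils and lower recommended density.
    """

    site_id: int
    name: str
    weights: tuple[float, float, float, float]
    texture: str
    depth_cm: float
    density: float   # plants m^-2

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError(f"site {self.site_id}: weights must sum to 1")
        if not 6.0 <= self.density <= 17.0:
            raise ConfigurationError(f"site {self.site_id}: density outside [6, 17]")

    def draw_archetype(self, rng: np.random.Generator) -> str:
        return ARCHETYPE_ORDER[rng.choice(4, p=np.asarray(self.weights))]


# Endpoint mixtures of the gradient (WW, LD, MD, ED).
_EAST_WEIGHTS = np.array([0.55, 0.25, 0.12, 0.08])
_WEST_WEIGHTS = np.array([0.08, 0.17, 0.30, 0.45])
_GRADIENT_TEXTURES = ["silty clay loam", "clay loam", "loam", "silty loam", "sandy loam"]


def generate_gradient_sites(n_sites: int, seed: int = 0) -> list[SiteSpec]:
    """Sites spanning the east (wet, low VPD) to west (dry, high VPD) gradient.

    Archetype mixtures interpolate linearly from WW/LD-dominated in the east
    (site 0) to MD/ED-dominated in the west; plant density declines from 14
    to 6 plants m^-2 with the drying trend.  Deterministic given
    ``n_sites`` (``seed`` is accepted for interface symmetry).
    """
    if n_sites < 2:
        raise ConfigurationError("need at least 2 sites for a gradient")
    sites = []
    for i in range(n_sites):
        t = i / (n_sites - 1)
        w = (1 - t) * _EAST_WEIGHTS + t * _WEST_WEIGHTS
        w = w / w.sum()
        texture = _GRADIENT_TEXTURES[min(int(t * len(_GRADIENT_TEXTURES)),
                                         len(_GRADIENT_TEXTURES) - 1)]
        density = round(14.0 - 8.0 * t)
        sites.append(SiteSpec(
            site_id=i,
            name=f"site{i:02d}",
            weights=tuple(w),
            texture=texture,
            depth_cm=200.0 - 50.0 * t,
            density=float(density),
        ))
    return sites


# ---------------------------------------------------------------------------
# Pedotransfer: texture class -> layered soil profile
# ---------------------------------------------------------------------------


def make_soil(texture_class: str, depth_cm: float = 180.0) -> SoilProfile:
    """Build a layered soil profile from a texture class.

    Layer limits come from a fixed pedotransfer lookup per texture class;
    kl (the daily extractable fraction) decays with depth as 0.07 / 0.05 /
    0.03 over the top / middle / bottom thirds of the profile.  Layer
    thicknesses are 150 mm near the surface and 300 mm below, with the last
    layer trimmed so the total equals ``depth_cm``.
    """
    key = texture_class.strip().lower()
    if key not in TEXTURE_TABLE:
        known = ", ".join(sorted(TEXTURE_TABLE))
        raise KeyError(f"unknown texture class {texture_class!r}; known: {known}")
    ll15, dul, sat = TEXTURE_TABLE[key]
    depth_mm = depth_cm * 10.0

    thicknesses: list[float] = []
    remaining = depth_mm
    while remaining > 1e-9:
        t = 150.0 if len(thicknesses) < 2 else 300.0
        t = min(t, remaining)
        thicknesses.append(t)
        remaining -= t

    layers = []
    top = 0.0
    for t in thicknesses:
        mid = top + t / 2
        third = min(int(3 * mid / depth_mm), 2)
        layers.append(SoilLayer(
            thickness=t, ll15=ll15, dul=dul, sat=sat,
            kl=KL_BY_THIRD[third], sw=ll15,
        ))
        top += t
    return SoilProfile(layers=layers)


# ---------------------------------------------------------------------------
# Weather file I/O (CSV and APSIM-.met-style dialects)
# ---------------------------------------------------------------------------

_MET_HEADER = "[weather.met.weather]"


def write_weather(series: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    """Write a weather series as CSV (``date,tmax,tmin,radn,rain``) or .met."""
    validate_weather(series)
    path = Path(path)
    if dialect == "csv":
        out = series.copy()
        dates = [
            f"{int(y):04d}-{m:02d}-{d:02d}"
            for y, (m, d) in zip(out.year, (doy_to_month_day(int(x)) for x in out.doy))
        ]
        out.insert(0, "date", dates)
        out[["date", "tmax", "tmin", "radn", "rain"]].to_csv(
            path, index=False, float_format="%.6f")
    elif dialect == "met":
        with open(path, "w") as fh:
            fh.write(f"{_MET_HEADER}\n")
            fh.write("latitude = 38.0  (DECIMAL DEGREES)\n")
            fh.write("year day radn maxt mint rain\n")
            fh.write("() () (MJ/m2) (oC) (oC) (mm)\n")
            for row in series.itertuples(index=False):
                fh.write(f"{int(row.year)} {int(row.doy)} {row.radn:.6f} "
                         f"{row.tmax:.6f} {row.tmin:.6f} {row.rain:.6f}\n")
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")


def read_weather(path: str | Path, dialect: str = "csv") -> pd.DataFrame:
    """Read a weather series written by :func:`write_weather`; validates."""
    path = Path(path)
    if dialect == "csv":
        raw = pd.read_csv(path)
        required = {"date", "tmax", "tmin", "radn", "rain"}
        missing = required - set(raw.columns)
        if missing:
            raise WeatherValidationError(f"missing weather columns: {sorted(missing)}")
        years, doys = [], []
        for s in raw["date"].astype(str):
            y, m, d = (int(x) for x in s.split("-"))
            years.append(y)
            doys.append(month_day_to_doy(m, d))
        series = pd.DataFrame({
            "year": years, "doy": doys,
            "tmax": raw.tmax, "tmin": raw.tmin,
            "radn": raw.radn, "rain": raw.rain,
        })
    elif dialect == "met":
        lines = Path(path).read_text().splitlines()
        try:
            start = next(i for i, l in enumerate(lines)
                         if l.strip().startswith("year"))
        except StopIteration:
            raise WeatherValidationError("no 'year day ...' header in met file")
        cols = lines[start].split()
        body = "\n".join(l for l in lines[start + 2:] if l.strip())
        raw = pd.read_csv(io.StringIO(body), sep=r"\s+", names=cols)
        series = pd.DataFrame({
            "year": raw.year.astype(int), "doy": raw.day.astype(int),
            "tmax": raw.maxt, "tmin": raw.mint,
            "radn": raw.radn, "rain": raw.rain,
        })
    else:
        raise ValueError(f"unknown weather dialect {dialect!r}")
    return validate_weather(series.reset_index(drop=True))


__all__ = [
    "ArchetypeParams", "SiteSpec", "WeatherValidationError", "ConfigurationError",
    "generate_season", "generate_gradient_sites", "make_soil",
    "read_weather", "write_weather", "validate_weather",
    "season_rain", "expected_season_rain",
    "doy_to_month", "doy_to_month_day", "month_day_to_doy", "WEATHER_COLUMNS",
]
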