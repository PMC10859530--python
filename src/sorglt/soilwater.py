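"""Layered tipping-bucket soil water balance.

The profile is a stack of layers, each with wilting point (LL15), drained
upper limit (DUL) and saturation (SAT) as volumetric fractions, a daily
extraction coefficient kl, and a current water content sw.  Water moves by
the usual tipping-bucket rules: rain is split into runoff and infiltration
by a threshold-excess rule, infiltration fills layers top-down with
immediate cascade of above-saturation excess, water above DUL drains
downward at a fixed daily coefficient, the surface layer loses water to
two-stage (energy- then diffusion-limited) soil evaporation shaded by the
canopy, and the crop extracts transpiration from rooted layers in
proportion to their kl-weighted available water.

Every flux is logged in a :class:`WaterFluxLedger` so that daily and
season-long conservation can be asserted to numerical precision.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SOIL, SoilParams


@dataclass
class SoilLayer:
    """One soil layer; water contents are volumetric fractions."""

    thickness: float  # mm
    ll15: float
    dul: float
    sat: float
    kl: float         # fraction of available water extractable per day
    sw: float

    def __post_init__(self):
        if not 0.0 < self.ll15 < self.dul < self.sat < 1.0:
            raise ValueError(
                f"need 0 < ll15 < dul < sat < 1, got "
                f"{self.ll15}/{self.dul}/{self.sat}")
        if not 0.0 < self.kl <= 0.12:
            raise ValueError(f"kl must be in (0, 0.12], got {self.kl}")
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")

    @property
    def water_mm(self) -> float:
        return self.sw * self.thickness

    @property
    def available_mm(self) -> float:
        return max(0.0, (self.sw - self.ll15) * self.thickness)


@dataclass
class SoilProfile:
    """Ordered layers (surface first) plus the balance coefficients."""

    layers: list[SoilLayer]
    params: SoilParams = field(default_factory=lambda: SOIL)
    # two-stage evaporation state
    cum_evap: float = 0.0        # mm evaporated since last rewetting
    stage2_days: float = 0.0     # days since stage II began

    def __post_init__(self):
        if not self.layers:
            raise ValueError("profile needs at least one layer")

    def copy(self) -> "SoilProfile":
        return copy.deepcopy(self)

    @property
    def depth_mm(self) -> float:
        return sum(l.thickness for l in self.layers)

    def water_mm(self) -> float:
        return sum(l.water_mm for l in self.layers)

    def available_mm(self, root_depth: float | None = None) -> float:
        """Plant-available water (mm) above LL15, optionally to root depth."""
        if root_depth is None:
            return sum(l.available_mm for l in self.layers)
        total, top = 0.0, 0.0
        for l in self.layers:
            frac = _rooted_fraction(top, l.thickness, root_depth)
            total += l.available_mm * frac
            top += l.thickness
        return total

    def pawc_mm(self) -> float:
        """Plant-available water capacity, sum of (DUL-LL15)*thickness."""
        return sum((l.dul - l.ll15) * l.thickness for l in self.layers)

    @property
    def air_dry(self) -> float:
        return self.params.air_dry_fraction * self.layers[0].ll15


def _rooted_fraction(layer_top: float, thickness: float, root_depth: float) -> float:
    return min(max(root_depth - layer_top, 0.0), thickness) / thickness


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def initialize_moisture(profile: SoilProfile, fraction_available: float) -> SoilProfile:
    """Set every layer to ll15 + fraction * (dul - ll15); returns the profile."""
    if not 0.0 <= fraction_available <= 1.0:
        raise ValueError(f"fraction_available must be in [0, 1], got {fraction_available}")
    for l in profile.layers:
        l.sw = l.ll15 + fraction_available * (l.dul - l.ll15)
    profile.cum_evap = 0.0
    profile.stage2_days = 0.0
    return profile


def partition_rain(profile: SoilProfile, rain: float) -> tuple[float, float]:
    """Split rain into (runoff, infiltration) by the threshold-excess rule."""
    if rain < 0:
        raise ValueError("rain must be non-negative")
    p = profile.params
    runoff = p.runoff_fraction * max(0.0, rain - p.runoff_threshold)
    return runoff, rain - runoff


def infiltrate(profile: SoilProfile, infiltration: float) -> float:
    """Add infiltration to the surface layer, cascading above-SAT excess.

    Returns water leaving the profile bottom (instant deep drainage of
    saturation excess, usually 0).
    """
    if infiltration >= profile.params.rewet_threshold:
        profile.cum_evap = 0.0
        profile.stage2_days = 0.0
    moving = infiltration
    for l in profile.layers:
        if moving <= 0:
            break
        room = (l.sat - l.sw) * l.thickness
        taken = min(moving, room)
        l.sw += taken / l.thickness
        moving -= taken
    return moving


def drain_cascade(profile: SoilProfile) -> float:
    """Move above-DUL water downward; returns deep drainage (mm).

    Each layer, top-down, sheds ``drainage_coeff`` of its water above DUL to
    the layer below; water that would push a receiving layer above SAT keeps
    moving down immediately.  Excess leaving the bottom layer is deep
    drainage.
    """
    coeff = profile.params.drainage_coeff
    moving = 0.0
    for l in profile.layers:
        # receive flux from above, shedding above-SAT excess onward
        room = (l.sat - l.sw) * l.thickness
        taken = min(moving, room)
        l.sw += taken / l.thickness
        moving -= taken
        # this layer's own drainage
        flux = coeff * max(0.0, (l.sw - l.dul)) * l.thickness
        l.sw -= flux / l.thickness
        moving += flux
    return moving


def soil_evaporation(profile: SoilProfile, radn: float, lai: float) -> float:
    """Two-stage evaporation from the surface layer, shaded by the canopy.

    Stage I (until ``evap_u`` mm have evaporated since the last wetting) is
    energy-limited; stage II follows the square-root-of-time law with
    coefficient ``evap_cona``.  The surface layer is never drawn below the
    air-dry limit.
    """
    p = profile.params
    top = profile.layers[0]
    potential = p.evap_alpha * radn / p.latent_heat * math.exp(-p.evap_shade_k * lai)
    if profile.cum_evap < p.evap_u:
        e = min(potential, p.evap_u - profile.cum_evap)
    else:
        t = profile.stage2_days
        e = min(potential, p.evap_cona * (math.sqrt(t + 1.0) - math.sqrt(t)))
        profile.stage2_days += 1.0
    e = min(e, max(0.0, (top.sw - profile.air_dry) * top.thickness))
    top.sw -= e / top.thickness
    profile.cum_evap += e
    return e


def potential_supply(profile: SoilProfile, root_depth: float) -> float:
    """Potential daily water uptake (mm): sum of kl-limited available water.

    Each rooted layer contributes kl * (sw - ll15) * thickness, the deepest
    partially rooted layer pro-rata by the rooted fraction.
    """
    if root_depth < 0:
        raise ValueError("root_depth must be non-negative")
    total, top = 0.0, 0.0
    for l in profile.layers:
        frac = _rooted_fraction(top, l.thickness, root_depth)
        if frac > 0:
            total += l.kl * max(0.0, l.sw - l.ll15) * l.thickness * frac
        top += l.thickness
    return total


def extract_transpiration(
    profile: SoilProfile, demand_actual: float, root_depth: float
) -> float:
    """Remove ``demand_actual`` mm from rooted layers pro-rata to supply.

    Raises if demand exceeds the potential supply (the crop model must have
    limited demand first).  Returns the amount extracted.
    """
    if demand_actual < 0:
        raise ValueError("demand must be non-negative")
    if demand_actual == 0.0:
        return 0.0
    supplies, tops = [], []
    top = 0.0
    for l in profile.layers:
        frac = _rooted_fraction(top, l.thickness, root_depth)
        supplies.append(l.kl * max(0.0, l.sw - l.ll15) * l.thickness * frac)
        top += l.thickness
    total = sum(supplies)
    if demand_actual > total + 1e-9:
        raise ValueError(
            f"transpiration demand {demand_actual:.6f} mm exceeds supply {total:.6f} mm")
    scale = demand_actual / total
    for l, s in zip(profile.layers, supplies):
        l.sw -= s * scale / l.thickness
    return demand_actual


# ---------------------------------------------------------------------------
# Conservation ledger
# ---------------------------------------------------------------------------


class WaterFluxLedger:
    """Daily water fluxes (mm) with a conservation check."""

    COLUMNS = ["doy", "rain", "runoff", "infiltration", "drainage",
               "evaporation", "transpiration", "delta_storage"]

    def __init__(self):
        self._rows: list[dict] = []

    def record(self, doy: int, rain: float, runoff: float, infiltration: float,
               drainage: float, evaporation: float, transpiration: float,
               delta_storage: float) -> None:
        self._rows.append(dict(zip(self.COLUMNS, (
            doy, rain, runoff, infiltration, drainage,
            evaporation, transpiration, delta_storage))))

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)

    def residuals(self) -> np.ndarray:
        f = self.frame
        return (f.rain - f.runoff - f.drainage - f.evaporation
                - f.transpiration - f.delta_storage).to_numpy()

    def max_residual(self) -> float:
        r = self.residuals()
        return float(np.abs(r).max()) if len(r) else 0.0

    def check_closure(self, tol: float = 1e-6) -> None:
        worst = self.max_residual()
        if worst > tol:
            raise AssertionError(f"water balance residual {worst:.3e} mm exceeds {tol}")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def read_soil_profile(path) -> SoilProfile:
    """Read a soil profile CSV with columns thickness_mm,ll15,dul,sat,kl."""
    raw = pd.read_csv(path)
    required = {"thickness_mm", "ll15", "dul", "sat", "kl"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"missing soil columns: {sorted(missing)}")
    layers = [
        SoilLayer(thickness=r.thickness_mm, ll15=r.ll15, dul=r.dul,
                  sat=r.sat, kl=r.kl, sw=r.ll15)
        for r in raw.itertuples(index=False)
    ]
    return SoilProfile(layers=layers)


def write_soil_profile(profile: SoilProfile, path) -> None:
    pd.DataFrame({
        "thickness_mm": [l.thickness for l in profile.layers],
        "ll15": [l.ll15 for l in profile.layers],
        "dul": [l.dul for l in profile.layers],
        "sat": [l.sat for l in profile.layers],
        "kl": [l.kl for l in profile.layers],
    }).to_csv(path, index=False)


__all__ = [
    "SoilLayer", "SoilProfile", "WaterFluxLedger",
    "initialize_moisture", "partition_rain", "infiltrate", "drain_cascade",
    "soil_evaporation", "potential_supply", "extract_transpiration",
    "read_soil_profile", "write_soil_profile",
]
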