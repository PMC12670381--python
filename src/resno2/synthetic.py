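"""Synthetic housing, geography, and behavior inputs for the full pipeline.

The real analysis draws on national housing-stock, census, and outdoor
air-quality databases. This module generates statistically analogous
stand-ins so the pipeline runs end-to-end with no external data:

* a ZIP-level table (population, density, annual-mean outdoor NO2,
  gas-stove prevalence, housing-stock mix, climate band) whose marginals
  match the national anchors — outdoor NO2 right-skewed with median
  ≈ 4.9 ppbv and mean ≈ 7.7 ppbv, gas-stove share ≈ 40%, and denser ZIPs
  receiving both higher outdoor NO2 (level-vs-log-density r² ≈ 0.2) and
  more multifamily/small-floor-area housing;
* a floorplan library (default 24 plans) spanning home types, floor-area
  classes, stories, and forced-air presence, with envelope leakage and
  window elements calibrated to whole-dwelling air-exchange anchors of
  ≈0 h⁻¹ (closed windows, calm, no ΔT) up to ≈6 h⁻¹ (windows open,
  −5 °C out, 10 m/s wind);
* behavioral samplers: kitchen-occupancy minutes with 5th/50th/95th
  percentiles near 5/35/150 min/day (a split lognormal, since the
  percentile anchors are asymmetric on the log scale) and hood-not-used
  probabilities of 0.64 for houses and 0.72 for apartments.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import HousingCell, ZipInputs
from .multizone import (
    FLOOR_AREA_CLASSES,
    HOME_TYPES,
    FlowPath,
    Floorplan,
    OUTDOORS,
    Zone,
)

#: Air-exchange calibration anchors (whole dwelling, h⁻¹).
AER_WINDOWS_OPEN_EXTREME = 6.0   # windows open, ΔT = 25 K, wind 10 m/s
EXTREME_DRIVER_WIND = 10.0       # m/s
EXTREME_DRIVER_DT = 25.0         # K

CEILING_HEIGHT_M = 2.5
FT2_TO_M2 = 0.09290304


class SyntheticError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Targets and sizes for the synthetic generators."""

    n_zips: int = 1000
    seed: int = 0
    outdoor_no2_median: float = 4.9   # ppbv
    outdoor_no2_mean: float = 7.7     # ppbv
    gas_fraction_mean: float = 0.40
    gas_fraction_concentration: float = 10.0  # beta a+b
    density_no2_rho: float = 0.60     # latent log-log correlation
    n_floorplans: int = 24
    zips_per_county: int = 10
    kitchen_minutes_percentiles: Tuple[float, float, float] = (5.0, 35.0, 150.0)
    hood_not_used_house: float = 0.64
    hood_not_used_apartment: float = 0.72

    def __post_init__(self) -> None:
        if self.n_zips <= 0 or self.n_floorplans < 4:
            raise SyntheticError("n_zips must be > 0 and n_floorplans >= 4")
        if not 0 <= self.density_no2_rho < 1:
            raise SyntheticError("density/NO2 correlation must be in [0, 1)")
        if not self.outdoor_no2_mean > self.outdoor_no2_median > 0:
            raise SyntheticError("outdoor NO2 mean must exceed the median (right skew)")
        p5, p50, p95 = self.kitchen_minutes_percentiles
        if not 0 < p5 <= p50 <= p95:
            raise SyntheticError("kitchen-minute percentile targets must be monotone")


# ---------------------------------------------------------------------------
# ZIP table
# ---------------------------------------------------------------------------

#: (home type, area class) combos the floorplan library can represent, in
#: priority order (most prevalent first). The housing-mix generator only
#: emits combos the configured library size covers, so every populated cell
#: always maps to at least one floorplan.
TYPE_AREA_PRIORITY: Tuple[Tuple[str, str], ...] = (
    ("single_detached", "0-1499"),
    ("single_detached", "1500-2499"),
    ("multifamily", "0-1499"),
    ("single_attached", "0-1499"),
    ("mobile", "0-1499"),
    ("single_detached", "2500-3999"),
    ("multifamily", "1500-2499"),
    ("single_attached", "1500-2499"),
    ("single_detached", ">=4000"),
)


def covered_type_area(n_floorplans: int) -> Tuple[Tuple[str, str], ...]:
    """The (home type, area class) combos a library of this size covers."""
    return TYPE_AREA_PRIORITY[: min(n_floorplans, len(TYPE_AREA_PRIORITY))]


def generate_zip_table(config: SynthConfig) -> List[ZipInputs]:
    """Synthetic ZIP inputs with the configured marginals and couplings.

    Outdoor NO2 is lognormal with parameters solved from the median/mean
    anchors (σ² = 2 ln(mean/median)); log density shares a latent normal
    with log NO2 at correlation ``density_no2_rho``; the multifamily and
    small-floor-area housing shares increase logistically with density.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_zips

    sigma = math.sqrt(2.0 * math.log(config.outdoor_no2_mean / config.outdoor_no2_median))
    mu = math.log(config.outdoor_no2_median)
    z_density = rng.standard_normal(n)
    z_indep = rng.standard_normal(n)
    rho = config.density_no2_rho
    log_no2 = mu + sigma * (rho * z_density + math.sqrt(1 - rho**2) * z_indep)
    outdoor_no2 = np.exp(log_no2)

    # density: lognormal, median 300 persons/km², broad spread
    density = np.exp(math.log(300.0) + 1.3 * z_density)

    a = config.gas_fraction_mean * config.gas_fraction_concentration
    b = (1 - config.gas_fraction_mean) * config.gas_fraction_concentration
    gas_fraction = rng.beta(a, b, size=n)

    population = np.round(np.exp(rng.normal(math.log(8000.0), 0.8, size=n))).astype(int)

    # climate band: colder at low index blocks to keep counties coherent
    bands = rng.choice(["cold", "warm", "mixed"], size=n, p=[0.35, 0.25, 0.40])

    covered = covered_type_area(config.n_floorplans)
    zips = []
    for i in range(n):
        mix = _housing_mix(rng, float(density[i]), covered)
        zips.append(
            ZipInputs(
                zip_id=f"Z{i:05d}",
                population=float(population[i]),
                outdoor_no2=float(outdoor_no2[i]),
                gas_stove_fraction=float(gas_fraction[i]),
                housing_mix=mix,
                climate_band=str(bands[i]),
                density=float(density[i]),
                county_id=f"C{i // config.zips_per_county:04d}",
            )
        )
    return zips


def _housing_mix(
    rng: np.random.Generator,
    density: float,
    covered: Tuple[Tuple[str, str], ...] = TYPE_AREA_PRIORITY,
) -> Dict[HousingCell, float]:
    """Logistic density→housing-stock coupling over the covered cells."""
    x = math.log(density / 300.0)
    p_multi = 1.0 / (1.0 + math.exp(-(0.9 * x - 0.3)))  # denser → more multifamily
    p_small = 1.0 / (1.0 + math.exp(-(0.6 * x + 0.2)))  # denser → smaller homes

    type_shares = {
        "multifamily": p_multi,
        "single_attached": 0.15 * (1 - p_multi) + 0.1 * p_multi,
        "mobile": 0.06 * (1 - p_multi),
    }
    type_shares["single_detached"] = 1.0 - sum(type_shares.values())

    area_shares_by_type = {
        "mobile": {"0-1499": 1.0},
        "multifamily": {"0-1499": 0.6 + 0.3 * p_small, "1500-2499": 0.4 - 0.3 * p_small},
        "single_attached": {"0-1499": 0.4 + 0.3 * p_small, "1500-2499": 0.6 - 0.3 * p_small},
        "single_detached": {
            "0-1499": 0.25 + 0.3 * p_small,
            "1500-2499": 0.35,
            "2500-3999": 0.28 - 0.2 * p_small,
            ">=4000": 0.12 - 0.1 * p_small,
        },
    }
    p_forced_air = float(np.clip(rng.normal(0.65, 0.1), 0.05, 0.95))
    mix: Dict[HousingCell, float] = {}
    for home_type, ts in type_shares.items():
        if ts <= 0:
            continue
        areas = area_shares_by_type[home_type]
        total_area = sum(areas.values())
        for area, ashare in areas.items():
            if ashare <= 0:
                continue
            if (home_type, area) not in covered:
                continue
            share = ts * ashare / total_area
            stories_opts = (1,) if home_type == "mobile" else (1, 2)
            for stories in stories_opts:
                s_share = 1.0 if len(stories_opts) == 1 else (0.55 if stories == 1 else 0.45)
                for fa, f_share in ((True, p_forced_air), (False, 1 - p_forced_air)):
                    mix[(home_type, area, stories, fa)] = (
                        mix.get((home_type, area, stories, fa), 0.0) + share * s_share * f_share
                    )
    total = sum(mix.values())
    return {k: v / total for k, v in mix.items()}


def zip_table_to_frame(zips: Sequence[ZipInputs]) -> pd.DataFrame:
    rows = []
    for z in zips:
        row = {
            "zip_id": z.zip_id,
            "county_id": z.county_id,
            "population": z.population,
            "density": z.density,
            "outdoor_no2": z.outdoor_no2,
            "gas_stove_fraction": z.gas_stove_fraction,
            "climate_band": z.climate_band,
        }
        for (ht, area, stories, fa), frac in sorted(z.housing_mix.items()):
            row[f"mix__{ht}__{area}__{stories}__{int(fa)}"] = frac
        rows.append(row)
    return pd.DataFrame(rows).fillna(0.0)


def frame_to_zip_table(frame: pd.DataFrame) -> List[ZipInputs]:
    zips = []
    mix_cols = [c for c in frame.columns if c.startswith("mix__")]
    for r in frame.to_dict("records"):
        mix: Dict[HousingCell, float] = {}
        for c in mix_cols:
            v = r[c]
            if v > 0:
                _, ht, area, stories, fa = c.split("__")
                mix[(ht, area, int(stories), bool(int(fa)))] = float(v)
        total = sum(mix.values())
        mix = {k: v / total for k, v in mix.items()}
        zips.append(
            ZipInputs(
                zip_id=r["zip_id"],
                population=float(r["population"]),
                outdoor_no2=float(r["outdoor_no2"]),
                gas_stove_fraction=float(r["gas_stove_fraction"]),
                housing_mix=mix,
                climate_band=r["climate_band"],
                density=float(r["density"]),
                county_id=r["county_id"],
            )
        )
    return zips


# ---------------------------------------------------------------------------
# Floorplan library
# ---------------------------------------------------------------------------

#: Representative floor areas (ft²) per area class.
AREA_FT2 = {"0-1499": 1000.0, "1500-2499": 1900.0, "2500-3999": 3100.0, ">=4000": 4500.0}


def generate_floorplans(config: SynthConfig) -> List[Floorplan]:
    """Floorplan library covering every housing cell the mix generator emits.

    The default 24 plans are the 9 covered (home type × area class) combos
    expanded over stories and forced-air presence, with zone counts and
    volumes scaled to the floor area. Envelope leakage and window reference
    flows are sized so the whole-dwelling air exchange hits the calibration
    anchors (≈0 h⁻¹ sealed/calm; ≈6 h⁻¹ windows open in −5 °C, 10 m/s wind).
    """
    covered = covered_type_area(config.n_floorplans)
    pool: List[Tuple[str, str, int, bool]] = []
    for ht, area in covered:
        stories_opts = (1,) if ht == "mobile" else ((1, 2) if ht != "multifamily" else (1,))
        for st in stories_opts:
            for fa in (True, False):
                pool.append((ht, area, st, fa))
    # guarantee every covered (type, area) combo appears before spending
    # slots on stories/forced-air variants
    first_of_combo = []
    seen = set()
    for s in pool:
        if (s[0], s[1]) not in seen:
            seen.add((s[0], s[1]))
            first_of_combo.append(s)
    rest = [s for s in pool if s not in first_of_combo]
    specs = (first_of_combo + rest)[: config.n_floorplans]
    while len(specs) < config.n_floorplans:
        specs.append(pool[len(specs) % len(pool)])
    plans = [
        _build_floorplan(f"FP{i:02d}", ht, area, st, fa)
        for i, (ht, area, st, fa) in enumerate(specs)
    ]
    built = {(p.home_type, p.floor_area_class) for p in plans}
    missing = [c for c in covered if c not in built]
    if missing:
        raise SyntheticError(f"floorplan library does not cover cells: {missing}")
    return plans


def _build_floorplan(
    plan_id: str, home_type: str, area_class: str, stories: int, forced_air: bool
) -> Floorplan:
    area_m2 = AREA_FT2[area_class] * FT2_TO_M2
    volume = area_m2 * CEILING_HEIGHT_M
    n_bedrooms = {"0-1499": 2, "1500-2499": 3, "2500-3999": 4, ">=4000": 5}[area_class]

    shares = {"kitchen": 0.12, "living": 0.30, "hallway": 0.10}
    bedroom_share = (1.0 - sum(shares.values())) / n_bedrooms
    zones = [
        Zone("kitchen", volume * shares["kitchen"], "kitchen", has_window=True),
        Zone("living", volume * shares["living"], "living", has_window=True),
        Zone("hallway", volume * shares["hallway"], "hallway", has_window=False),
    ]
    for b in range(n_bedrooms):
        zones.append(Zone(f"bedroom{b+1}", volume * bedroom_share, "bedroom", has_window=True))

    paths: List[FlowPath] = []
    # interior openings: hallway is the hub; kitchen also opens to living
    interzone = 150.0 * (volume / 250.0)  # m³/h, scaled to dwelling size
    for z in zones:
        if z.zone_id != "hallway":
            paths.append(FlowPath(z.zone_id, "hallway", "interzone_opening", interzone))
    paths.append(FlowPath("kitchen", "living", "interzone_opening", interzone))

    # leakage: distributed over exterior zones, sized so AER at the extreme
    # anchor splits ~15% leakage / 85% windows
    driver_extreme = 0.06 * EXTREME_DRIVER_WIND + 0.04 * math.sqrt(EXTREME_DRIVER_DT)
    total_ref = AER_WINDOWS_OPEN_EXTREME * volume / driver_extreme
    leak_ref = 0.15 * total_ref
    exterior = [z for z in zones if z.zone_kind != "hallway"]
    for z in exterior:
        paths.append(
            FlowPath(z.zone_id, OUTDOORS, "leakage", leak_ref * z.volume / sum(e.volume for e in exterior))
        )

    window_zones = [z for z in zones if z.has_window]
    win_ref = 0.85 * total_ref / len(window_zones)
    for z in window_zones:
        paths.append(FlowPath(z.zone_id, OUTDOORS, "open_window", win_ref))

    return Floorplan(
        floorplan_id=plan_id,
        zones=zones,
        paths=paths,
        stories=stories,
        home_type=home_type,
        floor_area_class=area_class,
        has_forced_air=forced_air,
    )


# ---------------------------------------------------------------------------
# Behavioral samplers
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSamplers:
    """Samplers for kitchen minutes, hood use, and occupancy draws."""

    kitchen_minutes: Callable[[np.random.Generator, int], np.ndarray]
    hood_not_used: Dict[str, float]
    params: dict = field(default_factory=dict)


def split_lognormal_sampler(p5: float, p50: float, p95: float):
    """Sampler with the three requested percentiles, exact by construction.

    A lognormal has symmetric log-scale percentiles; the kitchen-time
    anchors are not (35/5 = 7 ≠ 150/35 ≈ 4.3), so the two halves use
    separate log-scale spreads glued at the median.
    """
    z95 = 1.6448536269514722
    sigma_low = math.log(p50 / p5) / z95
    sigma_high = math.log(p95 / p50) / z95

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        z = rng.standard_normal(n)
        sigma = np.where(z < 0, sigma_low, sigma_high)
        return p50 * np.exp(sigma * z)

    return sample


def generate_behavior_samplers(config: SynthConfig) -> BehaviorSamplers:
    p5, p50, p95 = config.kitchen_minutes_percentiles
    if config.hood_not_used_house < 0 or config.hood_not_used_apartment < 0:
        raise SyntheticError("hood-not-used probabilities must be >= 0")
    if p5 == p50 == p95:
        sampler = lambda rng, n: np.full(n, p50)  # degenerate config
    else:
        sampler = split_lognormal_sampler(p5, p50, p95)
    return BehaviorSamplers(
        kitchen_minutes=sampler,
        hood_not_used={
            "house": config.hood_not_used_house,
            "apartment": config.hood_not_used_apartment,
        },
        params={
            "kitchen_minutes_percentiles": [p5, p50, p95],
            "hood_not_used_house": config.hood_not_used_house,
            "hood_not_used_apartment": config.hood_not_used_apartment,
        },
    )


@dataclass
class SynthBundle:
    """All synthetic inputs the pipeline needs."""

    zips: List[ZipInputs]
    floorplans: List[Floorplan]
    behavior: BehaviorSamplers
    config: SynthConfig

    @property
    def county_crosswalk(self) -> Dict[str, str]:
        return {z.zip_id: z.county_id for z in self.zips}


def generate_bundle(config: SynthConfig) -> SynthBundle:
    return SynthBundle(
        zips=generate_zip_table(config),
        floorplans=generate_floorplans(config),
        behavior=generate_behavior_samplers(config),
        config=config,
    )
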