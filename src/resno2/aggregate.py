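"""Population-weighted exposure aggregation: floorplans → ZIP → county → nation.

A ZIP code's exposure is a double-weighted sum over the floorplan library
and the scenario grid:

    Exp_ZIP = Σ_i Σ_j Exp_{i,j} · WScenario_j · WFloorplan_{i,ZIP}

with floorplan weights proportional to the prevalence of each floorplan's
housing cell (home type × floor-area class × stories × forced air) in the
ZIP's housing stock, scenario weights from the behavioral grid, and each
ZIP mixing one cold-season and one warm-season scenario distribution at
50% each. Exceedance fractions replace Exp with the indicator
1{Exp ≥ threshold}. Larger geographies are population-weighted means of
their ZIPs. Whole-population (gas + electric households) means multiply
the gas-stove-household value by the ZIP's gas-stove fraction, since
electric-stove households contribute zero stove-attributable exposure.

Geographies are classified against a long-term guideline into three
mutually exclusive categories: outdoor-attributable exposure alone already
exceeds it; the addition of stove-attributable exposure pushes the total
over; or the total stays below even with the stove.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exposure import ScenarioExposure, OutdoorScaling, outdoor_attributable
from .multizone import Floorplan
from .uncertainty import CIValue, McMultipliers, apply_ci, summarize_ci

#: Default long- and short-term benchmarks, ppbv.
WHO_LONG_TERM_PPBV = 5.2       # 10 µg/m³ annual guideline
CANADA_LONG_TERM_PPBV = 11.0   # 20 µg/m³
EPA_LONG_TERM_PPBV = 53.0
ACUTE_THRESHOLD_PPBV = 100.0   # WHO 200 µg/m³ 1-h guideline ≈ EPA 100 ppbv

HousingCell = Tuple[str, str, int, bool]  # (home_type, area class, stories, forced air)


class AggregationError(ValueError):
    pass


class BenchmarkClass(enum.Enum):
    OUTDOOR_ALONE_EXCEEDS = "outdoor_alone_exceeds"
    STOVE_PUSHES_OVER = "stove_pushes_over"
    BELOW_WITH_STOVE = "below_with_stove"


@dataclass
class ZipInputs:
    """ZIP-level predictors for the exposure model."""

    zip_id: str
    population: float
    outdoor_no2: float          # annual-mean, ppbv
    gas_stove_fraction: float
    housing_mix: Dict[HousingCell, float]
    climate_band: str = "mixed"  # cold / warm / mixed (50/50 season split)
    density: float = 0.0         # persons/km²
    county_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise AggregationError(f"{self.zip_id}: negative population")
        if not 0.0 <= self.gas_stove_fraction <= 1.0:
            raise AggregationError(f"{self.zip_id}: gas fraction outside [0, 1]")
        if self.outdoor_no2 < 0:
            raise AggregationError(f"{self.zip_id}: negative outdoor NO2")
        total = sum(self.housing_mix.values())
        if self.housing_mix and abs(total - 1.0) > 1e-6:
            raise AggregationError(f"{self.zip_id}: housing mix sums to {total}")
        if any(v < 0 for v in self.housing_mix.values()):
            raise AggregationError(f"{self.zip_id}: negative housing-mix fraction")


def floorplan_cell(fp: Floorplan) -> HousingCell:
    return (fp.home_type, fp.floor_area_class, fp.stories, fp.has_forced_air)


def floorplan_weights(
    zip_inputs: ZipInputs, floorplans: Sequence[Floorplan]
) -> Dict[str, float]:
    """Normalized floorplan weights from the ZIP's housing-stock mix.

    Each housing cell's prevalence goes to the floorplans matching it, split
    equally among ties. Matching relaxes progressively — exact cell, then
    ignoring forced air, then ignoring stories too — but home type and
    floor-area class must always match; a populated cell with no such
    floorplan is a configuration error.
    """
    weights = {fp.floorplan_id: 0.0 for fp in floorplans}
    for cell, prevalence in zip_inputs.housing_mix.items():
        if prevalence <= 0:
            continue
        matches = _match_cell(cell, floorplans)
        if not matches:
            raise AggregationError(
                f"{zip_inputs.zip_id}: no floorplan for housing cell {cell}"
            )
        share = prevalence / len(matches)
        for fp in matches:
            weights[fp.floorplan_id] += share
    total = sum(weights.values())
    if total <= 0:
        raise AggregationError(f"{zip_inputs.zip_id}: empty housing mix")
    return {k: v / total for k, v in weights.items()}


def _match_cell(cell: HousingCell, floorplans: Sequence[Floorplan]) -> List[Floorplan]:
    home_type, area, stories, forced_air = cell
    exact = [f for f in floorplans if floorplan_cell(f) == cell]
    if exact:
        return exact
    no_fa = [
        f
        for f in floorplans
        if (f.home_type, f.floor_area_class, f.stories) == (home_type, area, stories)
    ]
    if no_fa:
        return no_fa
    return [f for f in floorplans if (f.home_type, f.floor_area_class) == (home_type, area)]


@dataclass
class ZipExposure:
    """Aggregated exposure for one ZIP (gas-stove households), with CIs."""

    zip_id: str
    chron_stove: CIValue
    chron_outdoor: CIValue
    acute_stove: CIValue
    acute_outdoor: CIValue
    exceed_chron: float
    exceed_acute: float
    population: float = 0.0
    gas_stove_fraction: float = 1.0

    def __post_init__(self) -> None:
        for frac in (self.exceed_chron, self.exceed_acute):
            if not 0.0 <= frac <= 1.0 + 1e-12:
                raise AggregationError(f"exceedance fraction {frac} outside [0, 1]")

    @property
    def chron_total(self) -> CIValue:
        return self.chron_stove + self.chron_outdoor


#: Season mixing: each ZIP mixes one cold and one warm scenario distribution.
SEASON_WEIGHTS = {"cold": {"cold": 1.0}, "warm": {"warm": 1.0}, "mixed": {"cold": 0.5, "warm": 0.5}}


def zip_exposure(
    weights: Mapping[str, float],
    scenario_exposures: Mapping[str, Mapping[str, Sequence[ScenarioExposure]]],
    zip_inputs: ZipInputs,
    conta_exposures: Mapping[str, Mapping[str, Sequence[ScenarioExposure]]],
    chron_threshold: float = WHO_LONG_TERM_PPBV,
    acute_threshold: float = ACUTE_THRESHOLD_PPBV,
    multipliers: Optional[McMultipliers] = None,
) -> ZipExposure:
    """Double-weighted ZIP aggregation of scenario exposures.

    ``scenario_exposures[floorplan_id][band]`` holds the stove-NO2 channel
    (ppbv) and ``conta_exposures`` the infiltration-tracer channel (percent
    infiltration, scaled here by the ZIP's outdoor NO2); ``band`` is the
    seasonal distribution ('cold'/'warm'), mixed per the ZIP's climate.
    Exceedance fractions use total (stove + outdoor) exposure against the
    thresholds.
    """
    multipliers = multipliers or McMultipliers.unit()
    _check_normalized(weights, "floorplan weights")
    season_mix = SEASON_WEIGHTS.get(zip_inputs.climate_band)
    if season_mix is None:
        raise AggregationError(f"unknown climate band {zip_inputs.climate_band!r}")

    chron_stove = acute_stove = chron_out = acute_out = 0.0
    exceed_chron = exceed_acute = 0.0
    for fp_id, w_fp in weights.items():
        if w_fp == 0:
            continue
        for band, w_band in season_mix.items():
            stove = scenario_exposures[fp_id][band]
            conta = conta_exposures[fp_id][band]
            if len(stove) != len(conta):
                raise AggregationError("stove and tracer scenario sets must align")
            sw = np.array([s.weight for s in stove])
            if not np.isclose(sw.sum(), 1.0, atol=1e-6):
                raise AggregationError(f"{fp_id}/{band}: scenario weights not normalized")
            s_chron = np.array([s.chron for s in stove])
            s_acute = np.array([s.acute for s in stove])
            o_chron = np.array(
                [
                    outdoor_attributable(
                        OutdoorScaling(c.chron, zip_inputs.outdoor_no2)
                    )
                    for c in conta
                ]
            )
            o_acute = np.array(
                [
                    outdoor_attributable(
                        OutdoorScaling(min(c.acute, 100.0), zip_inputs.outdoor_no2)
                    )
                    for c in conta
                ]
            )
            w = w_fp * w_band * sw
            chron_stove += float(w @ s_chron)
            acute_stove += float(w @ s_acute)
            chron_out += float(w @ o_chron)
            acute_out += float(w @ o_acute)
            exceed_chron += float(w[(s_chron + o_chron) >= chron_threshold].sum())
            exceed_acute += float(w[(s_acute + o_acute) >= acute_threshold].sum())

    return ZipExposure(
        zip_id=zip_inputs.zip_id,
        chron_stove=apply_ci(chron_stove, multipliers.stove),
        chron_outdoor=apply_ci(chron_out, multipliers.outdoor),
        acute_stove=apply_ci(acute_stove, multipliers.stove),
        acute_outdoor=apply_ci(acute_out, multipliers.outdoor),
        exceed_chron=min(exceed_chron, 1.0),
        exceed_acute=min(exceed_acute, 1.0),
        population=zip_inputs.population,
        gas_stove_fraction=zip_inputs.gas_stove_fraction,
    )


def _check_normalized(weights: Mapping[str, float], what: str) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-6:
        raise AggregationError(f"{what} sum to {total}, expected 1")


def whole_population_mean(
    stove_value: float, gas_fraction: float, mode: str = "multiply"
) -> float:
    """Stove-attributable mean over the whole population (gas + electric).

    Electric-stove households contribute zero stove exposure, so the
    gas-household mean scales by the gas-stove fraction. ``mode='divide'``
    applies the inverse adjustment (recovering the gas-household value from
    a whole-population one).
    """
    if not 0.0 <= gas_fraction <= 1.0:
        raise AggregationError("gas fraction outside [0, 1]")
    if mode == "multiply":
        return stove_value * gas_fraction
    if mode == "divide":
        if gas_fraction == 0:
            raise AggregationError("cannot divide by zero gas fraction")
        return stove_value / gas_fraction
    raise AggregationError(f"unknown mode {mode!r}")


def rollup(values: Sequence[float], populations: Sequence[float]) -> float:
    """Population-weighted mean over geographies."""
    v = np.asarray(values, dtype=float)
    p = np.asarray(populations, dtype=float)
    if v.shape != p.shape or v.size == 0:
        raise AggregationError("values and populations must align and be non-empty")
    if np.any(p < 0):
        raise AggregationError("negative population")
    if p.sum() == 0:
        raise AggregationError("total population is zero")
    return float(v @ p / p.sum())


def rollup_ci(values: Sequence[CIValue], populations: Sequence[float]) -> CIValue:
    """Population-weighted mean applied component-wise to CI triples."""
    p = np.asarray(populations, dtype=float)
    return summarize_ci(lambda col: rollup(col, p), list(values))


def classify_benchmark(
    outdoor: float, stove: float, threshold: float = WHO_LONG_TERM_PPBV
) -> BenchmarkClass:
    """Three-way guideline classification of a geography.

    Outdoor-attributable exposure alone at/above the threshold dominates;
    otherwise the stove contribution may push the total over; otherwise the
    geography stays below the guideline even with the stove.
    """
    if outdoor < 0 or stove < 0 or threshold <= 0:
        raise AggregationError("inputs must be non-negative and threshold positive")
    if outdoor >= threshold:
        return BenchmarkClass.OUTDOOR_ALONE_EXCEEDS
    if outdoor + stove >= threshold:
        return BenchmarkClass.STOVE_PUSHES_OVER
    return BenchmarkClass.BELOW_WITH_STOVE


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def zip_exposures_to_frame(exposures: Sequence[ZipExposure]) -> pd.DataFrame:
    rows = []
    for e in exposures:
        cls = classify_benchmark(e.chron_outdoor.central, e.chron_stove.central)
        rows.append(
            {
                "zip_id": e.zip_id,
                "population": e.population,
                "gas_stove_fraction": e.gas_stove_fraction,
                "chron_stove_lower": e.chron_stove.lower,
                "chron_stove_central": e.chron_stove.central,
                "chron_stove_upper": e.chron_stove.upper,
                "chron_outdoor_lower": e.chron_outdoor.lower,
                "chron_outdoor_central": e.chron_outdoor.central,
                "chron_outdoor_upper": e.chron_outdoor.upper,
                "acute_stove_central": e.acute_stove.central,
                "acute_outdoor_central": e.acute_outdoor.central,
                "exceed_chron": e.exceed_chron,
                "exceed_acute": e.exceed_acute,
                "benchmark_class": cls.value,
            }
        )
    return pd.DataFrame(rows)


def county_rollup(
    frame: pd.DataFrame, crosswalk: Mapping[str, str]
) -> pd.DataFrame:
    """Population-weighted county means of the per-ZIP output table."""
    df = frame.copy()
    df["county_id"] = df["zip_id"].map(dict(crosswalk))
    if df["county_id"].isna().any():
        missing = df.loc[df["county_id"].isna(), "zip_id"].tolist()[:5]
        raise AggregationError(f"ZIPs missing from county crosswalk, e.g. {missing}")
    value_cols = [
        c
        for c in df.columns
        if c.startswith(("chron_", "acute_", "exceed_")) or c == "gas_stove_fraction"
    ]

    def agg(group: pd.DataFrame) -> pd.Series:
        out = {c: rollup(group[c].to_numpy(), group["population"].to_numpy()) for c in value_cols}
        out["population"] = group["population"].sum()
        return pd.Series(out)

    county = df.groupby("county_id").apply(agg, include_groups=False).reset_index()
    county["benchmark_class"] = [
        classify_benchmark(r.chron_outdoor_central, r.chron_stove_central).value
        for r in county.itertuples()
    ]
    return county
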