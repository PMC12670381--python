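"""End-to-end pipeline: synth → simulate → exposure → uncertainty → aggregate → report.

Every stage writes plain CSV/JSON artifacts into the run directory and can
be re-run from cached intermediates; identical config and seed give
byte-identical artifacts. The stove-NO2 channel is linear in the emission
rate, so each (stove day type × windspeed × window schedule) combination is
simulated once per floorplan and band with no hood, and hood capture is
applied afterwards as the (1 − CE) factor; occupancy weighting likewise
happens in post-processing. This reduces the 2,160-scenario grid per
floorplan to 81 stove simulations and 9 tracer simulations per band.

Climate bands stand in for the ambient-temperature axis at the ZIP level:
each band uses a representative ambient temperature (5 °C cold, 22 °C warm)
and its own window-opening weights; each ZIP mixes the two band
distributions according to its climate label.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import exposure as ex
from . import schedules
from .aggregate import (
    ACUTE_THRESHOLD_PPBV,
    WHO_LONG_TERM_PPBV,
    BenchmarkClass,
    classify_benchmark,
    county_rollup,
    floorplan_weights,
    rollup,
    rollup_ci,
    whole_population_mean,
    zip_exposure,
    zip_exposures_to_frame,
)
from .multizone import (
    Floorplan,
    SimConfig,
    air_exchange_constant,
    load_floorplans,
    save_floorplans,
    simulate_day,
)
from .scenarios import (
    Scenario,
    default_axes,
    temperature_conditioned_grid,
)
from .synthetic import SynthConfig, SynthBundle, generate_bundle, frame_to_zip_table, zip_table_to_frame
from .uncertainty import CIValue, McInputDistributions, McMultipliers, mc_multipliers

log = logging.getLogger("resno2.pipeline")

STAGES = ("synth", "simulate", "exposure", "uncertainty", "aggregate", "report")

#: Representative ambient temperature per climate band, °C.
BAND_TEMPERATURE = {"cold": 5.0, "warm": 22.0}


@dataclass
class PipelineConfig:
    """Run configuration; defaults give the small demo setup."""

    seed: int = 0
    out_dir: str = "scratch/run"
    n_zips: int = 200
    n_floorplans: int = 8
    heavy_week_weight: float = 0.10
    mc_iterations: int = 5000
    chron_threshold: float = WHO_LONG_TERM_PPBV
    acute_threshold: float = ACUTE_THRESHOLD_PPBV
    decay_rate: float = -0.86

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where artifacts land does not change what they contain
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_run: List[str]
    files: Dict[str, str]  # relative path -> sha256
    timings: Dict[str, float]
    created: str

    def write(self, out_dir: Path) -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Stage: synth
# ---------------------------------------------------------------------------

def stage_synth(config: PipelineConfig, out: Path) -> SynthBundle:
    bundle = generate_bundle(
        SynthConfig(n_zips=config.n_zips, seed=config.seed, n_floorplans=config.n_floorplans)
    )
    zip_table_to_frame(bundle.zips).to_csv(out / "zips.csv", index=False)
    pd.DataFrame(
        [{"zip_id": z, "county_id": c} for z, c in bundle.county_crosswalk.items()]
    ).to_csv(out / "counties.csv", index=False)
    save_floorplans(bundle.floorplans, out / "floorplans.json")
    with open(out / "samplers.json", "w") as fh:
        json.dump(bundle.behavior.params, fh, indent=1)
    log.info("synth: %d ZIPs, %d floorplans", len(bundle.zips), len(bundle.floorplans))
    return bundle


# ---------------------------------------------------------------------------
# Stage: simulate
# ---------------------------------------------------------------------------

def _physical_scenarios(config: PipelineConfig) -> List[dict]:
    """Occupancy- and hood-independent simulation jobs for one floorplan/band."""
    axes = {a.name: a for a in default_axes(heavy_week_weight=config.heavy_week_weight)}
    jobs = []
    for stove in axes["stove_use"].levels:
        day_types = schedules.day_type_emissions(
            stove.payload["daily_emission_mg"], stove.payload["day_types"]
        )
        for day_label, days_per_week, daily_mg in day_types:
            for wind in axes["windspeed"].levels:
                for window in axes["window_schedule"].levels:
                    jobs.append(
                        {
                            "stove_level": stove.label,
                            "day_type": day_label,
                            "days_per_week": days_per_week,
                            "daily_emission_mg": daily_mg,
                            "wind_level": wind.label,
                            "windspeed": wind.payload["windspeed"],
                            "window_level": window.label,
                            "open_hours": window.payload["open_hours"],
                        }
                    )
    return jobs


def stage_simulate(config: PipelineConfig, out: Path) -> pd.DataFrame:
    """Run the multizone simulator; emit person-day primitives.

    For each floorplan × band × (stove day type × windspeed × window) job,
    the no-hood NO2 day and (per wind × window) the tracer day are
    integrated once; chronic/acute person-day values are recorded for every
    occupancy level. The table also carries the whole-dwelling air-exchange
    constant recovered from the inert tracer.
    """
    floorplans = load_floorplans(out / "floorplans.json")
    axes = {a.name: a for a in default_axes(heavy_week_weight=config.heavy_week_weight)}
    occupancy_levels = axes["occupancy"].levels
    rows = []
    t0 = time.time()
    for fp in floorplans:
        occ_schedules = {
            lvl.label: schedules.build_occupancy_schedule(
                fp, lvl.payload["kitchen_minutes"], lvl.payload["outdoor_hours"]
            )
            for lvl in occupancy_levels
        }
        for band, temp in BAND_TEMPERATURE.items():
            tracer_cache: Dict[Tuple[str, str], dict] = {}
            for job in _physical_scenarios(config):
                sim_config = SimConfig(
                    decay_rate=config.decay_rate,
                    ambient_temperature=temp,
                    windspeed=job["windspeed"],
                )
                window_sched = schedules.build_window_schedule(job["open_hours"])
                tracer_key = (job["wind_level"], job["window_level"])
                if tracer_key not in tracer_cache:
                    source0 = schedules.build_source_schedule(fp, 0.0, 0.0, False)
                    series0 = simulate_day(fp, source0, sim_config, window_sched)
                    aer = air_exchange_constant(series0, sim_config)
                    conta_days = {}
                    for lvl in occupancy_levels:
                        ps = ex.person_series(series0, occ_schedules[lvl.label], "conta")
                        conta_days[lvl.label] = ex.person_day(ps)
                    tracer_cache[tracer_key] = {"aer": aer, "conta": conta_days}
                tracer = tracer_cache[tracer_key]

                source = schedules.build_source_schedule(
                    fp, job["daily_emission_mg"], 0.0, False
                )
                series = simulate_day(fp, source, sim_config, window_sched)
                for lvl in occupancy_levels:
                    ps = ex.person_series(series, occ_schedules[lvl.label], "no2_stove")
                    stove_day = ex.person_day(ps)
                    conta_day = tracer["conta"][lvl.label]
                    rows.append(
                        {
                            "floorplan_id": fp.floorplan_id,
                            "band": band,
                            "occupancy_level": lvl.label,
                            **{
                                k: job[k]
                                for k in (
                                    "stove_level",
                                    "day_type",
                                    "days_per_week",
                                    "wind_level",
                                    "window_level",
                                )
                            },
                            "chron_stove_day": stove_day.chron_day,
                            "acute_stove_day": stove_day.acute_day,
                            "chron_conta_day": conta_day.chron_day,
                            "acute_conta_day": conta_day.acute_day,
                            "air_exchange": tracer["aer"].rate,
                            "aer_reached": tracer["aer"].reached,
                        }
                    )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "day_exposures.csv", index=False)
    log.info("simulate: %d person-day rows in %.1fs", len(frame), time.time() - t0)
    return frame


# ---------------------------------------------------------------------------
# Stage: exposure
# ---------------------------------------------------------------------------

def stage_exposure(config: PipelineConfig, out: Path) -> pd.DataFrame:
    """Fold day-level primitives into the weighted 540-scenario tables.

    Applies hood capture (1 − CE) to the stove channel, weekly day-type
    expectations (days/7), and attaches the scenario weight from the
    temperature-conditioned grid of its band.
    """
    days = pd.read_csv(out / "day_exposures.csv")
    axes = default_axes(heavy_week_weight=config.heavy_week_weight)
    by_name = {a.name: a for a in axes}
    rows = []
    day_rows = []
    for band in BAND_TEMPERATURE:
        grid = temperature_conditioned_grid(axes, band)
        band_days = days[days["band"] == band]
        keyed = band_days.set_index(
            ["floorplan_id", "stove_level", "wind_level", "window_level", "occupancy_level", "day_type"]
        ).sort_index()
        for fp_id in band_days["floorplan_id"].unique():
            for sid, scen in enumerate(grid):
                lv = dict(scen.levels)
                ce = scen.payload["hood_use"]["capture_efficiency"] if scen.payload["hood_use"]["used"] else 0.0
                sub = keyed.loc[
                    (fp_id, lv["stove_use"], lv["windspeed"], lv["window_schedule"], lv["occupancy"])
                ]
                day_w = sub["days_per_week"].to_numpy() / 7.0
                stove_day = ex.weekly_expectation(
                    [
                        ex.PersonDayExposure(r.chron_stove_day * (1 - ce), r.acute_stove_day * (1 - ce))
                        for r in sub.itertuples()
                    ],
                    day_w,
                    scen.weight,
                )
                conta_day = ex.weekly_expectation(
                    [ex.PersonDayExposure(r.chron_conta_day, r.acute_conta_day) for r in sub.itertuples()],
                    day_w,
                    scen.weight,
                )
                heavy = bool(
                    by_name["stove_use"]
                    .levels[[l.label for l in by_name["stove_use"].levels].index(lv["stove_use"])]
                    .payload["heavy_week"]
                )
                rows.append(
                    {
                        "floorplan_id": fp_id,
                        "band": band,
                        "scenario_id": sid,
                        **lv,
                        "weight": scen.weight,
                        "heavy_week": heavy,
                        "chron_stove": stove_day.chron,
                        "acute_stove": stove_day.acute,
                        "chron_conta": conta_day.chron,
                        "acute_conta": conta_day.acute,
                        "air_exchange": float(sub["air_exchange"].iloc[0]),
                    }
                )
                # day-level acute values for exceedance-days accounting
                for r, dw in zip(sub.itertuples(), day_w):
                    day_rows.append(
                        {
                            "floorplan_id": fp_id,
                            "band": band,
                            "scenario_id": sid,
                            "acute_stove_day": r.acute_stove_day * (1 - ce),
                            "weight": scen.weight * dw,
                            "heavy_week": heavy,
                        }
                    )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "scenario_exposures.csv", index=False)
    pd.DataFrame(day_rows).to_csv(out / "day_acute.csv", index=False)
    log.info("exposure: %d scenario rows", len(frame))
    return frame


# ---------------------------------------------------------------------------
# Stage: uncertainty
# ---------------------------------------------------------------------------

def stage_uncertainty(config: PipelineConfig, out: Path) -> McMultipliers:
    mult = mc_multipliers(
        McInputDistributions.defaults(),
        iterations=config.mc_iterations,
        seed=config.seed + 1,
    )
    with open(out / "mc_multipliers.json", "w") as fh:
        json.dump(
            {
                "stove": list(mult.stove),
                "outdoor": list(mult.outdoor),
                "iterations": mult.iterations,
                "seed": mult.seed,
            },
            fh,
            indent=1,
        )
    log.info("uncertainty: stove %s outdoor %s", mult.stove, mult.outdoor)
    return mult


def _load_multipliers(out: Path) -> McMultipliers:
    with open(out / "mc_multipliers.json") as fh:
        d = json.load(fh)
    return McMultipliers(
        stove=tuple(d["stove"]), outdoor=tuple(d["outdoor"]), iterations=d["iterations"], seed=d["seed"]
    )


# ---------------------------------------------------------------------------
# Stage: aggregate
# ---------------------------------------------------------------------------

def _scenario_maps(frame: pd.DataFrame):
    """Nested {floorplan: {band: [ScenarioExposure,...]}} for both channels."""
    stove: Dict[str, Dict[str, List[ex.ScenarioExposure]]] = {}
    conta: Dict[str, Dict[str, List[ex.ScenarioExposure]]] = {}
    for (fp_id, band), g in frame.groupby(["floorplan_id", "band"]):
        stove.setdefault(fp_id, {})[band] = [
            ex.ScenarioExposure(r.chron_stove, r.acute_stove, r.weight) for r in g.itertuples()
        ]
        conta.setdefault(fp_id, {})[band] = [
            ex.ScenarioExposure(r.chron_conta, r.acute_conta, r.weight) for r in g.itertuples()
        ]
    return stove, conta


def stage_aggregate(config: PipelineConfig, out: Path) -> pd.DataFrame:
    zips = frame_to_zip_table(pd.read_csv(out / "zips.csv"))
    floorplans = load_floorplans(out / "floorplans.json")
    frame = pd.read_csv(out / "scenario_exposures.csv")
    mult = _load_multipliers(out)
    stove_map, conta_map = _scenario_maps(frame)

    exposures = []
    aer_values = []
    for z in zips:
        w = floorplan_weights(z, floorplans)
        exposures.append(
            zip_exposure(
                w,
                stove_map,
                z,
                conta_map,
                chron_threshold=config.chron_threshold,
                acute_threshold=config.acute_threshold,
                multipliers=mult,
            )
        )
        # scenario-weighted mean air exchange for this ZIP
        aer = 0.0
        for fp_id, w_fp in w.items():
            for band, w_band in (("cold", 0.5), ("warm", 0.5)):
                g = frame[(frame["floorplan_id"] == fp_id) & (frame["band"] == band)]
                aer += w_fp * w_band * float(g["weight"] @ g["air_exchange"])
        aer_values.append(aer)

    zdf = zip_exposures_to_frame(exposures)
    zdf["air_exchange"] = aer_values
    zdf.to_csv(out / "zip_exposures.csv", index=False)

    crosswalk = dict(pd.read_csv(out / "counties.csv").values)
    county = county_rollup(zdf, crosswalk)
    county.to_csv(out / "county_exposures.csv", index=False)
    log.info("aggregate: %d ZIPs, %d counties", len(zdf), len(county))
    return zdf


# ---------------------------------------------------------------------------
# Stage: report
# ---------------------------------------------------------------------------

def stage_report(config: PipelineConfig, out: Path) -> dict:
    zdf = pd.read_csv(out / "zip_exposures.csv")
    county = pd.read_csv(out / "county_exposures.csv")
    days = pd.read_csv(out / "day_acute.csv")
    mult = _load_multipliers(out)
    pop = zdf["population"].to_numpy()

    def nat(col: str) -> float:
        return rollup(zdf[col].to_numpy(), pop)

    chron_stove = rollup_ci(
        [CIValue(r.chron_stove_lower, r.chron_stove_central, r.chron_stove_upper) for r in zdf.itertuples()],
        pop,
    )
    chron_outdoor = rollup_ci(
        [
            CIValue(r.chron_outdoor_lower, r.chron_outdoor_central, r.chron_outdoor_upper)
            for r in zdf.itertuples()
        ],
        pop,
    )
    total = chron_stove + chron_outdoor
    whole_pop_stove = rollup(
        [
            whole_population_mean(r.chron_stove_central, r.gas_stove_fraction)
            for r in zdf.itertuples()
        ],
        pop,
    )

    exceed = ex.exceedance_days_per_year(
        list(zip(days["acute_stove_day"], days["weight"])),
        threshold=config.acute_threshold,
        heavy_mask=days["heavy_week"].to_numpy(),
        heavy_week_weights=(config.heavy_week_weight, config.heavy_week_weight / 2),
    )

    pushed_pop = float(zdf.loc[zdf["benchmark_class"] == "stove_pushes_over", "population"].sum())
    report = {
        "n_zips": int(len(zdf)),
        "chron_stove_gas_households_ppbv": asdict(chron_stove),
        "chron_outdoor_ppbv": asdict(chron_outdoor),
        "chron_total_gas_households_ppbv": asdict(total),
        "chron_stove_whole_population_ppbv": whole_pop_stove,
        "stove_share_of_total": whole_pop_stove / (whole_pop_stove + chron_outdoor.central),
        "mean_air_exchange_per_hour": nat("air_exchange"),
        "exceedance_days_per_year": {"low": exceed[0], "high": exceed[1]},
        "benchmark_class_counts_zips": zdf["benchmark_class"].value_counts().to_dict(),
        "benchmark_class_counts_counties": county["benchmark_class"].value_counts().to_dict(),
        "population_stove_pushes_over": pushed_pop,
        "mc_multipliers": {"stove": list(mult.stove), "outdoor": list(mult.outdoor)},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("report: total %.2f ppbv (gas households)", total.central)
    return report


STAGE_FUNCS = {
    "synth": stage_synth,
    "simulate": stage_simulate,
    "exposure": stage_exposure,
    "uncertainty": stage_uncertainty,
    "aggregate": stage_aggregate,
    "report": stage_report,
}


def run_pipeline(
    config: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> RunManifest:
    """Execute the requested stages in order and write the run manifest.

    Stages not requested must have left their artifacts in ``out_dir`` from
    a previous run; each stage reads only files, so any suffix of the
    pipeline can be re-run against cached intermediates.
    """
    stages = list(stages) if stages else list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; expected subset of {STAGES}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    timings = {}
    for s in stages:
        t0 = time.time()
        STAGE_FUNCS[s](config, out)
        timings[s] = round(time.time() - t0, 3)
        log.info("stage %s done in %.1fs", s, timings[s])

    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stages_run=stages,
        files=files,
        timings=timings,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out)
    return manifest
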