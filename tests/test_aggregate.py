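import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resno2.aggregate import (
    AggregationError,
    BenchmarkClass,
    ZipInputs,
    classify_benchmark,
    floorplan_weights,
    rollup,
    whole_population_mean,
    zip_exposure,
)
from resno2.exposure import ScenarioExposure
from resno2.synthetic import SynthConfig, generate_floorplans


@pytest.fixture(scope="module")
def library():
    return generate_floorplans(SynthConfig(n_zips=1, n_floorplans=24))


def make_zip(mix, outdoor=8.0, gas=0.4, band="mixed", pop=1000.0):
    return ZipInputs(
        zip_id="Z1",
        population=pop,
        outdoor_no2=outdoor,
        gas_stove_fraction=gas,
        housing_mix=mix,
        climate_band=band,
    )


# ---------------------------------------------------------------------------
# Floorplan weights
# ---------------------------------------------------------------------------

def test_single_cell_single_floorplan_gets_weight_one(library):
    fp = library[0]
    cell = (fp.home_type, fp.floor_area_class, fp.stories, fp.has_forced_air)
    weights = floorplan_weights(make_zip({cell: 1.0}), [fp])
    assert weights == {fp.floorplan_id: pytest.approx(1.0)}


def test_cell_prevalence_split_equally_among_ties(library):
    fp = library[0]
    cell = (fp.home_type, fp.floor_area_class, fp.stories, fp.has_forced_air)
    twins = [fp, fp.__class__.from_dict({**fp.to_dict(), "floorplan_id": "twin"})]
    other = next(p for p in library if p.floor_area_class != fp.floor_area_class)
    other_cell = (other.home_type, other.floor_area_class, other.stories, other.has_forced_air)
    weights = floorplan_weights(make_zip({cell: 0.6, other_cell: 0.4}), twins + [other])
    assert weights[fp.floorplan_id] == pytest.approx(0.3)
    assert weights["twin"] == pytest.approx(0.3)
    assert weights[other.floorplan_id] == pytest.approx(0.4)


def test_weights_sum_to_one_for_generated_zips(library):
    from resno2.synthetic import generate_zip_table

    zips = generate_zip_table(SynthConfig(n_zips=25, seed=5, n_floorplans=24))
    for z in zips:
        w = floorplan_weights(z, library)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)


def test_unmapped_cell_rejected(library):
    sd = [p for p in library if p.home_type == "single_detached"]
    with pytest.raises(AggregationError):
        floorplan_weights(make_zip({("multifamily", "0-1499", 1, True): 1.0}), sd)


# ---------------------------------------------------------------------------
# ZIP aggregation
# ---------------------------------------------------------------------------

def _toy_inputs(stove_vals, conta_vals, weights, fps=("A", "B"), fp_weights=(0.5, 0.5)):
    stove = {}
    conta = {}
    for fp in fps:
        stove[fp] = {
            band: [ScenarioExposure(c, c, w) for c, w in zip(stove_vals[fp], weights)]
            for band in ("cold", "warm")
        }
        conta[fp] = {
            band: [ScenarioExposure(c, c, w) for c, w in zip(conta_vals[fp], weights)]
            for band in ("cold", "warm")
        }
    return stove, conta, dict(zip(fps, fp_weights))


def test_constant_scenarios_pass_through():
    stove, conta, w = _toy_inputs(
        {"A": [3.0, 3.0, 3.0], "B": [3.0, 3.0, 3.0]},
        {"A": [50.0, 50.0, 50.0], "B": [50.0, 50.0, 50.0]},
        [0.2, 0.5, 0.3],
    )
    z = make_zip({("single_detached", "0-1499", 1, True): 1.0}, outdoor=10.0)
    out = zip_exposure(w, stove, z, conta)
    assert out.chron_stove.central == pytest.approx(3.0)
    assert out.chron_outdoor.central == pytest.approx(5.0)  # 50% infiltration x 10 ppbv


def test_toy_case_matches_explicit_double_sum():
    """2 floorplans x 3 scenarios: the aggregation equals the brute-force
    double-weighted sum computed by hand."""
    stove_vals = {"A": [1.0, 2.0, 4.0], "B": [3.0, 5.0, 7.0]}
    conta_vals = {"A": [10.0, 30.0, 60.0], "B": [20.0, 40.0, 80.0]}
    weights = [0.2, 0.5, 0.3]
    fp_w = (0.25, 0.75)
    stove, conta, w = _toy_inputs(stove_vals, conta_vals, weights, fp_weights=fp_w)
    outdoor = 12.0
    z = make_zip({("single_detached", "0-1499", 1, True): 1.0}, outdoor=outdoor)
    out = zip_exposure(w, stove, z, conta)

    expected_stove = sum(
        wf * ws * v
        for wf, fp in zip(fp_w, ("A", "B"))
        for ws, v in zip(weights, stove_vals[fp])
    )
    expected_outdoor = sum(
        wf * ws * v * outdoor / 100.0
        for wf, fp in zip(fp_w, ("A", "B"))
        for ws, v in zip(weights, conta_vals[fp])
    )
    assert out.chron_stove.central == pytest.approx(expected_stove)
    assert out.chron_outdoor.central == pytest.approx(expected_outdoor)


def test_exceedance_fraction_saturates_when_threshold_below_everything():
    stove, conta, w = _toy_inputs(
        {"A": [5.0, 6.0, 7.0], "B": [5.0, 6.0, 7.0]},
        {"A": [50.0, 50.0, 50.0], "B": [50.0, 50.0, 50.0]},
        [0.2, 0.5, 0.3],
    )
    z = make_zip({("single_detached", "0-1499", 1, True): 1.0})
    out = zip_exposure(w, stove, z, conta, chron_threshold=0.1, acute_threshold=0.1)
    assert out.exceed_chron == pytest.approx(1.0)
    assert out.exceed_acute == pytest.approx(1.0)


def test_zip_exposure_linear_in_scenario_value():
    weights = [0.2, 0.5, 0.3]
    base = {"A": [1.0, 2.0, 4.0], "B": [3.0, 5.0, 7.0]}
    bumped = {"A": [1.0, 12.0, 4.0], "B": [3.0, 5.0, 7.0]}  # +10 on A scenario 1
    conta_vals = {"A": [10.0] * 3, "B": [10.0] * 3}
    z = make_zip({("single_detached", "0-1499", 1, True): 1.0})
    s0, c0, w = _toy_inputs(base, conta_vals, weights, fp_weights=(0.25, 0.75))
    s1, c1, _ = _toy_inputs(bumped, conta_vals, weights, fp_weights=(0.25, 0.75))
    out0 = zip_exposure(w, s0, z, c0)
    out1 = zip_exposure(w, s1, z, c1)
    assert out1.chron_stove.central - out0.chron_stove.central == pytest.approx(0.25 * 0.5 * 10.0)


def test_stove_use_intensity_monotone_across_zip_exposures(tmp_path):
    """ZIP exposure restricted to the 95th-percentile stove-use level must
    dominate the 50th, which dominates the 5th (monotone in use intensity)."""
    from resno2.pipeline import PipelineConfig, stage_synth, stage_simulate, stage_exposure

    cfg = PipelineConfig(seed=4, out_dir=str(tmp_path), n_zips=5, n_floorplans=4, mc_iterations=1000)
    out = tmp_path
    stage_synth(cfg, out)
    stage_simulate(cfg, out)
    frame = stage_exposure(cfg, out)
    by_level = (
        frame.groupby("stove_use")
        .apply(lambda g: np.average(g["chron_stove"], weights=g["weight"]), include_groups=False)
        .to_dict()
    )
    assert by_level["p5"] <= by_level["p50"] <= by_level["p95"]


# ---------------------------------------------------------------------------
# Whole-population adjustment and rollup
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("gas, expected", [(1.0, 2.4), (0.0, 0.0)])
def test_whole_population_mean_edges(gas, expected):
    assert whole_population_mean(2.4, gas) == pytest.approx(expected)


def test_whole_population_share_arithmetic():
    """A 2.4 ppbv gas-household stove mean at ~40% gas-stove share is ~10%
    of total exposure when outdoor contributes 7.7 ppbv."""
    stove_all = whole_population_mean(2.4, 0.4)
    share = stove_all / (7.7 + stove_all)
    assert share == pytest.approx(0.10, abs=0.02)  # 0.96/8.66 ≈ 11% ~ "about 10%"


def test_whole_population_divide_mode_inverts():
    assert whole_population_mean(whole_population_mean(2.4, 0.4), 0.4, mode="divide") == pytest.approx(2.4)


def test_gas_fraction_bounds_enforced():
    with pytest.raises(AggregationError):
        whole_population_mean(1.0, 1.5)


def test_rollup_examples():
    assert rollup([1.0, 3.0], [10.0, 10.0]) == pytest.approx(2.0)
    assert rollup([1.0, 9.0], [1e9, 1.0]) == pytest.approx(1.0, abs=1e-6)
    # 5-ZIP toy table, hand-computed weighted mean
    vals = [2.0, 4.0, 6.0, 8.0, 10.0]
    pops = [100.0, 50.0, 25.0, 200.0, 125.0]
    expected = (200 + 200 + 150 + 1600 + 1250) / 500.0
    assert rollup(vals, pops) == pytest.approx(expected)


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=8),
    st.lists(st.floats(min_value=0.1, max_value=1e6), min_size=2, max_size=8),
    st.floats(min_value=0.1, max_value=100),
)
def test_rollup_bounds_and_scale_invariance(values, pops, scale):
    n = min(len(values), len(pops))
    values, pops = values[:n], pops[:n]
    r = rollup(values, pops)
    assert min(values) - 1e-9 <= r <= max(values) + 1e-9
    assert rollup(values, [p * scale for p in pops]) == pytest.approx(r, rel=1e-9)


def test_rollup_rejects_degenerate_populations():
    with pytest.raises(AggregationError):
        rollup([1.0, 2.0], [0.0, 0.0])


# ---------------------------------------------------------------------------
# Benchmark classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "outdoor, stove, expected",
    [
        (6.0, 1.0, BenchmarkClass.OUTDOOR_ALONE_EXCEEDS),
        (4.9, 1.0, BenchmarkClass.STOVE_PUSHES_OVER),
        (3.0, 1.0, BenchmarkClass.BELOW_WITH_STOVE),
    ],
)
def test_classification_examples(outdoor, stove, expected):
    assert classify_benchmark(outdoor, stove, 5.2) is expected


@settings(derandomize=True, max_examples=50)
@given(st.floats(min_value=0, max_value=20), st.floats(min_value=0, max_value=20))
def test_classification_partitions(outdoor, stove):
    cls = classify_benchmark(outdoor, stove, 5.2)
    assert cls in BenchmarkClass
    # exhaustive and mutually exclusive: exactly one branch can hold
    branches = [outdoor >= 5.2, outdoor < 5.2 <= outdoor + stove, outdoor + stove < 5.2]
    assert sum(branches) == 1


def test_classification_rejects_negative_inputs():
    with pytest.raises(AggregationError):
        classify_benchmark(-1.0, 0.0, 5.2)
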