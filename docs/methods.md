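# Methods

## Scope and structure

`resno2` models residential NO₂ exposure as three composable layers: a
multizone indoor mass-balance simulator (`resno2.multizone`), behavioral
scenario weighting and exposure statistics (`resno2.scenarios`,
`resno2.schedules`, `resno2.exposure`), and population aggregation with
Monte Carlo uncertainty (`resno2.aggregate`, `resno2.uncertainty`). The
`resno2.synthetic` module generates all inputs a real deployment would take
from housing-stock, census, and air-monitoring databases, so the whole
pipeline (`resno2.pipeline`) runs self-contained and deterministically
under a single seed.

## The multizone simulator

Zones are well mixed; per species the concentrations obey a linear ODE
system coupling zones through balanced volumetric flows, with first-order
indoor decay (default −0.86 h⁻¹ for NO₂, the literature value for surface
loss in a partially carpeted house) and a stove source in the kitchen zone.
Three species are integrated per day: stove NO₂, an infiltration tracer
(held at 100 ppbv outdoors, decaying like NO₂, initialized at steady state
so its 24-h mean is a valid infiltration percentage without burn-in), and
an inert air-exchange tracer (no decay, zero initial indoor concentration
by definition of the time-constant method).

**Flows, not pressures.** A full pressure-network airflow solver is
deliberately out of scope. Envelope flows are parametric:
each leakage or window path carries `reference_flow × driver`, with
`driver = 0.06·U + 0.04·√|ΔT| + base` (U in m/s, ΔT in K, base 0 by
default). The coefficients and the synthetic floorplans' reference flows
are jointly calibrated to two whole-dwelling air-exchange anchors: ≈0 h⁻¹
with windows closed, no wind, and no indoor–outdoor temperature difference,
and ≈6 h⁻¹ with windows open at −5 °C outdoors in a 10 m/s wind (85% of
that extreme exchange through windows, 15% through leakage). Interior
doors are fixed bidirectional openings (~150 m³/h scaled by dwelling
volume); a forced-air system, when present and running (ambient outside a
12–25 °C deadband), adds 5 air-changes/h of recirculating mixing between
each zone and a hub zone. All pairwise flows are symmetric, which enforces
per-zone air mass balance exactly, by construction.

**Integration.** Within each 10-min output interval the system matrix and
source are constant, so the state is advanced with Van Loan block matrix
exponentials; reported concentrations are exact interval *means*, not
instantaneous samples. There is no integration tolerance to tune; the only
approximation is the piecewise-constant schedule, which is the model's own
time resolution. The independent check integrates the same ODE with an
adaptive Runge–Kutta solver at rtol 1e-10 and agrees to <0.5% RMS.

**Hoods and windows.** Range hoods are modeled purely as source scaling by
(1 − CE) while running — never as exhaust fans, whose well-mixed-removal
semantics misrepresent capture at the source. Recirculating hoods get
CE = 0 (filter NO₂ removal degrades to negligible within weeks and filters
are rarely replaced). Pilot lights are not modeled. The "windows open"
state opens the kitchen, living-room, and every bedroom window together;
open-window flows scale with the same wind/stack driver, floored at 5% of
reference to represent residual buoyancy exchange on calm days.

**Air-exchange constant.** k = 1/τ, with τ the first time the
volume-weighted inert-tracer concentration reaches 1 − 1/e of the outdoor
level. Because the series stores interval means, each mean is first
converted to an end-of-interval concentration via an exponential
deficit-ratio correction (the ratio of successive deficits gives the local
approach rate; the correction is exact for a single zone at any rate —
naive midpoint interpolation on 10-min means cannot resolve τ when it is
comparable to one output interval, e.g. k = 6 h⁻¹). The crossing is then
located by linear interpolation between endpoints. A dwelling that never
reaches the threshold within 24 h returns a not-reached flag.

## Scenarios and exposure statistics

Six axes with level counts (4, 3, 5, 3, 3, 4): hood use (not used at
probability 0.64, else capture efficiencies 0.3/0.55/0.8), stove-use
intensity (5th/50th/95th percentile weeks at 0.64/31/199 mg NO₂ per day,
heavy weeks at 10% prevalence with a 5% sensitivity), occupancy
(kitchen-time percentiles 5–150 min/day plus outdoor time), windspeed
(1/3.5/7 m/s), window schedule (closed / 4 h / all day, weights
conditioned on climate band), and ambient temperature. Four axes are
geography independent (180 scenarios); each climate band's distribution is
the core × 3 window schedules = 540 weighted scenarios; the full factorial
is 2,160 per floorplan. Weights are per-axis prevalences, multiplied and
renormalized. Within a stove-use level a week is 2 light / 4 typical / 1
heavy cooking day (emission scaled 0.5/1/2 so the weekly mean equals the
level's nominal mass), combined by days/7 weighting.

Chronic exposure is the 24-h mean of the occupant's 144-interval series;
acute exposure the maximum hour-averaged value over the 139 *complete*
6-interval windows — windows never wrap around midnight, because the
modeled day is a standalone period, and "hour-averaged" fixes the window
statistic as the mean of six consecutive 10-min values. Occupant intervals
spent outdoors contribute zero stove NO₂ and the full outdoor tracer level
(i.e. outdoor air at the outdoor concentration). Exceedance fractions use
the indicator conc ≥ threshold, and convert to days/year by × 365; the
result is reported as a range over heavy-week prevalences of 10% and 5%.

## Aggregation

Floorplan weights per ZIP are proportional to the prevalence of each
housing cell (home type × floor-area class × stories × forced air), split
equally among floorplans sharing a cell; matching relaxes forced air, then
stories, but home type and area class must match (the synthetic generator
only emits cells its library covers). ZIP exposure is the normalized
double-weighted sum over floorplans and scenarios — the weights are
normalized, so no additional divisor is applied — with each ZIP mixing one
cold- and one warm-band distribution at 50/50 and the infiltration channel
scaled by the ZIP's outdoor NO₂. Whole-population (gas + electric) stove
means multiply the gas-household value by the gas-stove fraction, since
electric-stove households contribute zero; the package's own consistency
check (2.4 ppbv × 0.4 share against 7.7 ppbv outdoor ⇒ ≈10% of total) only
holds under multiplication, so the inverse "divide" form is offered as an
explicit option rather than the default. Counties and the nation are
population-weighted means of their ZIPs. Benchmark classification at a
long-term threshold (default 5.2 ppbv; 11, 53, and 100 ppbv also provided)
is three-way and exhaustive: outdoor alone exceeds / stove pushes the
total over / below even with the stove.

## Uncertainty

Two multiplicative Monte Carlo channels: stove = EF·|DR|·BI·(1−CE)·U,
outdoor = |DR|·(1−CE), one independent draw per factor per iteration
(default 10,000), percentiles (2.5, 50, 97.5) divided by the median so the
scaled median is exactly 1. Notes on deliberate choices:

- The decay-rate sampler is a skew normal with parameters solved
  numerically (three equations, three unknowns, quantile residuals) so the
  *median* is −0.86 h⁻¹ — "centered on" is read as the median, consistent
  with the median scaling step — and the central 95% interval is
  [−2.07, −0.17] h⁻¹. The anchors are asymmetric (heavier tail toward fast
  decay), giving shape ≈ −3.6.
- Decay draws are negative; the products use |DR|. Only relative
  dispersion survives the median scaling, so any consistent sign
  convention is equivalent, and |DR| keeps the multipliers positive.
- The outdoor channel includes (1 − CE) literally even though hood capture
  affecting outdoor-attributable exposure is physically surprising; it is
  part of the channel definition this package implements, and is flagged
  here rather than silently dropped.
- Whether cooking minutes U should scale acute as well as chronic exposure
  is ambiguous; the multipliers are applied to both (default), which is
  conservative for acute CIs.
- EF, CE, and U default samplers resample with replacement from synthetic
  empirical tables (lognormal-quantile tables with median 1 and modest
  spread for EF and U; a 64%-zeros + 0.1–0.8 spectrum for CE). These stand
  in for measured distributions that are not published as tables.

CI propagation through any monotone summary is component-wise (the lower
bound of a mean is the mean of lower bounds); a non-monotone summary
triggers a warning and a sort.

## Synthetic inputs: what they emulate and what they do not

The generators are first-class, tested code whose defaults *are* the study
conditions: outdoor NO₂ lognormal with median 4.9 / mean 7.7 ppbv
(σ² = 2 ln(mean/median)), sharing a latent normal with log population
density at ρ = 0.6 so the level-NO₂ ~ log-density regression lands near
r² ≈ 0.2; gas-stove share Beta with mean 0.40; multifamily and small-home
shares rising logistically with density; kitchen-occupancy minutes from a
split lognormal gluing two log-scale spreads at the median so the
5th/50th/95th percentiles hit 5/35/150 min/day exactly in distribution
(a single lognormal cannot, since 35/5 ≠ 150/35); hood-not-used
probabilities 0.64 (houses) and 0.72 (apartments); counties as contiguous
blocks of ~10 ZIPs. The floorplan library (default 24) spans the covered
home-type × area-class combos expanded over stories and forced air, with
volumes tied to floor area at 2.5 m ceilings.

What passing tests on these inputs show is that the *machinery* is correct
and calibrated to its anchors — not that any real geography's exposure is
reproduced. Real housing stock, spatially autocorrelated outdoor NO₂,
survey-derived behavior distributions, and the real floorplan library
would all shift the headline numbers; national summaries from the demo
pipeline are illustrative. Two visible consequences: infiltration
percentages here run ≈30% (decay 0.86 h⁻¹ against air exchange ≈0.3–0.6
h⁻¹), so outdoor-attributable exposure sits well below the outdoor
concentration; and with a single 48 mg/h burner, hour-averaged kitchen
concentrations only clear 100 ppbv in heavy-use scenarios, so exceedance
days/year at the default conditions are below estimates that assume
multi-burner events.

## Problem sizes and numerical notes

The demo pipeline uses 8 floorplans × 2 climate bands × 540-scenario
grids × 200 ZIPs with 5,000 Monte Carlo iterations — sizes chosen so a
full run completes in well under a minute while exercising every code
path; all sizes scale up through `PipelineConfig`. Linearity of the ODE is
exploited aggressively: hood capture and emission-rate scaling are applied
to simulated series post hoc, and occupancy weighting happens in
post-processing, so each floorplan/band needs 81 stove simulations and 9
tracer simulations rather than 2,160. Degenerate inputs are defined
errors, not silent results: disconnected floorplans, kitchens ≠ 1,
non-normalized weights, empty day sets, negative concentrations, and
unordered CI triples all raise. Tiny negative concentrations from
floating-point roundoff are clipped to zero at output.

## Known limitations

- No pressure-network airflow physics: wind direction, stack height, and
  envelope distribution effects are collapsed into one scalar driver.
- No spatial autocorrelation in the synthetic geography; counties are
  arbitrary contiguous blocks.
- The education/cooking-time adjustment, in-vehicle and workplace
  exposure, heaters, and pilot lights are out of scope.
- The Monte Carlo assumes exposure responds linearly to its input factors;
  it multiplies summary exposures rather than re-running the simulator per
  draw.
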