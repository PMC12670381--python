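"""Monte Carlo uncertainty multipliers and confidence-interval propagation.

Uncertainty in modeled exposure is summarized by two multiplicative Monte
Carlo distributions built from five input distributions — NO2 emission
factor (EF), indoor decay rate (DR), burner intensity (BI), the
model-to-measurement ratio / capture efficiency channel (CE), and cooking
minutes (U):

    MC_stove   = EF × |DR| × BI × (1 − CE) × U
    MC_outdoor = |DR| × (1 − CE)

Per iteration one value is drawn from each distribution with replacement;
across iterations the 2.5th/50th/97.5th percentiles are taken and divided
by the median so the scaled median is exactly 1. A scenario's central
exposure estimate is then multiplied by the scaled percentiles to form its
95% CI. This assumes exposure responds approximately linearly to the
inputs over their plausible ranges. (The sampled decay rates are negative;
the products use their magnitude, which the median scaling makes
equivalent to any consistent sign convention.)

The decay-rate distribution is a skew normal fitted so that its median is
−0.86 h⁻¹ and its central 95% of mass spans [−2.07, −0.17] h⁻¹, matching
the literature's central and bounding surface-loss rates.

Summary statistics over many geographies propagate CIs component-wise
(the lower bound of a mean of ZIPs is the mean of the lower bounds), valid
for any summary that is monotone in each argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

Sampler = Callable[[np.random.Generator, int], np.ndarray]

#: Literature anchors for the indoor NO2 decay rate, h⁻¹.
DECAY_MEDIAN = -0.86
DECAY_P025 = -2.07
DECAY_P975 = -0.17


class UncertaintyError(ValueError):
    pass


@dataclass(frozen=True)
class SkewNormalParams:
    shape: float
    loc: float
    scale: float

    def rvs(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return stats.skewnorm.rvs(self.shape, loc=self.loc, scale=self.scale, size=n, random_state=rng)


def fit_decay_skewnorm(
    median: float = DECAY_MEDIAN,
    lower: float = DECAY_P025,
    upper: float = DECAY_P975,
) -> SkewNormalParams:
    """Solve skew-normal parameters from three quantile anchors.

    Finds (shape, loc, scale) such that the 2.5th/50th/97.5th percentiles
    equal (lower, median, upper). The anchors are asymmetric about the
    median (the left tail toward faster decay is heavier), so the solved
    shape is negative.
    """
    if not lower < median < upper:
        raise UncertaintyError("quantile anchors must be ordered lower < median < upper")
    target = np.array([lower, median, upper])

    def resid(p):
        a, loc, log_scale = p
        q = stats.skewnorm.ppf([0.025, 0.5, 0.975], a, loc=loc, scale=np.exp(log_scale))
        return q - target

    span = upper - lower
    sol = optimize.least_squares(
        resid, x0=[-2.0, median + 0.3 * span, np.log(span / 4.0)], xtol=1e-14, ftol=1e-14
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise UncertaintyError(f"skew-normal quantile solve failed: {sol.message}")
    return SkewNormalParams(shape=float(sol.x[0]), loc=float(sol.x[1]), scale=float(np.exp(sol.x[2])))


def sample_decay(n: int, seed: int | np.random.Generator, params: SkewNormalParams | None = None) -> np.ndarray:
    """Draw ``n`` indoor decay rates (h⁻¹, negative) from the fitted skew normal."""
    if n <= 0:
        raise UncertaintyError("n must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = params or fit_decay_skewnorm()
    return params.rvs(rng, n)


# ---------------------------------------------------------------------------
# Input distributions and multipliers
# ---------------------------------------------------------------------------

def empirical_sampler(values: Sequence[float]) -> Sampler:
    """Resample-with-replacement sampler over an empirical table."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise UncertaintyError("empirical table is empty")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(arr, size=n, replace=True)

    return sample


def constant_sampler(value: float) -> Sampler:
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, float(value))

    return sample


def truncated_normal_sampler(mean: float, sd: float, low: float, high: float) -> Sampler:
    """Normal sampler with rejection outside (low, high]."""

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(mean, sd, size=2 * (n - filled))
            ok = draw[(draw > low) & (draw <= high)]
            take = min(ok.size, n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out

    return sample


@dataclass
class McInputDistributions:
    """The five input samplers for the multiplicative Monte Carlo.

    Defaults: emission factor and cooking minutes resampled from synthetic
    empirical tables (relative, median ≈ 1); decay rate from the fitted
    skew normal; burner intensity normal(0.5, 0.1) truncated to (0, 1];
    capture efficiency an empirical table on [0, 1].
    """

    emission_factor: Sampler
    decay_rate: Sampler
    burner_intensity: Sampler
    capture_efficiency: Sampler
    cooking_minutes: Sampler

    @classmethod
    def defaults(
        cls,
        emission_factor_table: Sequence[float] | None = None,
        capture_efficiency_table: Sequence[float] | None = None,
        cooking_minutes_table: Sequence[float] | None = None,
    ) -> "McInputDistributions":
        params = fit_decay_skewnorm()
        # synthetic empirical spreads (relative scales, median ~ 1)
        ef = emission_factor_table if emission_factor_table is not None else _default_ef_table()
        ce = capture_efficiency_table if capture_efficiency_table is not None else _default_ce_table()
        u = cooking_minutes_table if cooking_minutes_table is not None else _default_u_table()
        return cls(
            emission_factor=empirical_sampler(ef),
            decay_rate=lambda rng, n: params.rvs(rng, n),
            burner_intensity=truncated_normal_sampler(0.5, 0.1, 0.0, 1.0),
            capture_efficiency=empirical_sampler(ce),
            cooking_minutes=empirical_sampler(u),
        )


def _default_ef_table() -> np.ndarray:
    """Synthetic relative emission-factor spread (lognormal, median 1,
    ±~30% central 95%), standing in for measured per-stove emission factors."""
    q = np.linspace(0.02, 0.98, 49)
    return np.exp(stats.norm.ppf(q, loc=0.0, scale=0.15))


def _default_ce_table() -> np.ndarray:
    """Synthetic hood capture-efficiency spectrum: hoods unused ~64% of the
    time (CE 0), the rest spread over installed-hood efficiencies 0.1-0.8."""
    return np.concatenate([np.zeros(16), np.linspace(0.1, 0.8, 9)])


def _default_u_table() -> np.ndarray:
    """Synthetic relative cooking-minute spread (lognormal, median 1,
    right-skewed), standing in for monitored cooktop-use minutes."""
    q = np.linspace(0.02, 0.98, 49)
    return np.exp(stats.norm.ppf(q, loc=0.0, scale=0.30))


@dataclass(frozen=True)
class McMultipliers:
    """Median-scaled (p2.5, p50, p97.5) multipliers per channel."""

    stove: Tuple[float, float, float]
    outdoor: Tuple[float, float, float]
    iterations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for ch in (self.stove, self.outdoor):
            lo, med, hi = ch
            if abs(med - 1.0) > 1e-12:
                raise UncertaintyError("scaled median must equal 1")
            if not lo <= med <= hi:
                raise UncertaintyError("multiplier percentiles must be ordered")

    @classmethod
    def unit(cls) -> "McMultipliers":
        return cls(stove=(1.0, 1.0, 1.0), outdoor=(1.0, 1.0, 1.0), iterations=0)


def mc_multipliers(
    dists: McInputDistributions,
    iterations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> McMultipliers:
    """Run the multiplicative Monte Carlo and scale percentiles by the median.

    Stove channel: EF × |DR| × BI × (1 − CE) × U. Outdoor channel:
    |DR| × (1 − CE). Percentiles (2.5, 50, 97.5) of each product are
    divided by the product's median, so the central multiplier is 1 and the
    outer two bound the 95% CI.
    """
    if iterations < 1000:
        raise UncertaintyError("need at least 1000 iterations for stable percentiles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ef = dists.emission_factor(rng, iterations)
    dr = np.abs(dists.decay_rate(rng, iterations))
    bi = dists.burner_intensity(rng, iterations)
    ce = dists.capture_efficiency(rng, iterations)
    u = dists.cooking_minutes(rng, iterations)

    stove = ef * dr * bi * (1.0 - ce) * u
    outdoor = dr * (1.0 - ce)
    channels = {}
    for name, product in (("stove", stove), ("outdoor", outdoor)):
        med = float(np.median(product))
        if med == 0:
            raise UncertaintyError(f"degenerate {name} product: median 0")
        lo, med_, hi = np.percentile(product, [2.5, 50.0, 97.5])
        channels[name] = (float(lo / med), 1.0, float(hi / med))
    return McMultipliers(
        stove=channels["stove"],
        outdoor=channels["outdoor"],
        iterations=iterations,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


# ---------------------------------------------------------------------------
# Confidence-interval propagation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CIValue:
    """(lower, central, upper) exposure triple, ppbv."""

    lower: float
    central: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.central <= self.upper:
            raise UncertaintyError(
                f"CI not ordered: {self.lower} <= {self.central} <= {self.upper} fails"
            )

    def scale(self, factor: float) -> "CIValue":
        if factor < 0:
            raise UncertaintyError("scale factor must be >= 0")
        return CIValue(self.lower * factor, self.central * factor, self.upper * factor)

    def __add__(self, other: "CIValue") -> "CIValue":
        return CIValue(self.lower + other.lower, self.central + other.central, self.upper + other.upper)


def apply_ci(central: float, channel: Tuple[float, float, float]) -> CIValue:
    """Multiply a central estimate by a median-scaled multiplier triple."""
    if central < 0:
        raise UncertaintyError("central estimate must be >= 0")
    lo, med, hi = channel
    return CIValue(central * lo / med, central, central * hi / med)


def summarize_ci(
    f: Callable[[np.ndarray], float], values: Sequence[CIValue]
) -> CIValue:
    """Apply a monotone summary component-wise to lowers/centrals/uppers."""
    if not values:
        raise UncertaintyError("no CI values to summarize")
    lowers = np.array([v.lower for v in values])
    centrals = np.array([v.central for v in values])
    uppers = np.array([v.upper for v in values])
    lo, mid, hi = float(f(lowers)), float(f(centrals)), float(f(uppers))
    if not lo <= mid <= hi:
        # component-wise propagation is only valid for monotone summaries
        warnings.warn("summary function does not appear monotone; CI ordering violated")
        lo, mid, hi = sorted((lo, mid, hi))
    return CIValue(lo, mid, hi)
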