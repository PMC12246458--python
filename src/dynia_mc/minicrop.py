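"""minicrop — a daily-step, water-driven surrogate crop model.

minicrop is a deliberately small wheat-like simulator built around the
mechanisms that water-driven canopy models share: thermal-time phenology,
logistic canopy-cover growth throttled by a threshold-and-shape water-stress
coefficient, transpiration proportional to canopy cover, a single soil water
bucket, biomass accumulation through normalised water productivity (WP*),
and a harvest index that builds up after flowering.  It is NOT a
reimplementation of any particular crop model; its update rules are the
simplest forms consistent with that mechanism list, and it exists to provide
a fast, fully-known ground truth for the Monte-Carlo / DYNIA / GLUE
machinery in this package.

The parameter vocabulary follows the 47-entry wheat registry (X1–X47).
A documented subset is deliberately inert (salinity, pollination, aeration,
CO2 response …): those parameters are accepted and ignored, giving the
sensitivity analyses known negative controls.

All state updates are expressed with numpy ufuncs, so a parameter value may
be a scalar or an ``(n,)`` array — passing arrays simulates an entire
Monte-Carlo ensemble in one vectorised sweep over days.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .parameter_space import ParameterRegistry

__all__ = [
    "CHANNELS",
    "ACTIVE_PARAMETERS",
    "INERT_PARAMETERS",
    "WeatherSeries",
    "WeatherDay",
    "SoilBucket",
    "CropState",
    "DailyFluxes",
    "SimulationOutput",
    "generate_weather",
    "stress_coefficient",
    "step_day",
    "simulate",
    "simulate_ensemble",
    "reference_parameters",
]

#: The five harvested output channels of the crop use-case.
CHANNELS = (
    "soil_evaporation",
    "transpiration",
    "evapotranspiration",
    "biomass",
    "yield",
)

#: Registry names the simulator actually reads.
ACTIVE_PARAMETERS = (
    "X2", "X3",            # base / upper temperature for thermal time
    "X4", "X5", "X6",      # canopy-expansion stress thresholds + shape
    "X7", "X8",            # stomatal-closure stress threshold + shape
    "X9", "X10",           # early-senescence stress threshold + shape
    "X18",                 # crop transpiration coefficient KcTr
    "X20", "X21", "X22",   # rooting depth min/max + expansion shape
    "X26", "X28",          # seedling cover x plant density -> initial CC
    "X29", "X30",          # canopy growth coefficient CGC, max cover CCx
    "X31",                 # normalised water productivity WP*
    "X34",                 # reference harvest index HIo
    "X39", "X40", "X41", "X42", "X43",  # GDD milestones
    "X46",                 # canopy decline coefficient CDC
    "X47",                 # GDD span of harvest-index build-up
)

#: Registry names accepted but ignored — negative controls by construction.
#: (X13/X14/X44 join the active set only when cold/heat pollination stress
#: is switched on, which is off by default.)
INERT_PARAMETERS = (
    "X1", "X11", "X12", "X13", "X14", "X15", "X16", "X17",
    "X19", "X23", "X24", "X25", "X27", "X32", "X33", "X35",
    "X36", "X37", "X38", "X44", "X45",
)

KE_SOIL = 1.1          # bare-soil evaporation coefficient (mm/mm ETo)
EVAP_LAYER_M = 0.15    # surface layer feeding soil evaporation
STRESS_SENESCENCE = 0.05  # max extra daily relative canopy loss under drought
ROOT_SHAPE_REF = 15.0  # registry X22 value at which root expansion is linear


# --------------------------------------------------------------------------
# weather
# --------------------------------------------------------------------------

@dataclass
class WeatherSeries:
    """Daily forcing: reference ET, rain and temperature extremes."""

    eto: np.ndarray   # mm/day
    rain: np.ndarray  # mm/day
    tmin: np.ndarray  # degC
    tmax: np.ndarray  # degC

    def __post_init__(self) -> None:
        self.eto = np.asarray(self.eto, dtype=float)
        self.rain = np.asarray(self.rain, dtype=float)
        self.tmin = np.asarray(self.tmin, dtype=float)
        self.tmax = np.asarray(self.tmax, dtype=float)
        n = len(self.eto)
        if not (len(self.rain) == len(self.tmin) == len(self.tmax) == n):
            raise ValueError("weather arrays must share one length")
        if n < 1:
            raise ValueError("weather series must cover at least one day")
        if np.any(self.eto <= 0):
            raise ValueError("ETo must be strictly positive")
        if np.any(self.rain < 0):
            raise ValueError("rain must be non-negative")
        if np.any(self.tmin > self.tmax):
            raise ValueError("Tmin must not exceed Tmax")

    @property
    def n_days(self) -> int:
        return len(self.eto)

    def day(self, i: int) -> "WeatherDay":
        return WeatherDay(
            eto=float(self.eto[i]),
            rain=float(self.rain[i]),
            tmin=float(self.tmin[i]),
            tmax=float(self.tmax[i]),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["day", "eto_mm", "rain_mm", "tmin_c", "tmax_c"])
        for i in range(self.n_days):
            w.writerow(
                [i + 1, repr(float(self.eto[i])), repr(float(self.rain[i])),
                 repr(float(self.tmin[i])), repr(float(self.tmax[i]))]
            )
        path.write_text(buf.getvalue())
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeatherSeries":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = {"eto_mm": [], "rain_mm": [], "tmin_c": [], "tmax_c": []}
            for row in reader:
                for c in cols:
                    cols[c].append(float(row[c]))
        return cls(cols["eto_mm"], cols["rain_mm"], cols["tmin_c"], cols["tmax_c"])


@dataclass(frozen=True)
class WeatherDay:
    eto: float
    rain: float
    tmin: float
    tmax: float


_PRESETS = {
    # (rain probability early/late season, mean event depth mm)
    "semi_arid": (0.25, 0.06, 5.0),
    "no_rain": (0.0, 0.0, 0.0),
    "wet": (0.55, 0.35, 8.0),
}


def generate_weather(
    n_days: int, seed: int, climate_preset: str = "semi_arid"
) -> WeatherSeries:
    """Synthesise a winter-wheat season of daily forcing.

    The season starts at autumn sowing (around mid November), passes through
    a cool winter and warms into early summer, so thermal time accumulates
    slowly at first and quickly near maturity.  ``semi_arid`` concentrates
    sparse rain in winter/spring (~250 mm/season) so water stress is
    reachable; ``no_rain`` zeroes precipitation; ``wet`` keeps the crop close
    to well-watered.  Deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if climate_preset not in _PRESETS:
        raise ValueError(
            f"unknown climate preset {climate_preset!r}; choose from {sorted(_PRESETS)}"
        )
    p_early, p_late, rain_mean = _PRESETS[climate_preset]
    rng = np.random.default_rng(seed)

    d = np.arange(n_days)
    doy = (320 + d) % 365  # sowing ~ day-of-year 320
    tavg = 15.0 - 9.0 * np.cos(2 * np.pi * (doy - 15) / 365)
    tavg = tavg + rng.normal(0.0, 2.0, n_days)
    trange = np.clip(10.0 + rng.normal(0.0, 2.0, n_days), 4.0, None)
    tmin = tavg - trange / 2
    tmax = tavg + trange / 2

    eto = 0.8 + 0.24 * np.maximum(tavg, 0.0) + rng.normal(0.0, 0.3, n_days)
    eto = np.clip(eto, 0.3, None)

    p_rain = np.where(d < int(0.75 * n_days), p_early, p_late)
    wet_day = rng.random(n_days) < p_rain
    amounts = rng.exponential(rain_mean, n_days) if rain_mean > 0 else np.zeros(n_days)
    rain = np.where(wet_day, amounts, 0.0)
    return WeatherSeries(eto=eto, rain=rain, tmin=tmin, tmax=tmax)


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class SoilBucket:
    """Single-layer water bucket over the maximum rooting depth.

    ``water_content`` is the volumetric water fraction (vol%) assumed uniform
    over ``depth_m``; ``root_depth_m`` is the current effective rooting depth
    and only limits how much water transpiration can extract per day.
    """

    field_capacity: float = 28.0   # vol%
    wilting_point: float = 12.0    # vol%
    saturation: float = 42.0       # vol%
    depth_m: float = 1.5           # bucket depth (fixed, = max rooting depth)
    water_content: float | np.ndarray = 28.0  # vol%
    root_depth_m: float | np.ndarray = 0.3

    def __post_init__(self) -> None:
        if not (self.wilting_point < self.field_capacity < self.saturation):
            raise ValueError("need wilting point < field capacity < saturation")
        if np.any(np.asarray(self.water_content) < 0) or np.any(
            np.asarray(self.water_content) > self.saturation
        ):
            raise ValueError("water content must lie in [0, saturation]")

    @property
    def storage_mm(self) -> float | np.ndarray:
        """Water stored in the bucket (mm); vol% x depth(m) x 10."""
        return self.water_content * self.depth_m * 10.0


@dataclass
class CropState:
    """Canopy, biomass, thermal time and harvest index."""

    cc: float | np.ndarray = 0.0        # canopy cover fraction
    biomass: float | np.ndarray = 0.0   # g/m2, cumulative
    gdd: float | np.ndarray = 0.0       # degC day, cumulative
    hi: float | np.ndarray = 0.0        # harvest index fraction

    @property
    def grain_yield(self) -> float | np.ndarray:
        return self.hi * self.biomass


@dataclass(frozen=True)
class DailyFluxes:
    """Water fluxes of one simulated day (all mm)."""

    soil_evaporation: float | np.ndarray
    transpiration: float | np.ndarray
    drainage: float | np.ndarray
    irrigation: float | np.ndarray = 0.0

    @property
    def et(self) -> float | np.ndarray:
        return self.soil_evaporation + self.transpiration


# --------------------------------------------------------------------------
# process functions
# --------------------------------------------------------------------------

def stress_coefficient(relative_depletion, shape):
    """Water-stress multiplier Ks in [0, 1].

    ``relative_depletion`` D is the position between the process's upper
    threshold (D=0, stress-free) and lower threshold (D=1, full stress);
    inputs are clipped into [0, 1].  A shape of 0 gives the straight line
    ``Ks = 1 - D``; otherwise ``Ks = 1 - (exp(f*D) - 1)/(exp(f) - 1)``,
    convex for f > 0 (stress bites late) and concave for f < 0.
    """
    d = np.clip(np.asarray(relative_depletion, dtype=float), 0.0, 1.0)
    f = np.asarray(shape, dtype=float)
    safe_f = np.where(f == 0.0, 1.0, f)
    curved = 1.0 - np.expm1(safe_f * d) / np.expm1(safe_f)
    out = np.where(f == 0.0, 1.0 - d, curved)
    if out.ndim == 0:
        return float(out)
    return out


def _relative_depletion(depletion_fraction, upper, lower):
    span = np.maximum(np.asarray(lower, dtype=float) - upper, 1e-9)
    return np.clip((depletion_fraction - upper) / span, 0.0, 1.0)


def _require(params: Mapping[str, float | np.ndarray], *names: str):
    for n in names:
        if n not in params:
            raise KeyError(f"missing required parameter {n!r}")
    return [np.asarray(params[n], dtype=float) for n in names]


def step_day(
    state: CropState,
    soil: SoilBucket,
    params: Mapping[str, float | np.ndarray],
    weather_day: WeatherDay,
    irrigated: bool = False,
) -> tuple[CropState, SoilBucket, DailyFluxes]:
    """Advance the crop/soil system by one day.

    Update order: thermal time; canopy growth or decline (stress-modulated);
    transpiration and soil evaporation demands capped by extractable water;
    soil bucket (+rain/irrigation, -E, -Tr, drainage of excess above field
    capacity); biomass through WP*; harvest-index build-up after flowering.
    All arithmetic is elementwise, so parameter arrays advance a whole
    ensemble at once.
    """
    for v in (weather_day.eto, weather_day.rain, weather_day.tmin, weather_day.tmax):
        if not np.isfinite(v):
            raise ValueError("weather inputs must be finite")
    (tbase, tupper, p_exp_up, p_exp_lo, f_exp, p_sto, f_sto, p_sen, f_sen,
     kctr, zmin, zmax, zshape, seed_cm2, plants_ha, cgc, ccx, wpstar, hio,
     gdd_emerge, gdd_maxroot, gdd_sen, gdd_mat, gdd_flower, cdc, hi_gdd) = _require(
        params,
        "X2", "X3", "X4", "X5", "X6", "X7", "X8", "X9", "X10",
        "X18", "X20", "X21", "X22", "X26", "X28", "X29", "X30", "X31", "X34",
        "X39", "X40", "X41", "X42", "X43", "X46", "X47",
    )
    eto, rain = weather_day.eto, weather_day.rain
    fc, wp = soil.field_capacity, soil.wilting_point
    depth = soil.depth_m

    # (0) optional irrigation: refill to field capacity before anything else
    theta = np.asarray(soil.water_content, dtype=float)
    if irrigated:
        irrigation = np.maximum(0.0, fc - theta) * depth * 10.0
        theta = np.maximum(theta, fc)
    else:
        irrigation = np.zeros_like(theta) if theta.ndim else 0.0

    # (1) thermal time
    tavg = 0.5 * (weather_day.tmin + weather_day.tmax)
    dgdd = np.maximum(0.0, np.minimum(tupper, tavg) - tbase)
    gdd = state.gdd + dgdd

    # (2) stress state from start-of-day depletion
    depl = np.clip((fc - theta) / (fc - wp), 0.0, 1.0)
    ks_exp = stress_coefficient(_relative_depletion(depl, p_exp_up, p_exp_lo), f_exp)
    ks_sto = stress_coefficient(_relative_depletion(depl, p_sto, 1.0), f_sto)
    ks_sen = stress_coefficient(_relative_depletion(depl, p_sen, 1.0), f_sen)

    # (3) canopy cover: logistic growth before the senescence milestone,
    #     exponential decline after, drought-accelerated senescence always
    cc0 = seed_cm2 * plants_ha / 1e8  # cm2/plant x plants/ha over 1e8 cm2/ha
    emerged = gdd >= gdd_emerge
    senescing = gdd >= gdd_sen
    cc = np.maximum(state.cc, cc0 * (emerged & ~senescing))
    growth = cgc * ks_exp * cc * (1.0 - cc / ccx)
    declined = cc * np.clip(1.0 - cdc * dgdd, 0.0, 1.0)
    cc = np.where(senescing, declined, cc + growth)
    cc = cc * (1.0 - STRESS_SENESCENCE * (1.0 - ks_sen))
    cc = np.clip(cc, 0.0, ccx)

    # (4) root depth from thermal time (shape-skewed interpolation)
    frac = np.clip(gdd / np.maximum(gdd_maxroot, 1.0), 0.0, 1.0)
    zr = zmin + (zmax - zmin) * frac ** (zshape / ROOT_SHAPE_REF)
    zr = np.minimum(np.where(emerged, zr, zmin), depth)

    # (5) water fluxes: demand then supply cap (uniform-profile assumption)
    mature = gdd >= gdd_mat
    tr_demand = ks_sto * kctr * cc * eto * ~mature
    e_demand = KE_SOIL * (1.0 - cc) * eto
    tr_cap = np.maximum(0.0, theta - wp) * zr * 10.0
    e_cap = np.maximum(0.0, theta - 0.5 * wp) * EVAP_LAYER_M * 10.0
    tr = np.minimum(tr_demand, tr_cap)
    e = np.minimum(e_demand, e_cap)

    # (6) bucket update; excess above field capacity drains
    storage = theta * depth * 10.0 + rain + irrigation - e - tr
    drainage = np.maximum(0.0, storage - fc * depth * 10.0)
    storage = storage - drainage
    theta_new = storage / (depth * 10.0)

    # (7) biomass through normalised water productivity
    biomass = state.biomass + wpstar * (tr / eto)

    # (8) harvest index builds linearly over hi_gdd thermal time past flowering
    building = (gdd > gdd_flower) & ~mature
    hi = np.clip(
        state.hi + (hio / 100.0) * (dgdd / np.maximum(hi_gdd, 1.0)) * building,
        0.0,
        hio / 100.0,
    )

    new_state = CropState(cc=cc, biomass=biomass, gdd=gdd, hi=hi)
    new_soil = replace(soil, water_content=theta_new, root_depth_m=zr)
    fluxes = DailyFluxes(
        soil_evaporation=e, transpiration=tr, drainage=drainage,
        irrigation=irrigation,
    )
    return new_state, new_soil, fluxes


# --------------------------------------------------------------------------
# season driver
# --------------------------------------------------------------------------

@dataclass
class SimulationOutput:
    """Daily channels plus end-of-season scalars and water-balance terms."""

    time: np.ndarray                       # day index, 1-based
    channels: dict[str, np.ndarray]        # each (T,) or (T, n)
    storage: np.ndarray                    # end-of-day bucket storage, mm
    drainage: np.ndarray
    irrigation: np.ndarray
    initial_storage: float | np.ndarray
    canopy: np.ndarray | None = None       # daily canopy cover fraction

    @property
    def biomass_at_maturity(self):
        return self.channels["biomass"][-1]

    @property
    def grain_yield(self):
        return self.channels["yield"][-1]


def simulate(
    params: Mapping[str, float | np.ndarray],
    weather: WeatherSeries,
    soil: SoilBucket | None = None,
    irrigated: bool = False,
) -> SimulationOutput:
    """Run a full season and emit the five output channels day by day.

    ``params`` must contain every name in :data:`ACTIVE_PARAMETERS`
    (a missing one is rejected by name); entries from
    :data:`INERT_PARAMETERS` and any others are accepted and ignored.
    Values may be scalars or equal-length arrays (vectorised ensemble).
    Deterministic: identical inputs give identical output.
    """
    _require(params, *ACTIVE_PARAMETERS)
    shape = np.broadcast_shapes(
        *[np.asarray(params[n], dtype=float).shape for n in ACTIVE_PARAMETERS]
    )
    if soil is None:
        soil = SoilBucket()
    state = CropState(
        cc=np.zeros(shape), biomass=np.zeros(shape), gdd=np.zeros(shape),
        hi=np.zeros(shape),
    )
    soil = replace(
        soil,
        water_content=np.broadcast_to(
            np.asarray(soil.water_content, dtype=float), shape
        ).copy(),
        root_depth_m=np.broadcast_to(
            np.asarray(soil.root_depth_m, dtype=float), shape
        ).copy(),
    )
    initial_storage = np.array(soil.storage_mm, copy=True)

    T = weather.n_days
    chan = {c: [] for c in CHANNELS}
    storage, drain, irrig, canopy = [], [], [], []
    for i in range(T):
        state, soil, fx = step_day(state, soil, params, weather.day(i), irrigated)
        chan["soil_evaporation"].append(fx.soil_evaporation)
        chan["transpiration"].append(fx.transpiration)
        chan["evapotranspiration"].append(fx.et)
        chan["biomass"].append(state.biomass)
        chan["yield"].append(state.grain_yield)
        storage.append(soil.storage_mm)
        drain.append(fx.drainage)
        irrig.append(fx.irrigation)
        canopy.append(state.cc)

    squeeze = shape == ()
    def stack(xs):
        a = np.array(xs)
        return a if not squeeze else a.reshape(T)

    return SimulationOutput(
        time=np.arange(1, T + 1),
        channels={c: stack(v) for c, v in chan.items()},
        storage=stack(storage),
        drainage=stack(drain),
        irrigation=stack(irrig),
        initial_storage=initial_storage if not squeeze else float(initial_storage),
        canopy=stack(canopy),
    )


def simulate_ensemble(
    samples,
    weather: WeatherSeries,
    soil: SoilBucket | None = None,
    irrigated: bool = False,
) -> np.ndarray:
    """Simulate every row of a sample matrix in one vectorised sweep.

    Returns an ``(n_runs, n_days, n_channels)`` array with channels in
    :data:`CHANNELS` order.
    """
    params = {
        name: samples.column(name) for name in samples.column_names
    }
    out = simulate(params, weather, soil=soil, irrigated=irrigated)
    # channels are (T, n): reorder to (n, T, c)
    arr = np.stack([out.channels[c] for c in CHANNELS], axis=-1)  # (T, n, C)
    return np.moveaxis(arr, 0, 1)


def reference_parameters(registry: ParameterRegistry) -> dict[str, float]:
    """A 'true' parameter set at the centre of the registry bounds."""
    return registry.midpoint()
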