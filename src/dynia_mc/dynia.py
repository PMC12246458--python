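"""Dynamic Identifiability Analysis (DYNIA).

DYNIA turns a Monte-Carlo ensemble into a *time-resolved* picture of
parameter influence.  At every time step t an objective (MAE or RMSE of the
residuals against observations) is evaluated over a moving window of
+/- w steps; the best-fitting fraction q of runs forms the *support set*;
each parameter's support values are binned into M equal-width containers
over its prior range, giving a conditional density p(m, t).  From the
density come

* a gradient matrix ``G[m, t] = p[m, t] * M`` — the density ratio against
  the uniform prior, the quantity shaded in time-parameter diagrams;
* the Identifiability Index ``IDI(t)``, here the total-variation distance of
  p(., t) from uniform rescaled to [0, 1] (0 = unconstrained, 1 = all
  support mass in one container);
* percentile confidence limits of the support values (default 5th/95th) and
  the information content ``IC(t) = 1 - (CL width)/(prior width)``, which
  rises when the data pin the parameter down.

Only the marginal distribution of each parameter is examined; parameter
interaction is outside the method's reach.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .parameter_space import ParameterRegistry, SampleMatrix
from .treatment_runner import Ensemble

__all__ = [
    "DyniaConfig",
    "ObjectiveMatrix",
    "ParameterIdentifiability",
    "DyniaResult",
    "windowed_objective",
    "select_support",
    "container_density",
    "idi",
    "confidence_limits",
    "run_dynia",
    "ic_noise_band",
]

logger = logging.getLogger(__name__)

_METRICS = ("mae", "rmse")


@dataclass(frozen=True)
class DyniaConfig:
    """Knobs of the analysis.

    window
        half-width w of the moving window in time steps (the objective at t
        covers [t-w, t+w], truncated at the record's ends).
    support_fraction
        fraction q of runs kept as the support set (ceil(q*N), so q > 0
        never yields an empty set).
    containers
        number M of equal-width bins over each parameter's prior range.
    metric
        "mae" or "rmse" residual metric inside the window.
    percentiles
        confidence-limit percentiles of the support values (5/95 = 90% CL).
    """

    window: int = 10
    support_fraction: float = 0.10
    containers: int = 20
    metric: str = "mae"
    percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window half-width must be >= 0")
        if not (0 < self.support_fraction <= 1):
            raise ValueError("support fraction must be in (0, 1]")
        if self.containers < 2:
            raise ValueError("need at least 2 containers")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")


@dataclass
class ObjectiveMatrix:
    """Runs x time matrix of windowed residual errors."""

    values: np.ndarray
    metric: str
    window: int


def windowed_objective(
    simulated: np.ndarray,
    observed: np.ndarray,
    window: int = 10,
    metric: str = "mae",
) -> ObjectiveMatrix:
    """Residual error of every run over a moving +/- ``window`` steps.

    Entry (r, t) aggregates |sim_r - obs| (MAE) or the RMS residual (RMSE)
    over time indices [t-w, t+w] clipped to the record; windows are
    truncated at the boundaries, never padded.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.ndim != 2:
        raise ValueError("simulated must be a runs x time matrix")
    if obs.shape != (sim.shape[1],):
        raise ValueError(
            f"observed length {obs.shape} does not match ensemble time axis "
            f"{sim.shape[1]}"
        )
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    resid = np.abs(sim - obs)
    if metric == "rmse":
        resid = resid**2
    n, T = sim.shape
    out = np.empty((n, T))
    for t in range(T):
        lo, hi = max(0, t - window), min(T, t + window + 1)
        out[:, t] = resid[:, lo:hi].mean(axis=1)
    if metric == "rmse":
        out = np.sqrt(out)
    return ObjectiveMatrix(values=out, metric=metric, window=window)


def select_support(objective_column: np.ndarray, support_fraction: float) -> np.ndarray:
    """Indices of the ceil(q*N) best (smallest-error) runs, stably tie-broken.

    Ties at the cut are resolved by ascending run index (mergesort), so the
    selection is deterministic.
    """
    col = np.asarray(objective_column, dtype=float)
    if not (0 < support_fraction <= 1):
        raise ValueError("support fraction must be in (0, 1]")
    finite = np.isfinite(col)
    k = ceil(support_fraction * col.size)
    if finite.sum() < k:
        raise ValueError(
            f"need at least {k} finite objective values, have {int(finite.sum())}"
        )
    order = np.argsort(np.where(finite, col, np.inf), kind="stable")
    return order[:k]


def container_density(
    values: np.ndarray, lower: float, upper: float, containers: int
) -> np.ndarray:
    """Fraction of support values per equal-width bin over [lower, upper].

    Bins are half-open except the last, which is closed, so ``upper`` itself
    counts.  Values outside the bounds are clipped with a warning.  The
    result is the per-bin increment of the empirical CDF and sums to 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty support set")
    if not lower < upper:
        raise ValueError(
            "constant parameter (lower == upper) has no identifiability"
        )
    if np.any((v < lower) | (v > upper)):
        warnings.warn("support values outside prior bounds were clipped")
        v = np.clip(v, lower, upper)
    width = (upper - lower) / containers
    idx = np.minimum(((v - lower) / width).astype(int), containers - 1)
    counts = np.bincount(idx, minlength=containers)
    return counts / v.size


def idi(density: np.ndarray) -> float:
    """Identifiability Index of one container density.

    Rescaled total-variation distance from the uniform density:
    ``IDI = [0.5 * sum_m |p_m - 1/M|] * M / (M - 1)``, which is 0 exactly at
    uniformity and 1 for a point mass in a single container.
    """
    p = np.asarray(density, dtype=float)
    m = p.size
    if m < 2:
        raise ValueError("density needs at least 2 containers")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"density sums to {p.sum()!r}, not 1")
    return float(0.5 * np.abs(p - 1.0 / m).sum() * m / (m - 1))


def gradient(density: np.ndarray) -> np.ndarray:
    """Per-container density ratio against uniform, G_m = p_m * M."""
    p = np.asarray(density, dtype=float)
    return p * p.size


def confidence_limits(
    values: np.ndarray,
    lower: float,
    upper: float,
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> tuple[float, float, float]:
    """Percentile confidence limits of the support values and their IC.

    Returns ``(cl_low, cl_high, ic)`` with linear-interpolation percentiles
    and ``ic = 1 - (cl_high - cl_low)/(upper - lower)`` clipped to [0, 1]:
    narrow limits (concentrated support) give IC near 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty support set")
    cl_low, cl_high = np.percentile(v, percentiles)
    cl_low = float(np.clip(cl_low, lower, upper))
    cl_high = float(np.clip(cl_high, lower, upper))
    ic = float(np.clip(1.0 - (cl_high - cl_low) / (upper - lower), 0.0, 1.0))
    return cl_low, cl_high, ic


@dataclass
class ParameterIdentifiability:
    """Time-resolved identifiability of one parameter."""

    name: str
    density: np.ndarray    # (M, T) container densities
    gradient: np.ndarray   # (M, T) density ratios vs uniform
    idi: np.ndarray        # (T,)
    cl_low: np.ndarray     # (T,) in parameter units
    cl_high: np.ndarray    # (T,)
    ic: np.ndarray         # (T,) information content in [0, 1]


@dataclass
class DyniaResult:
    """Full analysis output: per-parameter series plus shared machinery."""

    parameters: dict[str, ParameterIdentifiability]
    objective: ObjectiveMatrix
    support: np.ndarray          # (support size, T) run indices
    time: np.ndarray
    config: DyniaConfig
    skipped: list[str] = field(default_factory=list)

    def save(self, directory: str | Path) -> Path:
        """Per-parameter CSV (time, IDI, CLs, IC) + density matrix CSV."""
        import csv as _csv
        import io as _io
        import json as _json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, pr in self.parameters.items():
            buf = _io.StringIO()
            w = _csv.writer(buf, lineterminator="\n")
            w.writerow(["time", "idi", "cl_low", "cl_high", "ic"])
            for i, t in enumerate(self.time):
                w.writerow([repr(float(t))] + [
                    repr(float(x[i]))
                    for x in (pr.idi, pr.cl_low, pr.cl_high, pr.ic)
                ])
            (directory / f"dynia_{name}.csv").write_text(buf.getvalue())
            buf = _io.StringIO()
            w = _csv.writer(buf, lineterminator="\n")
            for row in pr.density:
                w.writerow([repr(float(v)) for v in row])
            (directory / f"density_{name}.csv").write_text(buf.getvalue())
        (directory / "dynia.json").write_text(
            _json.dumps(
                {
                    "window": self.config.window,
                    "support_fraction": self.config.support_fraction,
                    "containers": self.config.containers,
                    "metric": self.config.metric,
                    "percentiles": list(self.config.percentiles),
                    "parameters": sorted(self.parameters),
                    "skipped": self.skipped,
                },
                indent=2,
            )
            + "\n"
        )
        return directory


def run_dynia(
    ensemble: Ensemble | np.ndarray,
    observed: np.ndarray | Mapping[str, np.ndarray],
    samples: SampleMatrix,
    registry: ParameterRegistry,
    config: DyniaConfig = DyniaConfig(),
    variable: str = "yield",
    parameters: Sequence[str] | None = None,
) -> DyniaResult:
    """The full DYNIA procedure over one or several output variables.

    ``ensemble`` is either an :class:`Ensemble` (sliced at ``variable``) or
    a raw runs x time matrix; its runs must align with the sample-matrix
    rows (an Ensemble's ``run_ids`` — 1-based treatment ids — select the
    rows, so failed runs drop out naturally).

    ``observed`` may be a single series, or a mapping of variable names to
    series for *joint multi-output conditioning*: each variable's windowed
    objective is normalised by the mean magnitude of its observations and
    the per-run scores are averaged, so a support run has to fit every
    observed output at once.  Constant-prior parameters are skipped with a
    notice.  Deterministic given identical inputs.
    """
    joint = isinstance(observed, Mapping)
    if isinstance(ensemble, Ensemble):
        rows = np.asarray(ensemble.run_ids, dtype=int) - 1
        time_axis = np.asarray(ensemble.time, dtype=float)
        sim = ensemble.channel(next(iter(observed)) if joint else variable)
    else:
        if joint:
            raise TypeError("joint conditioning needs a full Ensemble")
        sim = np.asarray(ensemble, dtype=float)
        rows = np.arange(sim.shape[0])
        time_axis = np.arange(1, sim.shape[1] + 1, dtype=float)
    if np.any(rows < 0) or np.any(rows >= samples.n):
        raise ValueError("ensemble run ids do not align with sample-matrix rows")
    values_matrix = samples.values[rows]

    n, T = sim.shape
    k = ceil(config.support_fraction * n)
    if n < k or n < 1:
        raise ValueError(
            f"need at least {k} completed runs for support fraction "
            f"{config.support_fraction}, have {n}"
        )

    if joint:
        combined = np.zeros((n, T))
        for var, obs_series in observed.items():
            obs_series = np.asarray(obs_series, dtype=float)
            scale = np.abs(obs_series).mean()
            if scale == 0:
                raise ValueError(f"{var}: zero-magnitude observations cannot "
                                 "be scale-normalised")
            part = windowed_objective(
                ensemble.channel(var), obs_series, config.window, config.metric
            )
            combined += part.values / scale
        combined /= len(observed)
        obj = ObjectiveMatrix(values=combined, metric=config.metric,
                              window=config.window)
    else:
        obj = windowed_objective(sim, observed, config.window, config.metric)
    support = np.empty((k, T), dtype=int)
    for t in range(T):
        support[:, t] = select_support(obj.values[:, t], config.support_fraction)

    names = list(parameters) if parameters is not None else list(samples.column_names)
    results: dict[str, ParameterIdentifiability] = {}
    skipped: list[str] = []
    for name in names:
        spec = registry[name]
        if spec.is_constant:
            logger.info("skipping constant parameter %s", name)
            skipped.append(name)
            continue
        col = values_matrix[:, samples.column_names.index(name)]
        lo, hi = spec.lower, spec.upper
        # integer parameters take at most (upper-lower+1) distinct values;
        # more containers than that would leave structurally empty bins and
        # fake identifiability, so the bin count is capped there
        M = config.containers
        if spec.integer_flag:
            M = min(M, int(round(hi - lo)) + 1)
        width = (hi - lo) / M
        sup_vals = col[support]                      # (k, T)
        bin_idx = np.minimum(
            ((np.clip(sup_vals, lo, hi) - lo) / width).astype(int), M - 1
        )
        density = np.zeros((M, T))
        np.add.at(density, (bin_idx, np.broadcast_to(np.arange(T), (k, T))), 1.0)
        density /= k
        dev = np.abs(density - 1.0 / M).sum(axis=0)
        idi_series = 0.5 * dev * M / (M - 1)
        cl = np.percentile(sup_vals, config.percentiles, axis=0)
        cl_low = np.clip(cl[0], lo, hi)
        cl_high = np.clip(cl[1], lo, hi)
        ic = np.clip(1.0 - (cl_high - cl_low) / (hi - lo), 0.0, 1.0)
        results[name] = ParameterIdentifiability(
            name=name,
            density=density,
            gradient=density * M,
            idi=idi_series,
            cl_low=cl_low,
            cl_high=cl_high,
            ic=ic,
        )
    return DyniaResult(
        parameters=results,
        objective=obj,
        support=support,
        time=time_axis,
        config=config,
        skipped=skipped,
    )


def ic_noise_band(
    samples: SampleMatrix,
    registry: ParameterRegistry,
    support_size: int,
    n_draws: int = 500,
    seed: int = 0,
    percentiles: tuple[float, float] = (0.5, 99.5),
    cl_percentiles: tuple[float, float] = (5.0, 95.0),
) -> dict[str, tuple[float, float]]:
    """Null distribution of the information content under random support.

    Draws ``n_draws`` random support sets of the given size (no conditioning
    on performance at all) and records each parameter's IC; the returned
    per-parameter band brackets the IC values an *uninformative* parameter
    produces purely from sampling noise.  An inert parameter's observed IC
    should sit inside this band; a genuinely constrained one escapes above.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[float, float]] = {}
    draws = np.stack(
        [rng.choice(samples.n, size=support_size, replace=False)
         for _ in range(n_draws)]
    )
    for j, name in enumerate(samples.column_names):
        spec = registry[name]
        if spec.is_constant:
            continue
        vals = samples.values[draws, j]              # (n_draws, support_size)
        cl = np.percentile(vals, cl_percentiles, axis=1)
        ic = np.clip(1.0 - (cl[1] - cl[0]) / spec.width, 0.0, 1.0)
        lo, hi = np.percentile(ic, percentiles)
        out[name] = (float(lo), float(hi))
    return out
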