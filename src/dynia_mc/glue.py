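"""GLUE-style behavioural filtering and prediction uncertainty.

Generalized Likelihood Uncertainty Estimation treats every Monte-Carlo run
whose error against observations passes a likelihood threshold as *equally
probable* ("behavioural").  Here the likelihood proxy is the Normalized Root
Mean Square Error, NRMSE = 100 * RMSE / mean(obs) in percent, with the
conventional 10% acceptance threshold as default.  Behavioural runs carry
equal weights and their per-time-step percentiles give prediction bounds;
because equal-likelihood GLUE is known to widen bounds, the summary reports
observed containment next to band width rather than claiming calibrated
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .treatment_runner import Ensemble

__all__ = [
    "nrmse",
    "nrmse_report",
    "BehaviouralSet",
    "behavioural_filter",
    "PredictionBounds",
    "prediction_bounds",
    "uncertainty_summary",
]

DEFAULT_THRESHOLD_PCT = 10.0


def nrmse(simulated: np.ndarray, observed: np.ndarray,
          normalization: str = "mean") -> float:
    """Normalized RMSE in percent: 100 * RMSE / mean(obs).

    ``normalization="range"`` divides by (max - min) of the observations
    instead.  A zero normaliser (zero-mean or constant record) is rejected —
    the statistic is undefined there, never silently 0 or inf.
    """
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError(f"length mismatch: sim {sim.shape} vs obs {obs.shape}")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    if normalization == "mean":
        denom = obs.mean()
    elif normalization == "range":
        denom = obs.max() - obs.min()
    else:
        raise ValueError("normalization must be 'mean' or 'range'")
    if denom == 0:
        raise ValueError("normalization undefined: zero observed " +
                         ("mean" if normalization == "mean" else "range"))
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    return 100.0 * rmse / float(denom)


def nrmse_report(
    ensemble: Ensemble,
    observed: Mapping[str, np.ndarray],
    normalization: str = "mean",
) -> pd.DataFrame:
    """NRMSE (%) of every done run against every observed variable.

    Rows are indexed by run id, columns by variable name.
    """
    data = {}
    for var, obs in observed.items():
        sim = ensemble.channel(var)
        data[var] = [nrmse(sim[i], obs, normalization) for i in range(ensemble.n_runs)]
    return pd.DataFrame(data, index=pd.Index(ensemble.run_ids, name="run_id"))


@dataclass
class BehaviouralSet:
    """Runs passing the threshold, each carrying the same weight 1/k."""

    run_ids: np.ndarray
    weights: np.ndarray
    threshold: float
    variable: str
    acceptance_rate: float

    def __post_init__(self) -> None:
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.run_ids) != len(self.weights):
            raise ValueError("run_ids and weights must align")
        if len(self.run_ids) and abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return len(self.run_ids)


def behavioural_filter(
    report: pd.DataFrame,
    variable: str,
    threshold: float = DEFAULT_THRESHOLD_PCT,
) -> BehaviouralSet:
    """Accept runs with NRMSE <= threshold (inclusive), equal weights.

    When nothing passes, the error cites the smallest observed NRMSE so the
    threshold can be relaxed deliberately rather than silently.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (percent NRMSE)")
    if variable not in report.columns:
        raise KeyError(f"variable {variable!r} not in report columns")
    scores = report[variable]
    accepted = report.index[scores <= threshold].to_numpy()
    if accepted.size == 0:
        raise ValueError(
            f"no run passed NRMSE <= {threshold}% on {variable!r}; "
            f"minimum observed NRMSE is {scores.min():.3f}%"
        )
    k = accepted.size
    return BehaviouralSet(
        run_ids=accepted,
        weights=np.full(k, 1.0 / k),
        threshold=threshold,
        variable=variable,
        acceptance_rate=k / len(report),
    )


@dataclass
class PredictionBounds:
    """Per-time-step lower/upper bounds over behavioural simulations."""

    lower: np.ndarray
    upper: np.ndarray
    level: float

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bounds must share a shape")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def prediction_bounds(
    ensemble: Ensemble,
    behavioural: BehaviouralSet,
    variable: str,
    level: float = 0.9,
) -> PredictionBounds:
    """Central ``level`` prediction band over the behavioural ensemble.

    At each time step the (1-level)/2 and (1+level)/2 weighted percentiles
    of the behavioural simulated values are taken; under GLUE's equal
    weights these are plain percentiles, and ``level=1`` is the min/max
    envelope.
    """
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    if len(behavioural) == 0:
        raise ValueError("behavioural set is empty")
    id_to_row = {rid: i for i, rid in enumerate(ensemble.run_ids)}
    rows = [id_to_row[rid] for rid in behavioural.run_ids]
    sims = ensemble.channel(variable)[rows]
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    lower, upper = np.percentile(sims, [lo_q, hi_q], axis=0)
    return PredictionBounds(lower=lower, upper=upper, level=level)


def uncertainty_summary(
    bounds: Mapping[str, PredictionBounds],
    observed: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Rank output variables by relative prediction-band width.

    Per variable: mean band width normalised by the observed mean, and the
    fraction of observations falling inside the band.  Rank 1 is the most
    certain (narrowest) variable; ties share the minimum rank.
    """
    if len(bounds) < 2:
        raise ValueError("need bounds for at least two variables to rank")
    rows = []
    for var, b in bounds.items():
        obs = np.asarray(observed[var], dtype=float)
        if obs.shape != b.lower.shape:
            raise ValueError(f"{var}: observed length does not match bounds")
        om = obs.mean()
        if om == 0:
            raise ValueError(f"{var}: zero observed mean, relative width undefined")
        rel_width = float(b.width.mean() / abs(om))
        inside = float(np.mean((obs >= b.lower) & (obs <= b.upper)))
        rows.append((var, rel_width, inside))
    df = pd.DataFrame(rows, columns=["variable", "relative_width", "containment"])
    df["rank"] = df["relative_width"].rank(method="min").astype(int)
    return df.sort_values("rank", kind="stable").reset_index(drop=True)
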