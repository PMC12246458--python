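"""Run configuration and the staged sample→run→analyse pipeline.

A single declarative YAML file drives the whole workflow.  Every stage
persists its products as CSV/JSON under the configured output directory and
*reads its inputs back from those artifacts*, so a partially-deleted output
tree resumes exactly where it must: deleting only the DYNIA outputs, for
example, recomputes them byte-identically from the persisted ensemble.

Defaults mirror the wheat study settings: a +/-10-step window, 20
containers, support fraction 0.10 and a 10% NRMSE acceptance threshold.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import minicrop
from .dynia import DyniaConfig, run_dynia
from .glue import behavioural_filter, nrmse_report, prediction_bounds, uncertainty_summary
from .parameter_space import (
    ParameterRegistry,
    load_registry,
    load_samples,
    sample_parameters,
    save_samples,
    wheat_registry,
)
from .treatment_runner import STUDY_CHANNELS, Ensemble

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PIPELINE_STAGES"]

logger = logging.getLogger(__name__)

PIPELINE_STAGES = ("sample", "run", "observe", "dynia", "glue", "manifest")

_TOP_KEYS = {
    "registry", "n_samples", "seed", "method", "backend", "output_dir",
    "weather", "observed", "dynia", "glue",
}
_WEATHER_KEYS = {"n_days", "preset"}
_OBSERVED_KEYS = {"noise", "file"}
_DYNIA_KEYS = {"window", "containers", "support_fraction", "metric", "variable"}
_GLUE_KEYS = {"variable", "threshold", "level"}


@dataclass
class RunConfig:
    """Fully-resolved pipeline settings with study defaults applied."""

    registry: str = "wheat"           # "wheat" or a registry CSV path
    n_samples: int = 500
    seed: int = 1
    method: str = "monte_carlo"
    backend: str = "minicrop"
    output_dir: str = "dynia_mc_out"
    weather_days: int = 240
    weather_preset: str = "semi_arid"
    observed_noise: float = 0.05
    observed_file: str | None = None
    dynia: DyniaConfig = field(default_factory=DyniaConfig)
    dynia_variable: str = "biomass"
    glue_variable: str = "biomass"
    glue_threshold: float = 10.0
    glue_level: float = 0.9

    def load_registry(self) -> ParameterRegistry:
        if self.registry == "wheat":
            return wheat_registry()
        return load_registry(self.registry)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dynia"] = {
            "window": self.dynia.window,
            "containers": self.dynia.containers,
            "support_fraction": self.dynia.support_fraction,
            "metric": self.dynia.metric,
            "percentiles": list(self.dynia.percentiles),
        }
        return d


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config file (or a pre-parsed mapping).

    Unknown keys are rejected with their path; referenced files must exist;
    the support fraction must leave at least one run (q*N >= 1).
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")
    weather = raw.get("weather") or {}
    observed = raw.get("observed") or {}
    dynia_raw = raw.get("dynia") or {}
    glue_raw = raw.get("glue") or {}
    _check_keys(weather, _WEATHER_KEYS, "weather")
    _check_keys(observed, _OBSERVED_KEYS, "observed")
    _check_keys(dynia_raw, _DYNIA_KEYS, "dynia")
    _check_keys(glue_raw, _GLUE_KEYS, "glue")

    cfg = RunConfig(
        registry=str(raw.get("registry", "wheat")),
        n_samples=int(raw.get("n_samples", 500)),
        seed=int(raw.get("seed", 1)),
        method=str(raw.get("method", "monte_carlo")),
        backend=str(raw.get("backend", "minicrop")),
        output_dir=str(raw.get("output_dir", "dynia_mc_out")),
        weather_days=int(weather.get("n_days", 240)),
        weather_preset=str(weather.get("preset", "semi_arid")),
        observed_noise=float(observed.get("noise", 0.05)),
        observed_file=observed.get("file"),
        dynia=DyniaConfig(
            window=int(dynia_raw.get("window", 10)),
            containers=int(dynia_raw.get("containers", 20)),
            support_fraction=float(dynia_raw.get("support_fraction", 0.10)),
            metric=str(dynia_raw.get("metric", "mae")),
        ),
        dynia_variable=str(dynia_raw.get("variable", "biomass")),
        glue_variable=str(glue_raw.get("variable", "biomass")),
        glue_threshold=float(glue_raw.get("threshold", 10.0)),
        glue_level=float(glue_raw.get("level", 0.9)),
    )
    if cfg.registry != "wheat" and not Path(cfg.registry).exists():
        raise ValueError(f"registry file does not exist: {cfg.registry}")
    if cfg.observed_file is not None and not Path(cfg.observed_file).exists():
        raise ValueError(f"observed file does not exist: {cfg.observed_file}")
    if cfg.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if cfg.backend != "minicrop":
        raise ValueError(
            f"unknown backend {cfg.backend!r}; the bundled backend is 'minicrop' "
            "(drive external executables through the treatment_runner API)"
        )
    support = int(np.ceil(cfg.dynia.support_fraction * cfg.n_samples))
    if support < 1:
        raise ValueError("support_fraction * n_samples must be >= 1")
    if support < 10:
        logger.warning(
            "support set has only %d runs; densities will be very noisy", support
        )
    if cfg.glue_threshold <= 0:
        raise ValueError("glue.threshold must be positive")
    return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


def _write_observed_csv(path: Path, time, observed: dict[str, np.ndarray]) -> None:
    import csv, io
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["day", *STUDY_CHANNELS])
    for i, t in enumerate(time):
        w.writerow([int(t)] + [repr(float(observed[c][i])) for c in STUDY_CHANNELS])
    path.write_text(buf.getvalue())


def _read_observed_csv(path: Path) -> dict[str, np.ndarray]:
    import csv
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    header = rows[0]
    data = np.array([[float(v) for v in r] for r in rows[1:]])
    return {c: data[:, header.index(c)] for c in header if c != "day"}


def run_pipeline(config: RunConfig, resume: bool = True) -> Path:
    """Execute sample → run → observe → dynia → glue, persisting each stage.

    With ``resume=True`` (default) a stage whose artifacts already exist is
    skipped and later stages are recomputed from the persisted files, so
    reruns are deterministic and byte-identical.
    Returns the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = config.load_registry()
    weather_seed, noise_seed = _child_seeds(config.seed, 2)

    # stage: sample ---------------------------------------------------------
    samples_path = out / "samples.csv"
    if not (resume and samples_path.exists()):
        samples = sample_parameters(
            registry, config.n_samples, config.seed, config.method
        )
        save_samples(samples, samples_path)
        logger.info("sample: wrote %d x %d matrix", samples.n, len(registry))
    samples = load_samples(samples_path, registry)

    # shared forcing (regenerated deterministically, also persisted)
    weather_path = out / "weather.csv"
    if not (resume and weather_path.exists()):
        minicrop.generate_weather(
            config.weather_days, weather_seed, config.weather_preset
        ).to_csv(weather_path)
    weather = minicrop.WeatherSeries.from_csv(weather_path)

    # stage: run + harvest --------------------------------------------------
    ens_dir = out / "ensemble"
    if not (resume and (ens_dir / "ensemble.json").exists()):
        values = minicrop.simulate_ensemble(samples, weather)
        ensemble = Ensemble(
            values=values,
            run_ids=list(range(1, samples.n + 1)),
            time=weather_series_time(weather),
            channel_names=list(STUDY_CHANNELS),
        )
        ensemble.save(ens_dir)
        logger.info("run: simulated %d treatments x %d days", samples.n,
                    weather.n_days)
    ensemble = Ensemble.load(ens_dir)

    # stage: observed series ------------------------------------------------
    obs_path = out / "observed.csv"
    if not (resume and obs_path.exists()):
        if config.observed_file:
            obs_path.write_text(Path(config.observed_file).read_text())
        else:
            truth = minicrop.reference_parameters(registry)
            ref = minicrop.simulate(truth, weather)
            rng = np.random.default_rng(noise_seed)
            observed = {
                c: ref.channels[c] * (1.0 + config.observed_noise
                                      * rng.standard_normal(weather.n_days))
                for c in STUDY_CHANNELS
            }
            _write_observed_csv(obs_path, ref.time, observed)
    observed = _read_observed_csv(obs_path)

    # stage: dynia ----------------------------------------------------------
    dynia_dir = out / "dynia"
    if not (resume and (dynia_dir / "dynia.json").exists()):
        result = run_dynia(
            ensemble, observed[config.dynia_variable], samples, registry,
            config.dynia, variable=config.dynia_variable,
        )
        result.save(dynia_dir)
        _write_idi_summary(dynia_dir / "idi_summary.csv", result)
        logger.info("dynia: analysed %d parameters on %r",
                    len(result.parameters), config.dynia_variable)

    # stage: glue -----------------------------------------------------------
    glue_dir = out / "glue"
    if not (resume and (glue_dir / "summary.csv").exists()):
        glue_dir.mkdir(parents=True, exist_ok=True)
        # variables whose observed mean is 0 (e.g. yield in a season that
        # never flowers) have no defined NRMSE and are skipped with a notice
        scoreable = {c: observed[c] for c in STUDY_CHANNELS
                     if np.asarray(observed[c]).mean() != 0}
        dropped = [c for c in STUDY_CHANNELS if c not in scoreable]
        if dropped:
            logger.warning("glue: skipping zero-mean variable(s) %s", dropped)
        if config.glue_variable not in scoreable:
            raise ValueError(
                f"glue variable {config.glue_variable!r} has zero observed "
                "mean; NRMSE is undefined for it"
            )
        report = nrmse_report(ensemble, scoreable)
        report.to_csv(glue_dir / "nrmse.csv", float_format="%.10g")
        bset = behavioural_filter(report, config.glue_variable,
                                  config.glue_threshold)
        (glue_dir / "behavioural.json").write_text(json.dumps({
            "variable": bset.variable,
            "threshold_pct": bset.threshold,
            "acceptance_rate": bset.acceptance_rate,
            "run_ids": [int(r) for r in bset.run_ids],
        }, indent=2) + "\n")
        bounds = {}
        for var in scoreable:
            b = prediction_bounds(ensemble, bset, var, config.glue_level)
            bounds[var] = b
            _write_bounds_csv(glue_dir / f"bounds_{var}.csv", ensemble.time, b)
        summary = uncertainty_summary(bounds, {v: observed[v] for v in bounds})
        summary.to_csv(glue_dir / "summary.csv", index=False,
                       float_format="%.10g")
        logger.info("glue: %d/%d behavioural runs on %r",
                    len(bset), ensemble.n_runs, config.glue_variable)

    # stage: manifest -------------------------------------------------------
    # the manifest lives inside output_dir; record the location relatively so
    # identical runs in different directories produce identical manifests
    config_echo = config.to_dict()
    config_echo["output_dir"] = "."
    manifest = {
        "config": config_echo,
        "derived_seeds": {"weather": weather_seed, "observed_noise": noise_seed},
        "counts": {
            "treatments_written": samples.n,
            "runs_done": ensemble.n_runs,
            "runs_failed": len(ensemble.failures),
        },
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out


def weather_series_time(weather: minicrop.WeatherSeries) -> np.ndarray:
    return np.arange(1, weather.n_days + 1, dtype=float)


def verify_manifest(output_dir: str | Path) -> list[str]:
    """Re-hash every listed artifact; return the names that changed."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for rel, digest in manifest["files"].items():
        p = out / rel
        if not p.is_file() or _sha256(p) != digest:
            bad.append(rel)
    return bad


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_bounds_csv(path: Path, time, bounds) -> None:
    import csv, io
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["time", "lower", "upper"])
    for i, t in enumerate(time):
        w.writerow([repr(float(t)), repr(float(bounds.lower[i])),
                    repr(float(bounds.upper[i]))])
    path.write_text(buf.getvalue())


def _write_idi_summary(path: Path, result) -> None:
    import csv, io
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["parameter", "mean_idi", "max_idi", "argmax_time", "mean_ic"])
    for name, pr in result.parameters.items():
        am = int(np.argmax(pr.idi))
        w.writerow([
            name,
            repr(float(pr.idi.mean())),
            repr(float(pr.idi.max())),
            repr(float(result.time[am])),
            repr(float(pr.ic.mean())),
        ])
    path.write_text(buf.getvalue())
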