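"""Batch execution of a simulator over sampled parameter sets.

Mirrors the write/run/harvest workflow used to drive closed-source
batch-executable models: each sampled parameter set is materialised as a
*treatment* — a unique folder of input files rendered from text templates —
then treatments are executed strictly one at a time, with completion
verified before the next launch, and finally the per-treatment output time
series are harvested into a runs x time x variables :class:`Ensemble`.

Two backend families are provided: in-process callables (e.g. the bundled
minicrop surrogate) and external executables driven through a command line,
whose completion is detected by polling for a sentinel output file.
"""

from __future__ import annotations

import csv
import io
import json
import re
import shutil
import subprocess
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .parameter_space import ParameterRegistry, SampleMatrix

__all__ = [
    "STUDY_CHANNELS",
    "TreatmentTemplate",
    "Treatment",
    "RunResult",
    "SimulatorBackend",
    "Ensemble",
    "write_treatments",
    "run_all",
    "harvest_outputs",
    "CallableBackend",
    "ExecutableBackend",
    "OutputSchema",
]

#: Default harvest schema of the crop use-case: the five outputs analysed.
STUDY_CHANNELS = (
    "soil_evaporation",
    "transpiration",
    "evapotranspiration",
    "biomass",
    "yield",
)

_PLACEHOLDER_RE = re.compile(r"\{\{\s*([A-Za-z0-9_]+)\s*\}\}")


@dataclass
class TreatmentTemplate:
    """Named text files with ``{{name}}`` placeholders.

    ``formats`` maps parameter names to Python format specs (e.g. ``".4f"``);
    unlisted parameters use ``default_format``.  With a registry attached,
    integer-flagged parameters render without a decimal point regardless of
    format (many closed-source models reject floats in integer fields).
    """

    files: dict[str, str]
    formats: dict[str, str] = field(default_factory=dict)
    default_format: str = ".6g"
    registry: ParameterRegistry | None = None

    def placeholders(self) -> set[str]:
        names: set[str] = set()
        for text in self.files.values():
            names.update(_PLACEHOLDER_RE.findall(text))
        return names

    def _format_value(self, name: str, value: float) -> str:
        if self.registry is not None and name in self.registry and \
                self.registry[name].integer_flag:
            return str(int(round(float(value))))
        spec = self.formats.get(name, self.default_format)
        return format(float(value), spec)

    def render(self, values: Mapping[str, float]) -> dict[str, str]:
        missing = self.placeholders() - set(values)
        if missing:
            raise KeyError(
                f"template placeholder(s) with no matching column: {sorted(missing)}"
            )

        def sub(m: re.Match) -> str:
            name = m.group(1)
            return self._format_value(name, values[name])

        return {fn: _PLACEHOLDER_RE.sub(sub, text) for fn, text in self.files.items()}

    @classmethod
    def from_paths(cls, paths: Sequence[str | Path], **kw) -> "TreatmentTemplate":
        files = {Path(p).name: Path(p).read_text() for p in paths}
        return cls(files=files, **kw)


@dataclass
class Treatment:
    """One materialised model run: an id, a folder and its parameter values."""

    id: int
    folder: Path
    values: dict[str, float]
    status: str = "pending"  # pending | running | done | failed


@dataclass
class RunResult:
    """Outcome of one treatment: exit status and per-variable time series."""

    treatment_id: int
    status: str                              # done | failed
    time: np.ndarray | None = None
    channels: dict[str, np.ndarray] = field(default_factory=dict)
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == "done":
            if self.time is None:
                raise ValueError("done result needs a time axis")
            lengths = {len(v) for v in self.channels.values()}
            if lengths and lengths != {len(self.time)}:
                raise ValueError("done result channels must match the time axis")


class SimulatorBackend(Protocol):
    """Contract every backend satisfies: declared channels + a run action."""

    output_channels: tuple[str, ...]

    def run(self, treatment: Treatment, timeout_s: float | None = None) -> RunResult:
        ...


def write_treatments(
    samples: SampleMatrix,
    template: TreatmentTemplate,
    workdir: str | Path,
    force: bool = False,
    extra_files: Mapping[str, str | Path] | None = None,
) -> list[Treatment]:
    """Materialise one folder per sample row from the template.

    Refuses to touch a non-empty ``workdir`` unless ``force`` is given, and
    validates every placeholder against the sample columns *before* creating
    any folder.  ``extra_files`` are copied verbatim into each treatment
    folder (e.g. a shared weather file).
    """
    workdir = Path(workdir)
    unknown = template.placeholders() - set(samples.column_names)
    if unknown:
        raise KeyError(
            f"template placeholder(s) with no matching column: {sorted(unknown)}"
        )
    if workdir.exists() and any(workdir.iterdir()):
        if not force:
            raise FileExistsError(
                f"workdir {workdir} is not empty; pass force=True to overwrite"
            )
        shutil.rmtree(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    treatments = []
    width = max(5, len(str(samples.n)))
    for i in range(samples.n):
        values = samples.row_dict(i)
        folder = workdir / f"treatment_{i + 1:0{width}d}"
        folder.mkdir()
        for fn, text in template.render(values).items():
            (folder / fn).write_text(text)
        if extra_files:
            for fn, src in extra_files.items():
                shutil.copyfile(src, folder / fn)
        (folder / "values.json").write_text(json.dumps(values, indent=2) + "\n")
        treatments.append(Treatment(id=i + 1, folder=folder, values=values))
    return treatments


def run_all(
    treatments: Sequence[Treatment],
    backend: SimulatorBackend,
    pause_s: float = 0.0,
    timeout_s: float | None = None,
) -> list[RunResult]:
    """Execute treatments strictly one at a time, in order.

    Each treatment must report completion (done or failed) before the next
    one is launched; a failure never aborts the batch.  ``pause_s`` sleeps
    between launches (useful to ease CPU pressure with external
    executables); ``timeout_s`` bounds one run's wall time.
    """
    if pause_s < 0:
        raise ValueError("pause_s must be >= 0")
    results: list[RunResult] = []
    for k, t in enumerate(treatments):
        if k > 0 and pause_s > 0:
            _time.sleep(pause_s)
        t.status = "running"
        start = _time.monotonic()
        try:
            result = backend.run(t, timeout_s=timeout_s)
        except TimeoutError:
            result = RunResult(t.id, "failed", reason="timeout")
        except Exception as e:  # fault isolation: one bad run must not abort
            result = RunResult(t.id, "failed", reason=f"{type(e).__name__}: {e}")
        elapsed = _time.monotonic() - start
        if timeout_s is not None and elapsed > timeout_s and result.status == "done":
            result = RunResult(t.id, "failed", reason="timeout")
        t.status = result.status
        results.append(result)
    return results


def harvest_outputs(
    results: Sequence[RunResult],
    channels: Sequence[str] = STUDY_CHANNELS,
) -> "Ensemble":
    """Collect done runs into a runs x time x variables ensemble.

    Time axes must be identical across done runs (the offending run is named
    otherwise); failed runs are recorded but excluded from the array.
    """
    done = [r for r in results if r.status == "done"]
    failed = [r for r in results if r.status != "done"]
    if not done:
        raise ValueError("no completed runs to harvest")
    ref_time = np.asarray(done[0].time)
    for r in done[1:]:
        if not np.array_equal(np.asarray(r.time), ref_time):
            raise ValueError(f"run {r.treatment_id}: time axis differs from run "
                             f"{done[0].treatment_id}")
    missing_runs = [
        r.treatment_id for r in done if any(c not in r.channels for c in channels)
    ]
    if missing_runs:
        raise ValueError(f"run(s) {missing_runs} missing declared output channels")
    values = np.empty((len(done), len(ref_time), len(channels)))
    for i, r in enumerate(done):
        for j, c in enumerate(channels):
            values[i, :, j] = np.asarray(r.channels[c], dtype=float)
    return Ensemble(
        values=values,
        run_ids=[r.treatment_id for r in done],
        time=ref_time,
        channel_names=list(channels),
        failures={r.treatment_id: r.reason for r in failed},
    )


@dataclass
class Ensemble:
    """Harvested outputs: ``values[run, time, variable]`` plus bookkeeping."""

    values: np.ndarray
    run_ids: list[int]
    time: np.ndarray
    channel_names: list[str]
    failures: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ensemble values must be runs x time x variables")
        r, t, c = self.values.shape
        if r != len(self.run_ids) or t != len(self.time) or c != len(self.channel_names):
            raise ValueError("ensemble axes do not match metadata")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """(runs, time) slice for one output variable."""
        return self.values[:, :, self.channel_names.index(name)]

    # -- persistence: one CSV per channel plus a JSON manifest --------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.channel_names:
            buf = io.StringIO()
            w = csv.writer(buf, lineterminator="\n")
            w.writerow(["run_id"] + [repr(float(t)) for t in self.time])
            for rid, row in zip(self.run_ids, self.channel(name)):
                w.writerow([rid] + [repr(float(v)) for v in row])
            (directory / f"channel_{name}.csv").write_text(buf.getvalue())
        manifest = {
            "channels": self.channel_names,
            "run_ids": self.run_ids,
            "n_time": int(len(self.time)),
            "failures": {str(k): v for k, v in self.failures.items()},
        }
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "Ensemble":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        channels = manifest["channels"]
        arrays = []
        time = None
        for name in channels:
            with open(directory / f"channel_{name}.csv", newline="") as fh:
                rows = list(csv.reader(fh))
            time = np.array([float(v) for v in rows[0][1:]])
            arrays.append(np.array([[float(v) for v in r[1:]] for r in rows[1:]]))
        values = np.stack(arrays, axis=-1)
        return cls(
            values=values,
            run_ids=[int(r) for r in manifest["run_ids"]],
            time=time,
            channel_names=list(channels),
            failures={int(k): v for k, v in manifest["failures"].items()},
        )


# --------------------------------------------------------------------------
# backends
# --------------------------------------------------------------------------

class CallableBackend:
    """In-process backend wrapping ``fn(values) -> (time, channels dict)``."""

    def __init__(self, fn: Callable[[Mapping[str, float]], tuple[np.ndarray, dict]],
                 output_channels: Sequence[str] = STUDY_CHANNELS):
        self._fn = fn
        self.output_channels = tuple(output_channels)

    def run(self, treatment: Treatment, timeout_s: float | None = None) -> RunResult:
        time_axis, channels = self._fn(treatment.values)
        return RunResult(treatment.id, "done", time=np.asarray(time_axis),
                         channels={k: np.asarray(v) for k, v in channels.items()})


@dataclass
class OutputSchema:
    """How to read one treatment's output file.

    ``output_file`` is the sentinel whose appearance marks completion;
    ``channels`` maps harvested names to column names of that file.
    """

    output_file: str
    channels: dict[str, str]
    time_column: str = "day"
    delimiter: str = ","
    skip_rows: int = 0

    def parse(self, path: Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        with open(path, newline="") as fh:
            for _ in range(self.skip_rows):
                next(fh)
            if self.delimiter.strip() == "":
                rows = [line.split() for line in fh if line.strip()]
            else:
                rows = [r for r in csv.reader(fh, delimiter=self.delimiter) if r]
        header = rows[0]
        idx = {name: header.index(name) for name in
               [self.time_column, *self.channels.values()]}
        data = np.array([[float(v) for v in r] for r in rows[1:]])
        time_axis = data[:, idx[self.time_column]]
        chans = {out: data[:, idx[col]] for out, col in self.channels.items()}
        return time_axis, chans

    @classmethod
    def from_json(cls, path: str | Path) -> "OutputSchema":
        d = json.loads(Path(path).read_text())
        return cls(**d)


class ExecutableBackend:
    """Drive an external executable inside each treatment folder.

    The command is launched in the treatment folder; completion is detected
    by process exit *and* the appearance of the schema's sentinel output
    file, polled every ``poll_s`` seconds up to the timeout (generalising the
    fixed-pause strategy used with closed-source models whose runtime can
    only be approximated).
    """

    def __init__(self, command: Sequence[str], schema: OutputSchema,
                 poll_s: float = 0.5):
        self.command = list(command)
        self.schema = schema
        self.poll_s = poll_s
        self.output_channels = tuple(schema.channels)

    def run(self, treatment: Treatment, timeout_s: float | None = None) -> RunResult:
        out_path = treatment.folder / self.schema.output_file
        proc = subprocess.Popen(
            self.command, cwd=treatment.folder,
            stdout=subprocess.DEVNULL, stderr=subprocess.PIPE,
        )
        deadline = None if timeout_s is None else _time.monotonic() + timeout_s
        while True:
            rc = proc.poll()
            if rc is not None:
                break
            if deadline is not None and _time.monotonic() > deadline:
                proc.kill()
                proc.wait()
                return RunResult(treatment.id, "failed", reason="timeout")
            _time.sleep(min(self.poll_s, 0.05))
        if rc != 0:
            err = proc.stderr.read().decode(errors="replace") if proc.stderr else ""
            return RunResult(treatment.id, "failed",
                             reason=f"exit code {rc}: {err.strip()[:200]}")
        # poll for the sentinel file (detached writers may lag process exit)
        while not out_path.exists():
            if deadline is not None and _time.monotonic() > deadline:
                return RunResult(treatment.id, "failed", reason="no output")
            _time.sleep(min(self.poll_s, 0.05))
        time_axis, channels = self.schema.parse(out_path)
        return RunResult(treatment.id, "done", time=time_axis, channels=channels)
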