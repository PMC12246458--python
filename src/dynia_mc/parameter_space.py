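"""Parameter registry and Monte-Carlo sampling.

A :class:`ParameterRegistry` is an ordered collection of
:class:`ParameterSpec` entries (name, bounds, prior distribution, integer
flag).  The bundled wheat registry transcribes the 47 varied crop parameters
X1–X47 of the AquaCrop wheat study; the table gives names and integer flags
only, so the numeric bounds shipped here are plausible wheat values from the
AquaCrop literature, documented as toolkit fixture values.

Sampling draws an ``n x p`` :class:`SampleMatrix` — one row per treatment —
with plain Monte-Carlo or Latin-hypercube stratification.  Priors are
independent: uniform over the bounds (the convention of the DYNIA
literature), a normal truncated to the bounds, or a constant.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import stats
from scipy.stats import qmc

__all__ = [
    "ParameterSpec",
    "ParameterRegistry",
    "SampleMatrix",
    "load_registry",
    "wheat_registry",
    "sample_parameters",
    "save_samples",
    "load_samples",
]

_NORMAL_RE = re.compile(r"^normal\(\s*([^,]+)\s*,\s*([^)]+)\s*\)$")

REGISTRY_COLUMNS = (
    "name",
    "description",
    "lower",
    "upper",
    "distribution",
    "integer_flag",
)


@dataclass(frozen=True)
class ParameterSpec:
    """One sampled model parameter: bounds, prior and formatting hints."""

    name: str
    lower: float
    upper: float
    description: str = ""
    distribution: str = "uniform"
    integer_flag: bool = False
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.lower > self.upper:
            raise ValueError(
                f"{self.name}: lower bound {self.lower} exceeds upper {self.upper}"
            )
        kind, _ = self._parse_distribution()
        if kind == "constant" and self.lower != self.upper:
            raise ValueError(
                f"{self.name}: constant distribution requires lower == upper"
            )
        if self.integer_flag and (
            self.lower != int(self.lower) or self.upper != int(self.upper)
        ):
            raise ValueError(f"{self.name}: integer parameter needs integer bounds")

    def _parse_distribution(self) -> tuple[str, tuple[float, ...]]:
        d = self.distribution.strip().lower()
        if d in ("uniform", "constant"):
            return d, ()
        m = _NORMAL_RE.match(d)
        if m:
            return "normal", (float(m.group(1)), float(m.group(2)))
        raise ValueError(
            f"{self.name}: unknown distribution {self.distribution!r} "
            "(expected uniform, constant or normal(mean,sd))"
        )

    @property
    def is_constant(self) -> bool:
        return self._parse_distribution()[0] == "constant" or self.lower == self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


class ParameterRegistry:
    """Ordered set of parameter specs with unique names."""

    def __init__(self, specs: Iterable[ParameterSpec]):
        self._specs: list[ParameterSpec] = list(specs)
        seen: set[str] = set()
        for s in self._specs:
            if s.name in seen:
                raise ValueError(f"duplicate parameter name: {s.name!r}")
            seen.add(s.name)
        self._by_name = {s.name: s for s in self._specs}

    def __len__(self) -> int:
        return len(self._specs)

    def __iter__(self) -> Iterator[ParameterSpec]:
        return iter(self._specs)

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __getitem__(self, key: str | int) -> ParameterSpec:
        if isinstance(key, str):
            return self._by_name[key]
        return self._specs[key]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self._specs]

    def bounds(self) -> np.ndarray:
        """(p, 2) array of lower/upper bounds in registry order."""
        return np.array([[s.lower, s.upper] for s in self._specs], dtype=float)

    def midpoint(self) -> dict[str, float]:
        """Mid-bound value per parameter (integers rounded half-up)."""
        out = {}
        for s in self._specs:
            v = 0.5 * (s.lower + s.upper)
            out[s.name] = float(np.floor(v + 0.5)) if s.integer_flag else v
        return out


def _parse_bool(raw: str, row: int, name: str) -> bool:
    v = raw.strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no", ""):
        return False
    raise ValueError(f"row {row} ({name}): bad integer_flag {raw!r}")


def load_registry(source: str | Path) -> ParameterRegistry:
    """Read a parameter registry from a CSV file.

    Required columns: ``name,description,lower,upper,distribution,
    integer_flag`` (plus optional ``units``).  Rows keep file order.
    """
    path = Path(source)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty registry file")
        missing = [c for c in REGISTRY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        specs = []
        for i, row in enumerate(reader, start=2):
            name = (row["name"] or "").strip()
            try:
                spec = ParameterSpec(
                    name=name,
                    description=(row["description"] or "").strip(),
                    lower=float(row["lower"]),
                    upper=float(row["upper"]),
                    distribution=(row["distribution"] or "uniform").strip(),
                    integer_flag=_parse_bool(row["integer_flag"] or "", i, name),
                    units=(row.get("units") or "").strip(),
                )
            except ValueError as e:
                raise ValueError(f"{path} row {i}: {e}") from e
            specs.append(spec)
    if not specs:
        raise ValueError(f"{path}: registry has no rows")
    return ParameterRegistry(specs)


def wheat_registry() -> ParameterRegistry:
    """The bundled 47-parameter wheat registry (X1–X47, table order)."""
    ref = resources.files("dynia_mc.data").joinpath("wheat_registry.csv")
    with resources.as_file(ref) as path:
        return load_registry(path)


@dataclass
class SampleMatrix:
    """N treatments x P parameters of sampled values with seed provenance."""

    values: np.ndarray
    column_names: list[str]
    seed: int
    method: str = "monte_carlo"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sample matrix must be 2-D")
        if self.values.shape[1] != len(self.column_names):
            raise ValueError("column count does not match column_names")
        if self.values.shape[0] < 1:
            raise ValueError("sample matrix needs at least one row")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]

    def row_dict(self, i: int) -> dict[str, float]:
        return dict(zip(self.column_names, self.values[i]))


_METHODS = ("monte_carlo", "latin_hypercube")


def sample_parameters(
    registry: ParameterRegistry,
    n: int,
    seed: int,
    method: str = "monte_carlo",
) -> SampleMatrix:
    """Draw ``n`` independent parameter sets from the registry priors.

    ``monte_carlo`` draws i.i.d. samples; ``latin_hypercube`` stratifies
    each marginal into ``n`` strata (scipy's LHS engine).  Integer-flagged
    parameters are drawn continuously, rounded half-up and clamped to the
    bounds, so every bound value stays reachable.  Identical inputs yield an
    identical matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in _METHODS:
        raise ValueError(f"unknown sampling method {method!r}; choose from {_METHODS}")

    p = len(registry)
    if method == "latin_hypercube":
        u = qmc.LatinHypercube(d=p, seed=seed).random(n)
    else:
        u = np.random.default_rng(seed).random((n, p))

    values = np.empty((n, p), dtype=float)
    for j, spec in enumerate(registry):
        kind, args = spec._parse_distribution()
        if kind == "constant" or spec.lower == spec.upper:
            col = np.full(n, spec.lower)
        elif kind == "uniform":
            col = spec.lower + u[:, j] * spec.width
        else:  # truncated normal via inverse CDF of the uniform deviate
            mean, sd = args
            a = (spec.lower - mean) / sd
            b = (spec.upper - mean) / sd
            col = stats.truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
        if spec.integer_flag:
            col = np.clip(np.floor(col + 0.5), spec.lower, spec.upper)
        values[:, j] = col
    return SampleMatrix(values, list(registry.names), seed=seed, method=method)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_samples(matrix: SampleMatrix, path: str | Path) -> Path:
    """Write a sample matrix as CSV plus a JSON sidecar with seed/method."""
    path = Path(path)
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(matrix.column_names)
    for row in matrix.values:
        writer.writerow([repr(float(v)) for v in row])
    path.write_text(buf.getvalue())
    _meta_path(path).write_text(
        json.dumps(
            {"seed": matrix.seed, "method": matrix.method, "n": matrix.n},
            indent=2,
        )
        + "\n"
    )
    return path


def load_samples(
    path: str | Path, registry: ParameterRegistry | None = None
) -> SampleMatrix:
    """Reload a saved sample matrix; optionally validate against a registry.

    With a registry, every value is checked against its spec's bounds and the
    offending cell is named on failure.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty sample file")
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    rows = []
    for i, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise ValueError(f"{path} row {i}: expected {len(header)} fields, got {len(row)}")
        try:
            rows.append([float(v) for v in row])
        except ValueError as e:
            raise ValueError(f"{path} row {i}: {e}") from e
    if not rows:
        raise ValueError(f"{path}: sample file has a header but no rows")
    values = np.array(rows, dtype=float)

    meta = {"seed": -1, "method": "monte_carlo"}
    mp = _meta_path(path)
    if mp.exists():
        meta.update(json.loads(mp.read_text()))

    if registry is not None:
        if header != registry.names:
            raise ValueError(f"{path}: columns do not match registry order")
        for j, spec in enumerate(registry):
            bad = np.where((values[:, j] < spec.lower) | (values[:, j] > spec.upper))[0]
            if bad.size:
                r = int(bad[0])
                raise ValueError(
                    f"{path}: value {values[r, j]} in row {r + 2}, column "
                    f"{spec.name!r} outside bounds [{spec.lower}, {spec.upper}]"
                )
    return SampleMatrix(values, header, seed=int(meta["seed"]), method=str(meta["method"]))
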