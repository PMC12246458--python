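"""Export of time-parameter identifiability maps.

A DYNIA heatmap shows, for one parameter, the support-set density across the
parameter's range (vertical, M containers) and time (horizontal): hot spots
mark periods when good runs cluster in a narrow slice of the prior.  The
matrix is exported as annotated CSV; rendering (low density green → high
density red) is optional and isolated so the analytical core stays headless.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path

import numpy as np

from .dynia import DyniaResult

__all__ = ["export_heatmap", "read_heatmap", "render_heatmap"]


def export_heatmap(
    result: DyniaResult,
    parameter: str,
    path: str | Path,
    lower: float | None = None,
    upper: float | None = None,
    image_path: str | Path | None = None,
) -> Path:
    """Write one parameter's M x T density matrix with axis annotations.

    Rows carry their container edges (``bin_low``, ``bin_high``), the header
    carries the time axis.  ``lower``/``upper`` default to container indices
    scaled to [0, 1] when the prior bounds are not supplied.  With
    ``image_path`` a green-to-red rendering is also written.
    """
    if parameter not in result.parameters:
        raise KeyError(f"no DYNIA result for parameter {parameter!r}")
    pr = result.parameters[parameter]
    m, T = pr.density.shape
    lo = 0.0 if lower is None else float(lower)
    hi = 1.0 if upper is None else float(upper)
    edges = np.linspace(lo, hi, m + 1)

    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["bin_low", "bin_high", *[repr(float(t)) for t in result.time]])
    for i in range(m):
        w.writerow(
            [repr(float(edges[i])), repr(float(edges[i + 1]))]
            + [repr(float(v)) for v in pr.density[i]]
        )
    path = Path(path)
    path.write_text(buf.getvalue())
    if image_path is not None:
        render_heatmap(pr.density, result.time, edges, parameter, image_path)
    return path


def read_heatmap(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reload an exported heatmap: (bin edges, time axis, M x T matrix)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    time = np.array([float(v) for v in rows[0][2:]])
    lows = np.array([float(r[0]) for r in rows[1:]])
    highs = np.array([float(r[1]) for r in rows[1:]])
    edges = np.append(lows, highs[-1])
    matrix = np.array([[float(v) for v in r[2:]] for r in rows[1:]])
    return edges, time, matrix


def render_heatmap(density, time, edges, title: str, image_path: str | Path) -> Path:
    """Density-coloured time-parameter diagram (green = low, red = high)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    mesh = ax.pcolormesh(
        np.append(np.asarray(time), time[-1] + (time[-1] - time[-2] if len(time) > 1 else 1)),
        edges,
        np.asarray(density),
        cmap="RdYlGn_r",
        shading="flat",
    )
    ax.set_xlabel("time step")
    ax.set_ylabel(f"{title} value")
    fig.colorbar(mesh, ax=ax, label="support density")
    fig.tight_layout()
    fig.savefig(image_path, dpi=120)
    plt.close(fig)
    return Path(image_path)
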