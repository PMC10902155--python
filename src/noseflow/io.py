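"""Serialization helpers: CSV time series, JSON globals, YAML models, VTK fields.

Formats are deliberately plain: CSV with a fixed ``t, Q, p_th, P`` header
for time series, JSON with an explicit units block for global quantities,
YAML for model/config blocks, and legacy ASCII VTK structured points for 2D
fields (small enough here that a dependency is not warranted).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcing import GlobalQuantities
from .lumped import AirwayNetwork

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_globals",
    "read_globals",
    "dump_network",
    "load_network",
    "write_vtk_fields",
]

_SERIES_COLUMNS = ["t", "Q", "p_th", "P"]


def write_timeseries(path: "str | Path", series: pd.DataFrame) -> None:
    missing = [c for c in _SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"time series is missing columns {missing}")
    series.loc[:, _SERIES_COLUMNS].to_csv(path, index=False)


def read_timeseries(path: "str | Path") -> pd.DataFrame:
    series = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return series


def write_globals(path: "str | Path", gq: GlobalQuantities, extra: dict | None = None) -> None:
    payload = gq.to_dict()
    if extra:
        payload["metadata"] = extra
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_globals(path: "str | Path") -> GlobalQuantities:
    payload = json.loads(Path(path).read_text())
    return GlobalQuantities(
        Q_mean=payload["Q_mean"],
        dp_mean=payload["dp_mean"],
        P_mean=payload["P_mean"],
        R=payload["R"],
    )


def dump_network(net: AirwayNetwork) -> str:
    """YAML block with keys left.a, left.b, right.a, right.b, common.a, common.b."""
    return yaml.safe_dump(net.to_dict(), sort_keys=True)


def load_network(text: str) -> AirwayNetwork:
    return AirwayNetwork.from_dict(yaml.safe_load(text))


def write_vtk_fields(
    path: "str | Path",
    x: np.ndarray,
    y: np.ndarray,
    point_data: dict[str, np.ndarray],
    title: str = "noseflow fields",
) -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS file with scalar point data.

    ``x`` and ``y`` are the (uniform) coordinate vectors; every array in
    ``point_data`` must have shape ``(len(x), len(y))``.
    """
    nx, ny = len(x), len(y)
    for name, arr in point_data.items():
        if arr.shape != (nx, ny):
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {(nx, ny)}")
    dx = float(x[1] - x[0]) if nx > 1 else 1.0
    dy = float(y[1] - y[0]) if ny > 1 else 1.0
    lines = [
        "# vtk DataFile Version 2.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {float(x[0])} {float(y[0])} 0.0",
        f"SPACING {dx} {dy} 1.0",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in point_data.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK orders x fastest
        lines.extend(f"{val:.9e}" for val in arr.T.ravel())
    Path(path).write_text("\n".join(lines) + "\n")
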