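"""Plain-text serialization of grids, signals and current fields.

Formats are deliberately simple: CSV with a small ``# key=value`` header
for gridded arrays, long-form CSV for signal traces and edge currents, and
YAML for the scanner geometry.  All files round-trip bitwise through the
reader/writer pairs here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ConductivityGrid, CurrentField, MomentField, ScanSignal
from .fields import ScanGeometry

__all__ = [
    "save_grid_csv", "load_grid_csv",
    "save_grid_json", "load_grid_json",
    "save_signal_csv", "load_signal_csv",
    "save_currents_csv", "load_currents_csv",
    "save_geometry_yaml", "load_geometry_yaml",
]


def _grid_header(grid) -> list[str]:
    return [f"# cell_size={grid.cell_size!r}",
            f"# origin={grid.origin[0]!r},{grid.origin[1]!r}",
            f"# thickness={getattr(grid, 'thickness', 0.01)!r}"]


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        if not ln.startswith("#"):
            break
        key, _, val = ln[1:].strip().partition("=")
        meta[key.strip()] = val.strip()
    return meta


def save_grid_csv(grid: ConductivityGrid | MomentField, path) -> None:
    """Matrix CSV: one row per x index, columns are y indices."""
    lines = _grid_header(grid)
    for row in grid.values:
        lines.append(",".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def load_grid_csv(path, kind: str = "conductivity"):
    text = Path(path).read_text().strip().splitlines()
    meta = _parse_header(text)
    data = [ln for ln in text if not ln.startswith("#")]
    values = np.array([[float(v) for v in ln.split(",")] for ln in data])
    cell = float(meta.get("cell_size", 0.02))
    ox, oy = (float(v) for v in meta.get("origin", "-0.2,-0.2").split(","))
    if kind == "moment":
        return MomentField(values, cell, (ox, oy))
    return ConductivityGrid(values, cell, (ox, oy),
                            thickness=float(meta.get("thickness", 0.01)))


def save_grid_json(grid: ConductivityGrid, path) -> None:
    obj = {"values": grid.values.tolist(), "cell_size": grid.cell_size,
           "origin": list(grid.origin), "thickness": grid.thickness}
    Path(path).write_text(json.dumps(obj))


def load_grid_json(path) -> ConductivityGrid:
    obj = json.loads(Path(path).read_text())
    return ConductivityGrid(np.array(obj["values"]), obj["cell_size"],
                            tuple(obj["origin"]), obj["thickness"])


def save_signal_csv(signal: ScanSignal, path) -> None:
    """Long-form CSV: receiver_id, x_s, value, component."""
    frames = []
    for comp in ("total", "phi", "psi"):
        arr = getattr(signal, comp)
        if arr is None:
            continue
        r, n = arr.shape
        frames.append(pd.DataFrame({
            "receiver_id": np.repeat(np.arange(r), n),
            "x_s": np.tile(signal.x_s, r),
            "value": arr.reshape(-1),
            "component": comp,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def load_signal_csv(path) -> ScanSignal:
    df = pd.read_csv(path, float_precision="round_trip")
    comps = {}
    x_s = None
    for comp, sub in df.groupby("component"):
        piv = sub.pivot(index="receiver_id", columns="x_s", values="value")
        piv = piv.sort_index(axis=0).sort_index(axis=1)
        comps[comp] = piv.to_numpy()
        x_s = piv.columns.to_numpy(dtype=float)
    return ScanSignal(x_s, comps["total"], comps.get("phi"), comps.get("psi"))


def save_currents_csv(J: CurrentField, path) -> None:
    """Edge-current CSV: edge_type ('x'|'y'), i, j, current."""
    rows = []
    for et, arr in (("x", J.ix), ("y", J.iy)):
        ii, jj = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                             indexing="ij")
        rows.append(pd.DataFrame({"edge_type": et, "i": ii.reshape(-1),
                                  "j": jj.reshape(-1),
                                  "current": arr.reshape(-1)}))
    header = "\n".join(_grid_header(J)) + "\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False,
                                                  float_format="%.17g")


def load_currents_csv(path) -> CurrentField:
    text = Path(path).read_text().splitlines()
    meta = _parse_header(text)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    parts = {}
    for et, sub in df.groupby("edge_type"):
        arr = np.zeros((sub["i"].max() + 1, sub["j"].max() + 1))
        arr[sub["i"], sub["j"]] = sub["current"]
        parts[et] = arr
    cell = float(meta.get("cell_size", 0.02))
    ox, oy = (float(v) for v in meta.get("origin", "-0.2,-0.2").split(","))
    return CurrentField(parts["x"], parts["y"], cell, (ox, oy))


def save_geometry_yaml(geometry: ScanGeometry, path) -> None:
    Path(path).write_text(yaml.safe_dump(geometry.to_dict()))


def load_geometry_yaml(path) -> ScanGeometry:
    return ScanGeometry.from_dict(yaml.safe_load(Path(path).read_text()))
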