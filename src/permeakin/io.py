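"""File formats: OpenDX scalar grids, PQR atom records, CSV tables, TOML.

Everything is plain text.  CSV tables always carry the units in the
header row (``V_mV``, ``I_pA`` …); OpenDX grids follow the regular-grid
subset of the format that electrostatics tools exchange.
"""

from __future__ import annotations

import csv
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .geometry import GridSpec

__all__ = [
    "PqrAtom",
    "read_pqr",
    "write_dx",
    "read_dx",
    "write_table",
    "read_table",
    "load_toml",
    "dump_toml",
]


@dataclass(frozen=True)
class PqrAtom:
    """One ATOM/HETATM record: position (Å), charge (e₀), radius (Å)."""

    name: str
    x: float
    y: float
    z: float
    charge: float
    radius: float


def read_pqr(path) -> list[PqrAtom]:
    """Parse whitespace-separated PQR ATOM/HETATM records.

    The last five numeric fields of each record are taken as
    x, y, z, charge, radius (this tolerates both chain-ID variants of the
    format).  A malformed record raises with its line number.
    """
    atoms: list[PqrAtom] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            tokens = line.split()
            if not tokens or tokens[0] not in ("ATOM", "HETATM"):
                continue
            if len(tokens) < 8:
                raise ValueError(f"{path}:{lineno}: truncated PQR record")
            try:
                values = [float(t) for t in tokens[-5:]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric field in PQR record: {exc}"
                ) from exc
            name = tokens[2] if len(tokens) > 2 else "X"
            atoms.append(PqrAtom(name, *values))
    return atoms


def write_dx(path, field: np.ndarray, grid: GridSpec, comment: str = "") -> None:
    """Write a scalar field as an OpenDX regular grid (text)."""
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} != grid shape {grid.shape}")
    nx, ny, nz = field.shape
    ox = grid.x[0] + grid.h / 2
    oy = grid.y[0] + grid.h / 2
    oz = grid.z[0] + grid.h / 2
    lines = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    lines.append(f"object 1 class gridpositions counts {nx} {ny} {nz}")
    lines.append(f"origin {ox:.6g} {oy:.6g} {oz:.6g}")
    lines.append(f"delta {grid.h:.6g} 0 0")
    lines.append(f"delta 0 {grid.h:.6g} 0")
    lines.append(f"delta 0 0 {grid.h:.6g}")
    lines.append(f"object 2 class gridconnections counts {nx} {ny} {nz}")
    lines.append(
        f"object 3 class array type double rank 0 items {field.size} data follows"
    )
    flat = field.ravel(order="C")
    for i in range(0, flat.size, 3):
        chunk = flat[i : i + 3]
        lines.append(" ".join(f"{v:.17g}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX regular grid written by :func:`write_dx`."""
    counts = None
    origin = None
    deltas: list[list[float]] = []
    data: list[float] = []
    n_items = None
    reading = False
    with open(path) as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if reading:
                if stripped.startswith(("attribute", "object", "component")):
                    reading = False
                else:
                    data.extend(float(t) for t in stripped.split())
                    if n_items is not None and len(data) >= n_items:
                        reading = False
                    continue
            if stripped.startswith("object 1"):
                counts = [int(t) for t in stripped.split()[-3:]]
            elif stripped.startswith("origin"):
                origin = [float(t) for t in stripped.split()[1:4]]
            elif stripped.startswith("delta"):
                deltas.append([float(t) for t in stripped.split()[1:4]])
            elif "data follows" in stripped:
                n_items = int(stripped.split()[-3])
                reading = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a regular OpenDX grid")
    h = deltas[0][0]
    if abs(deltas[1][1] - h) > 1e-9 or abs(deltas[2][2] - h) > 1e-9:
        raise ValueError(f"{path}: anisotropic grids are not supported")
    nx, ny, nz = counts
    grid = GridSpec(
        x=(origin[0] - h / 2, origin[0] - h / 2 + nx * h),
        y=(origin[1] - h / 2, origin[1] - h / 2 + ny * h),
        z=(origin[2] - h / 2, origin[2] - h / 2 + nz * h),
        h=h,
    )
    field = np.array(data, dtype=float).reshape((nx, ny, nz), order="C")
    return field, grid


def write_table(path, columns: Mapping[str, Iterable]) -> None:
    """CSV with unit-bearing column names (e.g. ``V_mV,I_pA``)."""
    keys = list(columns)
    rows = zip(*(np.asarray(columns[k]).tolist() for k in keys))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(keys)
        writer.writerows(rows)


def read_table(path) -> dict[str, np.ndarray]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        cols: list[list[float]] = [[] for _ in header]
        for row in reader:
            for i, v in enumerate(row):
                cols[i].append(float(v))
    return {k: np.array(c) for k, c in zip(header, cols)}


def load_toml(path) -> dict:
    with open(path, "rb") as handle:
        return tomllib.load(handle)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dump_toml(data: Mapping, path=None) -> str:
    """Minimal TOML emitter for nested dicts of scalars/lists.

    Sufficient for the run configurations this package writes; round-trips
    through :func:`load_toml`.
    """

    def emit(table: Mapping, prefix: str, out: list[str]) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, Mapping)}
        subtables = {k: v for k, v in table.items() if isinstance(v, Mapping)}
        if prefix and (scalars or not subtables):
            out.append(f"[{prefix}]")
        for k, v in scalars.items():
            out.append(f"{k} = {_toml_value(v)}")
        for k, v in subtables.items():
            if out and out[-1] != "":
                out.append("")
            emit(v, f"{prefix}.{k}" if prefix else k, out)

    lines: list[str] = []
    emit(data, "", lines)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
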