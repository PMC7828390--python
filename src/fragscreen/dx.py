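"""Minimal OpenDX volumetric file I/O for GFE maps.

Writes the de-facto standard layout used for cosolvent maps::

    object 1 class gridpositions counts nx ny nz
    origin ox oy oz
    delta dx 0 0
    delta 0 dy 0
    delta 0 0 dz
    object 2 class gridconnections counts nx ny nz
    object 3 class array type double rank 0 items n data follows
    ... values, three per line, z fastest ...

Only regular orthogonal grids with isotropic spacing are supported, which
is all the map builder produces.  A write→read round trip preserves origin,
spacing and dims exactly and values to float precision.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .constants import DEFAULT_GFE_CAP, DEFAULT_TEMPERATURE
from .grid import GFEGrid, GridSpec


class DXFormatError(ValueError):
    """Malformed OpenDX file; message carries the offending line number."""


def write_dx(grid: GFEGrid, path: str | Path) -> None:
    path = Path(path)
    nx, ny, nz = grid.spec.dims
    d = grid.spec.spacing
    ox, oy, oz = grid.spec.origin
    lines = [
        f"# fragscreen GFE map, type {grid.map_type}, "
        f"T {grid.temperature:g} K, cap {grid.gfe_cap:g} kcal/mol",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.values.reshape(-1)  # C order: z fastest
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{v:.9g}" for v in flat[i : i + 3]))
    lines.append(f'attribute "dep" string "positions"')
    lines.append(f'object "{grid.map_type}" class field')
    path.write_text("\n".join(lines) + "\n")


_COUNTS_RE = re.compile(r"class gridpositions counts\s+(\d+)\s+(\d+)\s+(\d+)")
_ITEMS_RE = re.compile(r"class array .* items\s+(\d+)\s+data follows")


def read_dx(
    path: str | Path,
    map_type: str | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    gfe_cap: float = DEFAULT_GFE_CAP,
) -> GFEGrid:
    """Read an OpenDX scalar field into a :class:`GFEGrid`.

    The map type is taken from the header comment written by
    :func:`write_dx` when present, else from ``map_type``.
    """
    path = Path(path)
    dims = None
    origin = None
    deltas: list[list[float]] = []
    n_items = None
    values: list[float] = []
    header_type = None
    header_temp = None
    header_cap = None

    with path.open() as fh:
        in_data = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if in_data:
                if line.startswith(("attribute", "object", "#")):
                    in_data = False
                    continue
                try:
                    values.extend(float(tok) for tok in line.split())
                except ValueError as exc:
                    raise DXFormatError(
                        f"{path}:{lineno}: bad data token ({exc})"
                    ) from None
                continue
            if line.startswith("#"):
                m = re.search(r"type (\w+)", line)
                if m:
                    header_type = m.group(1)
                m = re.search(r"T ([0-9.eE+-]+) K", line)
                if m:
                    header_temp = float(m.group(1))
                m = re.search(r"cap ([0-9.eE+-]+) kcal/mol", line)
                if m:
                    header_cap = float(m.group(1))
                continue
            m = _COUNTS_RE.search(line)
            if m and dims is None:
                dims = tuple(int(g) for g in m.groups())
                continue
            if line.startswith("origin"):
                toks = line.split()[1:]
                if len(toks) != 3:
                    raise DXFormatError(f"{path}:{lineno}: origin needs 3 values")
                origin = tuple(float(t) for t in toks)
                continue
            if line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:]])
                continue
            m = _ITEMS_RE.search(line)
            if m:
                n_items = int(m.group(1))
                in_data = True
                continue

    if dims is None or origin is None or n_items is None:
        raise DXFormatError(f"{path}: missing gridpositions/origin/data header")
    if len(deltas) != 3:
        raise DXFormatError(f"{path}: expected 3 delta records, got {len(deltas)}")
    delta = np.asarray(deltas)
    off_diag = delta - np.diag(np.diag(delta))
    if np.any(np.abs(off_diag) > 1e-8):
        raise DXFormatError(f"{path}: non-orthogonal delta records not supported")
    spacings = np.diag(delta)
    if np.ptp(spacings) > 1e-8:
        raise DXFormatError(f"{path}: anisotropic spacing not supported")
    if len(values) != n_items or n_items != int(np.prod(dims)):
        raise DXFormatError(
            f"{path}: data count {len(values)} inconsistent with "
            f"declared items {n_items} and dims {dims}"
        )
    spec = GridSpec(origin=origin, spacing=float(spacings[0]), dims=dims)
    arr = np.asarray(values, dtype=float).reshape(dims)
    mtype = map_type or header_type
    if mtype is None:
        raise DXFormatError(f"{path}: map type not recorded; pass map_type=")
    return GFEGrid(
        spec=spec,
        values=arr,
        map_type=mtype,
        temperature=header_temp if header_temp is not None else temperature,
        gfe_cap=header_cap if header_cap is not None else gfe_cap,
    )
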