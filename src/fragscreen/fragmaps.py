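"""Build grid free energy maps from solute-probe occupancies.

The chain is: bin probe atoms of one map type from trajectory snapshots
into 1 Å voxels, divide the per-voxel occupancy by the bulk expectation to
get a normalized probability p, and Boltzmann-invert,

    GFE(v) = -k_B T ln p(v),

so bulk voxels sit at 0 kcal/mol and favorably occupied voxels go
negative.  Voxels with no usable statistics are assigned a finite cap.
Specific (per-probe-atom) maps are combined into generic classes (APOLAR,
HBDON, HBACC, MAMN, ACEO) by a voxelwise minimum over member GFEs, which
keeps the most favorable accessible interaction of each class.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .constants import (
    DEFAULT_CONCENTRATION,
    DEFAULT_GFE_CAP,
    DEFAULT_TEMPERATURE,
    K_B,
    PARTICLES_PER_A3_PER_MOLAR,
)
from .dx import read_dx, write_dx
from .grid import (
    GENERIC_MAP_COMBINATION,
    GFEGrid,
    GridSpec,
    OccupancyGrid,
    SPECIFIC_TO_GENERIC,
    require_same_spec,
    validate_map_type,
)

log = logging.getLogger(__name__)


@dataclass
class SoluteSnapshot:
    """One trajectory frame of probe atoms.

    ``atoms`` is a list of ``(coords, map_types)`` with coords an (x, y, z)
    triple in Å and map_types the set of specific map types the atom is
    counted into (one atom may carry several).
    """

    frame_index: int
    atoms: list[tuple[tuple[float, float, float], frozenset[str]]]


# ---------------------------------------------------------------------------
# Occupancy binning and normalization
# ---------------------------------------------------------------------------


def bin_atoms(
    snapshots: Iterable[SoluteSnapshot],
    map_type: str,
    spec: GridSpec,
) -> OccupancyGrid:
    """Count atoms carrying ``map_type`` into voxels of ``spec``.

    Voxels are half-open boxes [low, high): an atom exactly on a boundary
    belongs to the higher-index voxel.  Atoms outside the grid extent are
    tallied in ``overflow`` rather than dropped silently.
    """
    validate_map_type(map_type)
    coords: list[tuple[float, float, float]] = []
    n_frames = 0
    for snap in snapshots:
        n_frames += 1
        for xyz, types in snap.atoms:
            if map_type in types:
                coords.append(xyz)
    if n_frames == 0:
        raise ValueError("empty snapshot stream")

    counts = np.zeros(spec.dims, dtype=np.int64)
    overflow = 0
    if coords:
        idx, inside = spec.voxel_indices(np.asarray(coords, dtype=float))
        overflow = int(np.sum(~inside))
        if overflow:
            log.warning(
                "%d %s atom(s) outside the grid extent counted to overflow",
                overflow, map_type,
            )
        good = idx[inside]
        np.add.at(counts, (good[:, 0], good[:, 1], good[:, 2]), 1)
    return OccupancyGrid(
        spec=spec, counts=counts, n_frames=n_frames, map_type=map_type,
        overflow=overflow,
    )


def estimate_bulk(
    occ: OccupancyGrid,
    strategy: str = "concentration",
    concentration: float | None = None,
    atoms_per_solute: int = 1,
    margin: int = 2,
) -> float:
    """Expected counts per voxel (over all frames) in bulk solution.

    ``concentration`` strategy: the analytic expectation
    c * N_A * V_voxel * n_frames * atoms_per_solute with V_voxel in litres.
    ``shell`` strategy: the empirical mean count over a margin shell of
    voxels at the box faces, assumed to lie outside the solute-attracting
    region; robust when a strong site shifts the box-average concentration
    away from the nominal target.
    """
    if strategy == "concentration":
        if concentration is None:
            concentration = DEFAULT_CONCENTRATION
        if concentration <= 0:
            raise ValueError("concentration must be positive")
        per_frame = (
            concentration
            * PARTICLES_PER_A3_PER_MOLAR
            * occ.spec.voxel_volume
            * atoms_per_solute
        )
        return per_frame * occ.n_frames
    if strategy == "shell":
        if margin < 1:
            raise ValueError("shell strategy requires margin >= 1 voxel")
        nx, ny, nz = occ.spec.dims
        if min(nx, ny, nz) <= 2 * margin:
            raise ValueError("grid too small for the requested bulk margin")
        mask = np.ones(occ.spec.dims, dtype=bool)
        mask[margin:nx - margin, margin:ny - margin, margin:nz - margin] = False
        if not np.any(mask):
            raise ValueError("empty bulk margin")
        return float(occ.counts[mask].mean())
    raise ValueError(f"unknown bulk strategy {strategy!r}")


def normalize_occupancy(occ: OccupancyGrid, bulk_expected: float) -> np.ndarray:
    """Per-voxel occupancy probability relative to bulk (1.0 = bulk-like)."""
    if bulk_expected <= 0:
        raise ValueError("bulk_expected must be positive")
    return occ.counts.astype(float) / bulk_expected


def to_gfe(
    prob: np.ndarray,
    spec: GridSpec,
    map_type: str,
    temperature: float = DEFAULT_TEMPERATURE,
    gfe_cap: float = DEFAULT_GFE_CAP,
    p_min: float | None = None,
) -> GFEGrid:
    """Boltzmann-invert a normalized probability grid into grid free energies.

    Voxels with p <= p_min (notably unsampled voxels, p = 0) are assigned
    ``gfe_cap``; above that floor the transform is -k_B T ln p and is
    invertible.  The default floor is exp(-gfe_cap / k_B T), i.e. exactly
    the probability whose GFE equals the cap, so the map is continuous at
    the cap.
    """
    prob = np.asarray(prob, dtype=float)
    if np.any(prob < 0):
        raise ValueError("probabilities must be non-negative")
    kt = K_B * temperature
    if p_min is None:
        p_min = float(np.exp(-gfe_cap / kt))
    values = np.full(prob.shape, gfe_cap, dtype=float)
    ok = prob > p_min
    values[ok] = -kt * np.log(prob[ok])
    values = np.minimum(values, gfe_cap)
    return GFEGrid(
        spec=spec, values=values, map_type=map_type,
        temperature=temperature, gfe_cap=gfe_cap,
    )


def occupancy_to_gfe(
    occ: OccupancyGrid,
    bulk_strategy: str = "concentration",
    concentration: float | None = None,
    atoms_per_solute: int = 1,
    margin: int = 2,
    temperature: float = DEFAULT_TEMPERATURE,
    gfe_cap: float = DEFAULT_GFE_CAP,
) -> GFEGrid:
    """Convenience chain: estimate bulk, normalize, Boltzmann-invert."""
    bulk = estimate_bulk(
        occ, strategy=bulk_strategy, concentration=concentration,
        atoms_per_solute=atoms_per_solute, margin=margin,
    )
    prob = normalize_occupancy(occ, bulk)
    return to_gfe(
        prob, occ.spec, occ.map_type, temperature=temperature, gfe_cap=gfe_cap
    )


# ---------------------------------------------------------------------------
# Map combination and comparison
# ---------------------------------------------------------------------------


def combine_maps(specific: Mapping[str, GFEGrid]) -> dict[str, GFEGrid]:
    """Combine specific maps into generic classes by voxelwise minimum GFE.

    APOLAR <- {BENC, PRPC}; HBDON <- {MEOHD, FORHD, IMIHD};
    HBACC <- {MEOO, FORO, AALO, IMIN}; MAMN and ACEO pass through.
    Generic classes with no member map present are omitted.
    """
    grids = list(specific.values())
    if not grids:
        raise ValueError("no specific maps supplied")
    for g in grids[1:]:
        require_same_spec(grids[0].spec, g.spec, "specific maps")
    unknown = [t for t in specific if t not in SPECIFIC_TO_GENERIC]
    if unknown:
        raise ValueError(f"not specific map types: {unknown}")

    out: dict[str, GFEGrid] = {}
    for generic, members in GENERIC_MAP_COMBINATION.items():
        present = [specific[t] for t in specific if t in members]
        if not present:
            continue
        values = np.minimum.reduce([g.values for g in present])
        out[generic] = GFEGrid(
            spec=present[0].spec,
            values=values,
            map_type=generic,
            temperature=present[0].temperature,
            gfe_cap=max(g.gfe_cap for g in present),
        )
    return out


def difference_map(a: GFEGrid, b: GFEGrid) -> GFEGrid:
    """Voxelwise GFE difference a - b between two pre-aligned targets.

    Negative where binding is more favorable in a; antisymmetric under
    exchange.  Both grids must share a GridSpec and map type.
    """
    require_same_spec(a.spec, b.spec, "difference-map inputs")
    if a.map_type != b.map_type:
        raise ValueError(f"map types differ: {a.map_type} vs {b.map_type}")
    values = a.values - b.values
    cap = a.gfe_cap + b.gfe_cap
    return GFEGrid(
        spec=a.spec, values=values, map_type=a.map_type,
        temperature=a.temperature, gfe_cap=cap,
    )


# ---------------------------------------------------------------------------
# FragMap sets
# ---------------------------------------------------------------------------


class FragMapSet(dict):
    """A dict of map_type -> GFEGrid sharing one GridSpec."""

    def __init__(self, maps: Mapping[str, GFEGrid]):
        maps = dict(maps)
        if not maps:
            raise ValueError("FragMapSet needs at least one map")
        specs = list(maps.values())
        for g in specs[1:]:
            require_same_spec(specs[0].spec, g.spec, "FragMapSet members")
        for t, g in maps.items():
            if t != g.map_type:
                raise ValueError(f"key {t} != grid map_type {g.map_type}")
        super().__init__(maps)

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.values())).spec

    @property
    def gfe_cap(self) -> float:
        return max(g.gfe_cap for g in self.values())

    def save_dir(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for t, g in self.items():
            write_dx(g, out_dir / f"{t}.dx")

    @classmethod
    def load_dir(cls, in_dir: str | Path) -> "FragMapSet":
        in_dir = Path(in_dir)
        maps = {}
        for path in sorted(in_dir.glob("*.dx")):
            g = read_dx(path, map_type=path.stem)
            maps[g.map_type] = g
        if not maps:
            raise FileNotFoundError(f"no .dx maps found in {in_dir}")
        return cls(maps)


# ---------------------------------------------------------------------------
# Snapshot exchange format
# ---------------------------------------------------------------------------

_SNAPSHOT_COLUMNS = ("frame", "x", "y", "z", "types")


def write_snapshots_csv(snapshots: Iterable[SoluteSnapshot], path: str | Path) -> None:
    """Write snapshots as ``frame,x,y,z,types`` rows (types ';'-joined)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SNAPSHOT_COLUMNS)
        for snap in snapshots:
            if not snap.atoms:
                # keep frame count honest for occupancy normalization
                writer.writerow([snap.frame_index, "", "", "", ""])
                continue
            for (x, y, z), types in snap.atoms:
                writer.writerow(
                    [snap.frame_index, f"{x:.4f}", f"{y:.4f}", f"{z:.4f}",
                     ";".join(sorted(types))]
                )


def read_snapshots_csv(path: str | Path) -> list[SoluteSnapshot]:
    path = Path(path)
    frames: dict[int, list] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _SNAPSHOT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        for row in reader:
            frame = int(row["frame"])
            atoms = frames.setdefault(frame, [])
            if row["x"] == "":
                continue  # placeholder row for an empty frame
            types = frozenset(t for t in row["types"].split(";") if t)
            atoms.append(
                ((float(row["x"]), float(row["y"]), float(row["z"])), types)
            )
    return [
        SoluteSnapshot(frame_index=f, atoms=frames[f]) for f in sorted(frames)
    ]
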