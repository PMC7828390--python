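"""Regular cubic-voxel grids and typed volumetric maps.

The lattice convention used throughout: a grid is defined by the *minimum
corner* ``origin``, an isotropic ``spacing`` and integer ``dims``.  Voxel
``(i, j, k)`` covers the half-open interval
``[origin + i*spacing, origin + (i+1)*spacing)`` along each axis and its
center sits at ``origin + (i + 1/2)*spacing``.  Points exactly on a voxel
boundary belong to the higher-index voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_GFE_CAP, DEFAULT_TEMPERATURE

# ---------------------------------------------------------------------------
# Map types
# ---------------------------------------------------------------------------

#: Specific (per-probe-atom) map types and the solute atom each represents.
SPECIFIC_MAP_TYPES = (
    "BENC",   # benzene carbon
    "PRPC",   # propane carbon
    "MEOHD",  # methanol hydroxyl hydrogen (donor)
    "FORHD",  # formamide amide hydrogen (donor)
    "IMIHD",  # imidazole NH hydrogen (donor)
    "MEOO",   # methanol oxygen (acceptor)
    "FORO",   # formamide oxygen (acceptor)
    "AALO",   # acetaldehyde oxygen (acceptor)
    "IMIN",   # imidazole basic nitrogen (acceptor)
    "MAMN",   # methylammonium nitrogen (positive)
    "ACEO",   # acetate oxygen (negative)
)

#: Generic map types as unions of specific types.  A generic map is the
#: voxelwise minimum GFE (maximum probability) over its members.
GENERIC_MAP_COMBINATION: dict[str, frozenset[str]] = {
    "APOLAR": frozenset({"BENC", "PRPC"}),
    "HBDON": frozenset({"MEOHD", "FORHD", "IMIHD"}),
    "HBACC": frozenset({"MEOO", "FORO", "AALO", "IMIN"}),
    "MAMN": frozenset({"MAMN"}),
    "ACEO": frozenset({"ACEO"}),
}

GENERIC_MAP_TYPES = tuple(GENERIC_MAP_COMBINATION)

#: Specific type -> generic class it contributes to.
SPECIFIC_TO_GENERIC: dict[str, str] = {
    specific: generic
    for generic, members in GENERIC_MAP_COMBINATION.items()
    for specific in members
}

ALL_MAP_TYPES = frozenset(SPECIFIC_MAP_TYPES) | frozenset(GENERIC_MAP_TYPES)


def validate_map_type(name: str) -> str:
    if name not in ALL_MAP_TYPES:
        raise ValueError(f"unknown map type {name!r}; known: {sorted(ALL_MAP_TYPES)}")
    return name


# ---------------------------------------------------------------------------
# Grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular cubic-voxel grid (1 Å voxels by default)."""

    origin: tuple[float, float, float]
    spacing: float = 1.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 along every axis")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, Å^3."""
        return self.spacing ** 3

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(o + d * self.spacing for o, d in zip(self.origin, self.dims))

    def voxel_indices(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map points (n, 3) to voxel indices with the half-open convention.

        Returns ``(indices, inside)`` where ``indices`` is (n, 3) int and
        ``inside`` marks points inside the grid extent.  Indices of outside
        points are meaningless and must be masked by the caller.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.origin)) / self.spacing
        idx = np.floor(rel).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        return idx, inside

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an (nx, ny, nz, 3) array."""
        axes = [
            self.origin[a] + (np.arange(self.dims[a]) + 0.5) * self.spacing
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def center_of(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(index) + 0.5) * self.spacing

    def compatible_with(self, other: "GridSpec", atol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= atol
            and all(abs(a - b) <= atol for a, b in zip(self.origin, other.origin))
        )


def require_same_spec(a: GridSpec, b: GridSpec, what: str = "grids") -> None:
    if not a.compatible_with(b):
        raise ValueError(f"{what} are defined on different GridSpecs: {a} vs {b}")


# ---------------------------------------------------------------------------
# Volumetric containers
# ---------------------------------------------------------------------------


@dataclass
class OccupancyGrid:
    """Per-voxel occupancy counts of one probe atom type over a trajectory."""

    spec: GridSpec
    counts: np.ndarray
    n_frames: int
    map_type: str
    overflow: int = 0  # atoms of this type that fell outside the grid

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.spec.dims:
            raise ValueError(
                f"counts shape {self.counts.shape} != grid dims {self.spec.dims}"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if np.any(self.counts < 0):
            raise ValueError("occupancy counts must be non-negative")
        validate_map_type(self.map_type)


@dataclass
class GFEGrid:
    """Grid free energies (kcal/mol) for one map type.

    Zero in bulk solution; negative where probe binding is favorable.
    Unsampled voxels carry the finite cap so downstream Monte Carlo scores
    stay bounded.
    """

    spec: GridSpec
    values: np.ndarray
    map_type: str
    temperature: float = DEFAULT_TEMPERATURE
    gfe_cap: float = DEFAULT_GFE_CAP

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.spec.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GFE values must be finite everywhere")
        if np.any(self.values > self.gfe_cap + 1e-9):
            warnings.warn(
                "GFE values above the declared cap; clipping", stacklevel=2
            )
            self.values = np.minimum(self.values, self.gfe_cap)
        validate_map_type(self.map_type)

    def min_voxel(self) -> tuple[tuple[int, int, int], float]:
        """Index and value of the most favorable voxel."""
        flat = int(np.argmin(self.values))
        idx = np.unravel_index(flat, self.values.shape)
        return tuple(int(i) for i in idx), float(self.values[idx])
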