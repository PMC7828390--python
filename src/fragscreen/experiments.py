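"""Self-contained verification experiments with planted ground truth.

These drive the package's own estimators against independent references:
a grand-canonical run over a planted Gaussian well checked against the
Boltzmann law, and Monte Carlo docking checked against exhaustive
enumeration over translations and orientations.  They are used by the
test suite and by the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .docking import MCParams, SamplingBox, mc_dock
from .fragmaps import FragMapSet, bin_atoms, occupancy_to_gfe
from .gcmc import FieldDefinition, GCMCParams, GaussianTerm, ProbeSpec, run_gcmc
from .grid import GFEGrid, GridSpec
from .ligand import Atom, Ligand

#: Exchange-heavy move mix used for field-recovery runs: insertions and
#: deletions decorrelate the slowly exchanging well occupancy far faster
#: than local translations do.
RECOVERY_MOVE_MIX = {"insert": 0.45, "delete": 0.45, "translate": 0.1, "rotate": 0.0}


@dataclass
class WellRecoveryResult:
    planted_depth: float
    recovered_depth: float
    planted_voxel: tuple[int, int, int]
    recovered_voxel: tuple[int, int, int]
    n_frames: int

    @property
    def voxel_error(self) -> int:
        """Chebyshev distance between planted and recovered minima, voxels."""
        return int(
            max(abs(a - b) for a, b in zip(self.planted_voxel, self.recovered_voxel))
        )


def recover_planted_well(
    depth: float = -2.0,
    width: float = 2.0,
    box_edge: int = 20,
    n_cycles: int = 200_000,
    steps_per_cycle: int = 100,
    seed: int = 3,
) -> WellRecoveryResult:
    """Grand-canonical sampling over one planted Gaussian well, then the
    occupancy → bulk-normalized probability → grid free energy chain.

    The well center sits at a voxel center, so the recovered minimum can
    be compared to the planted depth up to voxel-averaging of the
    Boltzmann factor (a few hundredths of a kcal/mol at these widths).
    """
    spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(box_edge,) * 3)
    center = tuple(box_edge / 2.0 + 0.5 for _ in range(3))
    field = FieldDefinition(
        box=spec,
        terms=[GaussianTerm(center=center, depth=depth, width=width, map_type="APOLAR")],
    )
    probes = (ProbeSpec.single_site("benzene", {"BENC"}),)
    params = GCMCParams(
        n_cycles=n_cycles,
        steps_per_cycle=steps_per_cycle,
        move_mix=dict(RECOVERY_MOVE_MIX),
        seed=seed,
    )
    snapshots, _, _ = run_gcmc(field, probes, params)
    occ = bin_atoms(snapshots, "BENC", spec)
    gfe = occupancy_to_gfe(occ, bulk_strategy="shell", margin=2)
    idx, value = gfe.min_voxel()
    planted_voxel = tuple(int(c - 0.5) for c in center)
    return WellRecoveryResult(
        planted_depth=depth,
        recovered_depth=value,
        planted_voxel=planted_voxel,
        recovered_voxel=idx,
        n_frames=occ.n_frames,
    )


# ---------------------------------------------------------------------------
# Docking vs exhaustive enumeration
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit vectors (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def two_atom_ligand(bond_length: float = 1.0, map_class: str = "APOLAR") -> Ligand:
    return Ligand(
        id="diatomic",
        atoms=[
            Atom("C", (0.0, 0.0, 0.0), classes=frozenset({map_class})),
            Atom("C", (bond_length, 0.0, 0.0), classes=frozenset({map_class})),
        ],
        bonds=[(0, 1, 1)],
    )


def enumerate_min_lgfe_diatomic(
    maps: FragMapSet,
    bond_length: float = 1.0,
    translation_step: float = 0.5,
    n_orientations: int = 128,
    chunk: int = 200_000,
) -> float:
    """Exhaustive minimum LGFE of a rigid two-atom ligand.

    Enumerates the first atom over a dense translation lattice and the
    bond direction over a Fibonacci sphere, scoring both atoms with the
    same trilinear interpolation as the docking path; independent of the
    Monte Carlo machinery.
    """
    ligand = two_atom_ligand(bond_length)
    spec = maps.spec
    axes = [
        np.arange(spec.origin[a] + 0.5, spec.origin[a] + spec.dims[a] * spec.spacing - 0.5 + 1e-9, translation_step)
        for a in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    positions = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    directions = _fibonacci_directions(n_orientations) * bond_length

    best = math.inf
    for start in range(0, len(positions), max(1, chunk // n_orientations)):
        pos = positions[start : start + max(1, chunk // n_orientations)]
        a1 = np.broadcast_to(
            pos[:, None, :], (len(pos), n_orientations, 3)
        ).reshape(-1, 3)
        a2 = (pos[:, None, :] + directions[None, :, :]).reshape(-1, 3)
        total = _interp_many(maps, a1) + _interp_many(maps, a2)
        m = float(total.min())
        if m < best:
            best = m
    return best


def _interp_many(maps: FragMapSet, points: np.ndarray, map_type: str = "APOLAR") -> np.ndarray:
    """Vectorized trilinear interpolation on voxel-center nodes."""
    grid = maps[map_type]
    spec = grid.spec
    g = (points - np.asarray(spec.origin)) / spec.spacing - 0.5
    i0 = np.floor(g).astype(int)
    outside = np.any((i0 < 0) | (i0 + 1 > np.asarray(spec.dims) - 1), axis=1)
    i0c = np.clip(i0, 0, np.asarray(spec.dims) - 2)
    f = g - i0c
    v = np.zeros(len(points))
    vals = grid.values
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                v += w * vals[i0c[:, 0] + dx, i0c[:, 1] + dy, i0c[:, 2] + dz]
    v[outside] = grid.gfe_cap
    return v


def make_two_well_map(
    dims: tuple[int, int, int] = (10, 10, 10),
    global_center: tuple[float, float, float] = (3.5, 3.5, 3.5),
    global_depth: float = -3.0,
    local_center: tuple[float, float, float] = (7.5, 7.5, 7.5),
    local_depth: float = -2.0,
    width: float = 1.6,
) -> FragMapSet:
    """A smooth APOLAR test map with a global and a decoy local minimum."""
    spec = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=dims)
    centers = spec.voxel_centers()
    values = global_depth * np.exp(
        -np.sum((centers - np.asarray(global_center)) ** 2, axis=-1) / (2 * width**2)
    ) + local_depth * np.exp(
        -np.sum((centers - np.asarray(local_center)) ** 2, axis=-1) / (2 * width**2)
    )
    return FragMapSet(
        {"APOLAR": GFEGrid(spec=spec, values=values, map_type="APOLAR")}
    )


def docking_enumeration_agreement(
    n_seeds: int = 50,
    tolerance: float = 0.1,
    maps: FragMapSet | None = None,
    params: MCParams = MCParams(),
    base_seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Fraction of seeded docking runs matching the enumeration optimum.

    Returns ``(agreement_fraction, enumeration_minimum, docked_lgfes)``.
    """
    if maps is None:
        maps = make_two_well_map()
    enum_min = enumerate_min_lgfe_diatomic(maps)
    ligand = two_atom_ligand()
    spec = maps.spec
    center = tuple(
        spec.origin[a] + spec.dims[a] * spec.spacing / 2.0 for a in range(3)
    )
    edge = max(spec.dims) * spec.spacing
    box = SamplingBox(center=center, edge=edge)
    lgfes = [
        mc_dock(ligand, box, maps, params, seed=base_seed + s).lgfe
        for s in range(n_seeds)
    ]
    hits = sum(1 for v in lgfes if abs(v - enum_min) <= tolerance)
    return hits / n_seeds, enum_min, lgfes
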