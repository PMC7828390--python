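"""Fragment docking into grid free energy maps by Metropolis MC with
simulated annealing, LGFE scoring, and hotspot identification.

The ligand grid free energy (LGFE) of a pose is the sum over classified
atoms of the (trilinearly interpolated) GFE of that atom's map class at
the atom position; it approximates the binding free energy.  Docking runs
a Metropolis chain of rigid translations/rotations and dihedral twists at
a fixed exploration temperature, followed by simulated annealing with a
linearly decaying temperature and tight move maxima.  The reported pose
of a run is the lowest-LGFE configuration visited, so annealing can never
worsen the reported score.

Hotspot search tiles the target-extent volume into cubic sampling boxes
(edge 14.14 Å by default), repeats seeded docking runs per fragment per
box, removes redundancy by greedy leader clustering of pose centroids per
fragment (round 1), then clusters the surviving representatives across
fragments (round 2) into ranked putative binding sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .constants import DOCKING_TEMPERATURE, K_B
from .fragmaps import FragMapSet
from .ligand import Ligand, Pose

log = logging.getLogger(__name__)

_INTERP_TRILINEAR = 0
_INTERP_NEAREST = 1


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCParams:
    """Docking Monte Carlo protocol parameters.

    Defaults follow the full-scale protocol: 10,000 Metropolis steps at
    300 K with moves up to 1.0 Å / 180° / 180°, then 40,000 simulated-
    annealing steps from 300 to 0 K with moves up to 0.2 Å / 9° / 9°,
    and 1000 independent replicates per sampling box for hotspot search.
    """

    n_mc_steps: int = 10_000
    mc_temperature: float = DOCKING_TEMPERATURE
    max_translation: float = 1.0     # Å
    max_rotation: float = 180.0      # degrees
    max_dihedral: float = 180.0      # degrees
    n_anneal_steps: int = 40_000
    anneal_t_start: float = DOCKING_TEMPERATURE
    anneal_t_end: float = 0.0
    anneal_max_translation: float = 0.2
    anneal_max_rotation: float = 9.0
    anneal_max_dihedral: float = 9.0
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "max_translation", "max_rotation", "max_dihedral",
            "anneal_max_translation", "anneal_max_rotation",
            "anneal_max_dihedral",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.anneal_t_end > self.anneal_t_start:
            raise ValueError("annealing schedule must be non-increasing")


@dataclass(frozen=True)
class SamplingBox:
    """Cubic region a docking run is launched from."""

    center: tuple[float, float, float]
    edge: float = 14.14  # Å
    id: int = 0

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("edge must be positive")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - self.edge / 2.0

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + self.edge / 2.0


@dataclass(frozen=True)
class ClusterParams:
    round1_cutoff: float = 2.0  # Å, per-fragment redundancy removal
    round2_cutoff: float = 3.0  # Å, cross-fragment hotspot merging


@dataclass
class HotspotCluster:
    """A ranked putative binding site shared by one or more fragments."""

    id: int
    representative_poses: dict[str, Pose]  # fragment id -> best pose
    member_fragments: set[str]
    centroid: np.ndarray
    rank_score: float  # mean of members' LGFE; lower (more favorable) first


# ---------------------------------------------------------------------------
# LGFE evaluation (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _interp_value(map3d, ox, oy, oz, spacing, cap, x, y, z, mode):
    nx, ny, nz = map3d.shape
    gx = (x - ox) / spacing - 0.5
    gy = (y - oy) / spacing - 0.5
    gz = (z - oz) / spacing - 0.5
    if mode == _INTERP_NEAREST:
        i = int(math.floor(gx + 0.5))
        j = int(math.floor(gy + 0.5))
        k = int(math.floor(gz + 0.5))
        if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
            return cap
        return map3d[i, j, k]
    i = int(math.floor(gx))
    j = int(math.floor(gy))
    k = int(math.floor(gz))
    if i < 0 or j < 0 or k < 0 or i + 1 >= nx or j + 1 >= ny or k + 1 >= nz:
        return cap
    fx = gx - i
    fy = gy - j
    fz = gz - k
    c00 = map3d[i, j, k] * (1 - fx) + map3d[i + 1, j, k] * fx
    c10 = map3d[i, j + 1, k] * (1 - fx) + map3d[i + 1, j + 1, k] * fx
    c01 = map3d[i, j, k + 1] * (1 - fx) + map3d[i + 1, j, k + 1] * fx
    c11 = map3d[i, j + 1, k + 1] * (1 - fx) + map3d[i + 1, j + 1, k + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=False)
def _eval_pose(maps, map_ids, coords, ox, oy, oz, spacing, cap, mode, per_atom):
    total = 0.0
    n_atoms = coords.shape[0]
    for a in range(n_atoms):
        best = 0.0
        found = False
        for c in range(map_ids.shape[1]):
            mid = map_ids[a, c]
            if mid < 0:
                continue
            v = _interp_value(
                maps[mid], ox, oy, oz, spacing, cap,
                coords[a, 0], coords[a, 1], coords[a, 2], mode,
            )
            if (not found) or v < best:
                best = v
                found = True
        per_atom[a] = best if found else 0.0
        total += per_atom[a]
    return total


@njit(cache=False)
def _rotate_subset(coords_in, coords_out, mask, px, py, pz, ax, ay, az, angle):
    """Rodrigues rotation of masked atoms about axis (a) through pivot (p)."""
    ca = math.cos(angle)
    sa = math.sin(angle)
    for i in range(coords_in.shape[0]):
        if not mask[i]:
            coords_out[i, 0] = coords_in[i, 0]
            coords_out[i, 1] = coords_in[i, 1]
            coords_out[i, 2] = coords_in[i, 2]
            continue
        vx = coords_in[i, 0] - px
        vy = coords_in[i, 1] - py
        vz = coords_in[i, 2] - pz
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        coords_out[i, 0] = px + vx * ca + cx * sa + ax * dot * (1 - ca)
        coords_out[i, 1] = py + vy * ca + cy * sa + ay * dot * (1 - ca)
        coords_out[i, 2] = pz + vz * ca + cz * sa + az * dot * (1 - ca)


@njit(cache=False)
def _mc_chain(
    coords, maps, map_ids, ox, oy, oz, spacing, cap, mode,
    temps, move_kind, trans_vec, rot_axis, rot_angle,
    tor_index, tor_angle, u_rand, tor_axes, tor_moved, kb,
    box_lo, box_hi,
):
    """Run one Metropolis chain in place; returns (final, best) LGFE and
    stores the best-visited coordinates back into ``coords``'s companion
    output array.  The chain mutates ``coords``."""
    n_atoms = coords.shape[0]
    n_steps = temps.shape[0]
    per_atom = np.zeros(n_atoms)
    new_coords = np.empty_like(coords)
    all_mask = np.ones(n_atoms, dtype=np.bool_)
    cur = _eval_pose(maps, map_ids, coords, ox, oy, oz, spacing, cap, mode, per_atom)
    best = cur
    best_coords = coords.copy()

    for s in range(n_steps):
        k = move_kind[s]
        if k == 0:  # rigid translation
            for a in range(n_atoms):
                new_coords[a, 0] = coords[a, 0] + trans_vec[s, 0]
                new_coords[a, 1] = coords[a, 1] + trans_vec[s, 1]
                new_coords[a, 2] = coords[a, 2] + trans_vec[s, 2]
        elif k == 1:  # rigid rotation about the centroid
            px = 0.0
            py = 0.0
            pz = 0.0
            for a in range(n_atoms):
                px += coords[a, 0]
                py += coords[a, 1]
                pz += coords[a, 2]
            px /= n_atoms
            py /= n_atoms
            pz /= n_atoms
            _rotate_subset(
                coords, new_coords, all_mask, px, py, pz,
                rot_axis[s, 0], rot_axis[s, 1], rot_axis[s, 2], rot_angle[s],
            )
        else:  # dihedral twist about a rotatable bond
            t = tor_index[s]
            b = tor_axes[t, 0]
            c = tor_axes[t, 1]
            ax = coords[c, 0] - coords[b, 0]
            ay = coords[c, 1] - coords[b, 1]
            az = coords[c, 2] - coords[b, 2]
            norm = math.sqrt(ax * ax + ay * ay + az * az)
            if norm == 0.0:
                continue
            _rotate_subset(
                coords, new_coords, tor_moved[t],
                coords[b, 0], coords[b, 1], coords[b, 2],
                ax / norm, ay / norm, az / norm, tor_angle[s],
            )
        # confine the ligand centroid to the sampling box
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for a in range(n_atoms):
            cx += new_coords[a, 0]
            cy += new_coords[a, 1]
            cz += new_coords[a, 2]
        cx /= n_atoms
        cy /= n_atoms
        cz /= n_atoms
        if (
            cx < box_lo[0] or cx > box_hi[0]
            or cy < box_lo[1] or cy > box_hi[1]
            or cz < box_lo[2] or cz > box_hi[2]
        ):
            continue
        new_total = _eval_pose(
            maps, map_ids, new_coords, ox, oy, oz, spacing, cap, mode, per_atom
        )
        du = new_total - cur
        accept = du <= 0.0
        if not accept:
            t_now = temps[s]
            if t_now > 1e-12 and u_rand[s] < math.exp(-du / (kb * t_now)):
                accept = True
        if accept:
            for a in range(n_atoms):
                coords[a, 0] = new_coords[a, 0]
                coords[a, 1] = new_coords[a, 1]
                coords[a, 2] = new_coords[a, 2]
            cur = new_total
            if cur < best:
                best = cur
                for a in range(n_atoms):
                    best_coords[a, 0] = coords[a, 0]
                    best_coords[a, 1] = coords[a, 1]
                    best_coords[a, 2] = coords[a, 2]
    return cur, best, best_coords


# ---------------------------------------------------------------------------
# Map packing and public LGFE
# ---------------------------------------------------------------------------


def _pack_maps(maps: FragMapSet):
    names = sorted(maps)
    stack = np.ascontiguousarray(
        np.stack([maps[n].values for n in names]), dtype=np.float64
    )
    index = {n: i for i, n in enumerate(names)}
    spec = maps.spec
    return stack, index, spec, float(maps.gfe_cap)


def _atom_map_ids(ligand: Ligand, index: Mapping[str, int]) -> np.ndarray:
    rows = []
    width = max(1, max((len(a.classes) for a in ligand.atoms), default=1))
    any_mapped = False
    for a in ligand.atoms:
        ids = sorted(index[c] for c in a.classes if c in index)
        if ids:
            any_mapped = True
        rows.append(ids + [-1] * (width - len(ids)))
    if not any_mapped:
        raise ValueError(
            f"ligand {ligand.id!r}: no map available for any atom class "
            f"(maps: {sorted(index)})"
        )
    return np.asarray(rows, dtype=np.int64)


def lgfe(
    ligand: Ligand,
    maps: FragMapSet,
    coords: np.ndarray | None = None,
    interpolation: str = "trilinear",
) -> tuple[float, np.ndarray]:
    """Ligand grid free energy of a configuration, with per-atom breakdown.

    Each classified atom contributes the interpolated GFE of its most
    favorable applicable map at its position (multi-class atoms take the
    minimum over their classes, avoiding double counting); unclassified
    atoms contribute 0; atoms outside the map bounds score the GFE cap.
    """
    mode = {"trilinear": _INTERP_TRILINEAR, "nearest": _INTERP_NEAREST}[interpolation]
    stack, index, spec, cap = _pack_maps(maps)
    map_ids = _atom_map_ids(ligand, index)
    xyz = np.ascontiguousarray(
        ligand.coords if coords is None else np.asarray(coords, dtype=float)
    )
    per_atom = np.zeros(len(ligand.atoms))
    total = _eval_pose(
        stack, map_ids, xyz,
        spec.origin[0], spec.origin[1], spec.origin[2],
        spec.spacing, cap, mode, per_atom,
    )
    return float(total), per_atom


def measure_torsions(ligand: Ligand, coords: np.ndarray) -> tuple:
    """Dihedral angles (degrees) of the ligand's rotatable torsions."""
    out = []
    for a, b, c, d in ligand.rotatable_torsions:
        b0 = coords[a] - coords[b]
        b1 = coords[c] - coords[b]
        b2 = coords[d] - coords[c]
        b1n = b1 / np.linalg.norm(b1)
        v = b0 - np.dot(b0, b1n) * b1n
        w = b2 - np.dot(b2, b1n) * b1n
        out.append(math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w))))
    return tuple(out)


# ---------------------------------------------------------------------------
# Docking
# ---------------------------------------------------------------------------


def _random_start(
    ligand: Ligand, box: SamplingBox, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random placement: centroid in the box, random orientation,
    random dihedral angles."""
    coords = ligand.coords.copy()
    # random torsions
    for t_i, torsion in enumerate(ligand.rotatable_torsions):
        moved = sorted(ligand.torsion_moved_atoms(torsion))
        if not moved:
            continue
        _, b, c, _ = torsion
        axis = coords[c] - coords[b]
        norm = np.linalg.norm(axis)
        if norm == 0:
            continue
        axis /= norm
        angle = rng.uniform(-math.pi, math.pi)
        mask = np.zeros(len(coords), dtype=bool)
        mask[moved] = True
        out = np.empty_like(coords)
        _rotate_subset(
            coords, out, mask, coords[b][0], coords[b][1], coords[b][2],
            axis[0], axis[1], axis[2], angle,
        )
        coords = out
    # random rigid orientation about the centroid
    centroid = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-math.pi, math.pi)
    out = np.empty_like(coords)
    _rotate_subset(
        coords, out, np.ones(len(coords), dtype=bool),
        centroid[0], centroid[1], centroid[2],
        axis[0], axis[1], axis[2], angle,
    )
    coords = out
    # centroid uniform in the box
    target = box.lo + rng.random(3) * (box.hi - box.lo)
    coords += target - coords.mean(axis=0)
    return np.ascontiguousarray(coords)


def _chain_randoms(
    rng: np.random.Generator,
    n_steps: int,
    n_torsions: int,
    max_trans: float,
    max_rot_deg: float,
    max_dihedral_deg: float,
):
    n_kinds = 3 if n_torsions > 0 else 2
    move_kind = rng.integers(0, n_kinds, size=n_steps).astype(np.int64)
    direction = rng.normal(size=(n_steps, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = max_trans * rng.random(n_steps) ** (1.0 / 3.0)
    trans_vec = direction * radius[:, None]
    rot_axis = rng.normal(size=(n_steps, 3))
    rot_axis /= np.linalg.norm(rot_axis, axis=1, keepdims=True)
    rot_angle = np.radians(rng.uniform(-max_rot_deg, max_rot_deg, size=n_steps))
    if n_torsions > 0:
        tor_index = rng.integers(0, n_torsions, size=n_steps).astype(np.int64)
    else:
        tor_index = np.zeros(n_steps, dtype=np.int64)
    tor_angle = np.radians(
        rng.uniform(-max_dihedral_deg, max_dihedral_deg, size=n_steps)
    )
    u_rand = rng.random(n_steps)
    return move_kind, trans_vec, rot_axis, rot_angle, tor_index, tor_angle, u_rand


def _torsion_arrays(ligand: Ligand):
    n_t = len(ligand.rotatable_torsions)
    n_atoms = len(ligand.atoms)
    tor_axes = np.zeros((max(n_t, 1), 2), dtype=np.int64)
    tor_moved = np.zeros((max(n_t, 1), n_atoms), dtype=np.bool_)
    for t_i, torsion in enumerate(ligand.rotatable_torsions):
        tor_axes[t_i] = (torsion[1], torsion[2])
        for a in ligand.torsion_moved_atoms(torsion):
            tor_moved[t_i, a] = True
    return tor_axes, tor_moved


def mc_dock(
    ligand: Ligand,
    box: SamplingBox,
    maps: FragMapSet,
    params: MCParams = MCParams(),
    seed: int | None = None,
    interpolation: str = "trilinear",
) -> Pose:
    """One docking run: exploration Metropolis stage then simulated
    annealing; returns the lowest-LGFE configuration visited.

    Deterministic for a given seed (defaults to ``params.seed``).
    """
    mode = {"trilinear": _INTERP_TRILINEAR, "nearest": _INTERP_NEAREST}[interpolation]
    stack, index, spec, cap = _pack_maps(maps)
    lo = np.asarray(spec.origin)
    hi = np.asarray(spec.upper)
    if np.any(np.asarray(box.center) < lo) or np.any(np.asarray(box.center) >= hi):
        raise ValueError(
            f"sampling box center {box.center} outside map extent [{lo}, {hi})"
        )
    map_ids = _atom_map_ids(ligand, index)
    tor_axes, tor_moved = _torsion_arrays(ligand)
    n_torsions = len(ligand.rotatable_torsions)
    rng = np.random.default_rng(params.seed if seed is None else seed)

    coords = _random_start(ligand, box, rng)
    args_geo = (
        stack, map_ids,
        spec.origin[0], spec.origin[1], spec.origin[2], spec.spacing, cap, mode,
    )

    # Stage 1: fixed-temperature exploration.
    temps1 = np.full(params.n_mc_steps, params.mc_temperature)
    rnd1 = _chain_randoms(
        rng, params.n_mc_steps, n_torsions,
        params.max_translation, params.max_rotation, params.max_dihedral,
    )
    box_lo = np.ascontiguousarray(box.lo, dtype=float)
    box_hi = np.ascontiguousarray(box.hi, dtype=float)
    _, best1, best1_coords = _mc_chain(
        coords, args_geo[0], args_geo[1], *args_geo[2:],
        temps1, *rnd1, tor_axes, tor_moved, K_B, box_lo, box_hi,
    )

    # Stage 2: simulated annealing from the stage-1 endpoint.
    temps2 = np.linspace(
        params.anneal_t_start, params.anneal_t_end, params.n_anneal_steps
    )
    rnd2 = _chain_randoms(
        rng, params.n_anneal_steps, n_torsions,
        params.anneal_max_translation, params.anneal_max_rotation,
        params.anneal_max_dihedral,
    )
    _, best2, best2_coords = _mc_chain(
        coords, args_geo[0], args_geo[1], *args_geo[2:],
        temps2, *rnd2, tor_axes, tor_moved, K_B, box_lo, box_hi,
    )

    if best2 <= best1:
        best_coords = best2_coords
    else:
        best_coords = best1_coords
    per_atom = np.zeros(len(ligand.atoms))
    total = _eval_pose(
        stack, map_ids, np.ascontiguousarray(best_coords),
        spec.origin[0], spec.origin[1], spec.origin[2], spec.spacing, cap,
        mode, per_atom,
    )
    return Pose(
        ligand_id=ligand.id,
        coords=best_coords,
        lgfe=float(total),
        per_atom_gfe=per_atom,
        torsion_angles=measure_torsions(ligand, best_coords),
        box_id=box.id,
    )


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


def tile_sampling_boxes(
    lo: Sequence[float], hi: Sequence[float], edge: float = 14.14
) -> list[SamplingBox]:
    """Cubic boxes of the given edge tiling the bounding volume [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(hi <= lo):
        raise ValueError("empty extent")
    counts = np.maximum(1, np.ceil((hi - lo) / edge).astype(int))
    # center the tiling on the extent so the overhang is symmetric and
    # every box center stays inside the mapped volume
    start = lo + ((hi - lo) - counts * edge) / 2.0
    boxes = []
    bid = 0
    for i in range(counts[0]):
        for j in range(counts[1]):
            for k in range(counts[2]):
                center = start + (np.asarray([i, j, k]) + 0.5) * edge
                boxes.append(SamplingBox(center=tuple(center), edge=edge, id=bid))
                bid += 1
    return boxes


def _leader_cluster(poses: list[Pose], cutoff: float) -> list[list[Pose]]:
    """Greedy leader clustering on pose centroids, seeded by LGFE rank.

    Poses are visited from most to least favorable; each joins the first
    cluster whose leader centroid lies within ``cutoff``, else founds a
    new cluster.  Leaders are therefore the lowest-LGFE members."""
    clusters: list[list[Pose]] = []
    leaders: list[np.ndarray] = []
    for pose in sorted(poses, key=lambda p: p.lgfe):
        c = pose.centroid
        for ci, leader in enumerate(leaders):
            if np.linalg.norm(c - leader) <= cutoff:
                clusters[ci].append(pose)
                break
        else:
            clusters.append([pose])
            leaders.append(c)
    return clusters


def hotspots(
    ligands: Sequence[Ligand],
    maps: FragMapSet,
    extent: tuple[Sequence[float], Sequence[float]] | None = None,
    params: MCParams = MCParams(),
    clustering: ClusterParams = ClusterParams(),
    box_edge: float = 14.14,
    seed: int | None = None,
) -> list[HotspotCluster]:
    """Two-round hotspot search over the whole target extent.

    ``extent`` defaults to the map extent.  Per fragment and sampling box,
    ``params.n_replicates`` seeded docking runs are launched; round-1
    clustering removes redundant poses per fragment (keeping the best pose
    per site), round-2 clustering merges representatives across fragments
    into hotspots ranked by mean member LGFE (ascending).
    """
    if not ligands:
        raise ValueError("empty fragment set")
    spec = maps.spec
    if extent is None:
        extent = (spec.origin, spec.upper)
    boxes = tile_sampling_boxes(extent[0], extent[1], edge=box_edge)
    base_seed = params.seed if seed is None else seed
    seed_seq = np.random.SeedSequence(base_seed)

    representatives: dict[str, list[Pose]] = {}
    for li, ligand in enumerate(ligands):
        reps: list[Pose] = []
        for box in boxes:
            child = np.random.SeedSequence(
                entropy=seed_seq.entropy, spawn_key=(li, box.id)
            )
            run_seeds = child.generate_state(params.n_replicates)
            poses = [
                mc_dock(ligand, box, maps, params, seed=int(s))
                for s in run_seeds
            ]
            for cluster in _leader_cluster(poses, clustering.round1_cutoff):
                reps.append(min(cluster, key=lambda p: p.lgfe))
        representatives[ligand.id] = reps

    all_reps = [p for reps in representatives.values() for p in reps]
    clusters = _leader_cluster(all_reps, clustering.round2_cutoff)

    out: list[HotspotCluster] = []
    for poses in clusters:
        best_by_fragment: dict[str, Pose] = {}
        for p in poses:
            cur = best_by_fragment.get(p.ligand_id)
            if cur is None or p.lgfe < cur.lgfe:
                best_by_fragment[p.ligand_id] = p
        members = set(best_by_fragment)
        centroid = np.mean([p.centroid for p in best_by_fragment.values()], axis=0)
        rank_score = float(
            np.mean([p.lgfe for p in best_by_fragment.values()])
        )
        out.append(
            HotspotCluster(
                id=-1,
                representative_poses=best_by_fragment,
                member_fragments=members,
                centroid=centroid,
                rank_score=rank_score,
            )
        )
    out.sort(key=lambda h: h.rank_score)
    for i, h in enumerate(out):
        h.id = i
    return out


# ---------------------------------------------------------------------------
# NMR-consistent pose selection
# ---------------------------------------------------------------------------


def select_pose_consistent_with_nmr(
    poses: Sequence[Pose],
    perturbed_residues: set,
    residue_coords: Mapping,
    contact_cutoff: float = 5.0,
) -> Pose:
    """Pick the candidate pose most consistent with the NMR perturbations.

    The winner maximizes the number of perturbed residues having any
    residue–ligand atom distance within ``contact_cutoff`` (Å); ties break
    toward the lower (more favorable) LGFE.
    """
    if not poses:
        raise ValueError("empty pose list")
    missing = [r for r in perturbed_residues if r not in residue_coords]
    if missing:
        raise ValueError(f"no coordinates for perturbed residue(s) {missing}")
    res_xyz = {r: np.asarray(residue_coords[r], dtype=float) for r in perturbed_residues}

    def contacts(pose: Pose) -> int:
        n = 0
        for xyz in res_xyz.values():
            d = np.linalg.norm(pose.coords - xyz, axis=1)
            if np.any(d <= contact_cutoff):
                n += 1
        return n

    return max(poses, key=lambda p: (contacts(p), -p.lgfe))
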