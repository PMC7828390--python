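"""Grand-canonical Monte Carlo sampling of rigid solute probes in a fixed field.

A desk-scale stand-in for the oscillating-μ GCMC stage of cosolvent
mapping: rigid probes are inserted, deleted, translated and rotated in an
external potential field built from Gaussian wells/barriers and hard-core
exclusions, with the excess chemical potential of each probe type retuned
every few cycles so the box concentration tracks a set-point (0.25 M by
default).  Probe-probe interactions and explicit water are not modelled —
at 0.25 M the probes are nearly ideal, and the water's competitive role is
folded into the effective field.  The emitted snapshots feed the occupancy
binning of :mod:`fragscreen.fragmaps`.

Acceptance rules are the standard grand-canonical ones with activity
z = c_target * exp(μ_excess / k_B T) (particles/Å^3), so that μ_excess = 0
reproduces the target concentration exactly in a flat field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .constants import (
    DEFAULT_CONCENTRATION,
    DEFAULT_TEMPERATURE,
    K_B,
    PARTICLES_PER_A3_PER_MOLAR,
)
from .fragmaps import SoluteSnapshot
from .grid import GridSpec, SPECIFIC_TO_GENERIC

log = logging.getLogger(__name__)

MOVE_KINDS = ("insert", "delete", "translate", "rotate")


# ---------------------------------------------------------------------------
# Field definition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianTerm:
    """Isotropic Gaussian well (depth < 0) or barrier (depth > 0).

    ``map_type`` restricts the term to probe sites of one map class
    (generic or specific); None applies it to every site.
    """

    center: tuple[float, float, float]
    depth: float  # kcal/mol at the center
    width: float  # Å (Gaussian sigma)
    map_type: str | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")

    def applies_to(self, site_types: frozenset[str]) -> bool:
        if self.map_type is None:
            return True
        if self.map_type in site_types:
            return True
        return any(
            SPECIFIC_TO_GENERIC.get(t) == self.map_type for t in site_types
        )


@dataclass(frozen=True)
class ExclusionSphere:
    """Hard-core region (e.g. a pseudo-protein interior); infinite energy."""

    center: tuple[float, float, float]
    radius: float


@dataclass
class FieldDefinition:
    """External potential for probe sampling over a rectangular box."""

    box: GridSpec
    terms: list[GaussianTerm] = dc_field(default_factory=list)
    exclusions: list[ExclusionSphere] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self._term_cache: dict[frozenset, tuple] = {}

    @property
    def volume(self) -> float:
        """Box volume, Å^3."""
        return self.box.n_voxels * self.box.voxel_volume

    def _terms_for(self, site_types: frozenset[str]):
        cached = self._term_cache.get(site_types)
        if cached is None:
            active = [t for t in self.terms if t.applies_to(site_types)]
            if active:
                centers = np.asarray([t.center for t in active], dtype=float)
                depths = np.asarray([t.depth for t in active], dtype=float)
                inv2w2 = 1.0 / (2.0 * np.asarray([t.width for t in active]) ** 2)
            else:
                centers = np.zeros((0, 3))
                depths = np.zeros(0)
                inv2w2 = np.zeros(0)
            cached = (centers, depths, inv2w2)
            self._term_cache[site_types] = cached
        return cached

    def energy(self, point: np.ndarray, site_types: frozenset[str]) -> float:
        """Potential energy (kcal/mol) of one probe site at ``point``."""
        point = np.asarray(point, dtype=float)
        for excl in self.exclusions:
            if np.sum((point - np.asarray(excl.center)) ** 2) < excl.radius**2:
                return math.inf
        centers, depths, inv2w2 = self._terms_for(site_types)
        if depths.size == 0:
            return 0.0
        d2 = np.sum((centers - point) ** 2, axis=1)
        return float(np.sum(depths * np.exp(-d2 * inv2w2)))

    def energy_many(self, points: np.ndarray, site_types: frozenset[str]) -> np.ndarray:
        """Vectorized :meth:`energy` for an (n, 3) array of points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.zeros(len(points))
        centers, depths, inv2w2 = self._terms_for(site_types)
        if depths.size:
            d2 = np.sum(
                (points[:, None, :] - centers[None, :, :]) ** 2, axis=2
            )
            u = np.sum(depths * np.exp(-d2 * inv2w2), axis=1)
        for excl in self.exclusions:
            inside = (
                np.sum((points - np.asarray(excl.center)) ** 2, axis=1)
                < excl.radius**2
            )
            u[inside] = math.inf
        return u

    # -- YAML exchange ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "box": {
                "origin": list(self.box.origin),
                "spacing": self.box.spacing,
                "dims": list(self.box.dims),
            },
            "terms": [
                {
                    "center": list(t.center),
                    "depth": t.depth,
                    "width": t.width,
                    "map_type": t.map_type,
                }
                for t in self.terms
            ],
            "exclusions": [
                {"center": list(e.center), "radius": e.radius}
                for e in self.exclusions
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldDefinition":
        doc = yaml.safe_load(Path(path).read_text())
        box = GridSpec(
            origin=tuple(doc["box"]["origin"]),
            spacing=float(doc["box"]["spacing"]),
            dims=tuple(doc["box"]["dims"]),
        )
        terms = [
            GaussianTerm(
                center=tuple(t["center"]),
                depth=float(t["depth"]),
                width=float(t["width"]),
                map_type=t.get("map_type"),
            )
            for t in doc.get("terms", [])
        ]
        exclusions = [
            ExclusionSphere(center=tuple(e["center"]), radius=float(e["radius"]))
            for e in doc.get("exclusions", [])
        ]
        return cls(box=box, terms=terms, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Probes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeSpec:
    """A rigid probe: one or more sites at fixed body-frame offsets,
    each carrying the specific map types it is binned into."""

    name: str
    sites: tuple[tuple[tuple[float, float, float], frozenset[str]], ...]

    @classmethod
    def single_site(cls, name: str, types) -> "ProbeSpec":
        return cls(name=name, sites=((((0.0, 0.0, 0.0)), frozenset(types)),))

    @property
    def n_sites(self) -> int:
        return len(self.sites)


#: One probe per representative cosolvent solute.  Single interaction
#: sites; a site may carry both a donor and an acceptor type (e.g.
#: methanol's hydroxyl), in which case it is binned into both maps.
DEFAULT_PROBE_SET: tuple[ProbeSpec, ...] = (
    ProbeSpec.single_site("benzene", {"BENC"}),
    ProbeSpec.single_site("propane", {"PRPC"}),
    ProbeSpec.single_site("methanol", {"MEOO", "MEOHD"}),
    ProbeSpec.single_site("formamide", {"FORO", "FORHD"}),
    ProbeSpec.single_site("acetaldehyde", {"AALO"}),
    ProbeSpec.single_site("imidazole", {"IMIN", "IMIHD"}),
    ProbeSpec.single_site("methylammonium", {"MAMN"}),
    ProbeSpec.single_site("acetate", {"ACEO"}),
)


def probes_from_yaml(path: str | Path) -> tuple[ProbeSpec, ...]:
    doc = yaml.safe_load(Path(path).read_text())
    probes = []
    for p in doc["probes"]:
        sites = tuple(
            (tuple(s.get("offset", (0.0, 0.0, 0.0))), frozenset(s["types"]))
            for s in p["sites"]
        )
        probes.append(ProbeSpec(name=p["name"], sites=sites))
    return tuple(probes)


def probes_to_yaml(probes, path: str | Path) -> None:
    doc = {
        "probes": [
            {
                "name": p.name,
                "sites": [
                    {"offset": list(off), "types": sorted(types)}
                    for off, types in p.sites
                ],
            }
            for p in probes
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Parameters and state
# ---------------------------------------------------------------------------


@dataclass
class GCMCParams:
    target_concentration: float = DEFAULT_CONCENTRATION  # mol/L per probe type
    mu_update_period: int = 3      # cycles between μ retunes
    steps_per_cycle: int = 50
    n_cycles: int = 2000
    temperature: float = DEFAULT_TEMPERATURE
    move_mix: dict = dc_field(
        default_factory=lambda: {
            "insert": 0.3, "delete": 0.3, "translate": 0.3, "rotate": 0.1
        }
    )
    max_translation: float = 1.0   # Å
    mu_step_bound: float = 0.5     # kcal/mol max change per retune
    mu_window: int = 150           # cycles of history averaged by the controller
    mu_gain: float = 0.02          # fraction of the log error applied per retune
    burn_in_fraction: float = 0.2  # cycles excluded from the snapshot stream
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_concentration <= 0:
            raise ValueError("target_concentration must be positive")
        total = sum(self.move_mix.get(k, 0.0) for k in MOVE_KINDS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("move_mix probabilities must sum to 1")
        if any(k not in MOVE_KINDS for k in self.move_mix):
            raise ValueError(f"move kinds must be among {MOVE_KINDS}")


@dataclass
class SoluteInstance:
    probe: ProbeSpec
    position: np.ndarray            # (3,) body origin
    rotation: np.ndarray            # (3, 3) body->lab
    energy: float                   # cached field energy

    def site_coords(self) -> np.ndarray:
        offsets = np.asarray([off for off, _ in self.probe.sites], dtype=float)
        return self.position + offsets @ self.rotation.T


@dataclass
class GCMCState:
    solutes: dict                   # probe name -> list[SoluteInstance]
    mu_excess: dict                 # probe name -> kcal/mol
    cycle: int = 0


# ---------------------------------------------------------------------------
# Acceptance and μ control
# ---------------------------------------------------------------------------


def _activity(probe_name: str, state: GCMCState, params: GCMCParams) -> float:
    """Activity z in particles/Å^3: c_target * exp(μ_excess / kT)."""
    c_a3 = params.target_concentration * PARTICLES_PER_A3_PER_MOLAR
    kt = K_B * params.temperature
    return c_a3 * math.exp(state.mu_excess[probe_name] / kt)


def metropolis_accept(
    delta_u: float,
    kind: str,
    state: GCMCState,
    params: GCMCParams,
    rng: np.random.Generator,
    probe_name: str,
    volume: float,
) -> bool:
    """Grand-canonical Metropolis acceptance.

    ``delta_u`` is the total energy change of the move (for a deletion
    that is minus the energy of the removed solute).  Translation and
    rotation use plain Metropolis; insertion/deletion carry the zV/(N+1)
    and N/(zV) prefactors of the grand-canonical ensemble.
    """
    if kind not in MOVE_KINDS:
        raise ValueError(f"unknown move kind {kind!r}")
    if math.isinf(delta_u):
        return delta_u < 0  # moves into an exclusion are always rejected
    kt = K_B * params.temperature
    if kind in ("translate", "rotate"):
        if delta_u <= 0:
            return True
        return rng.random() < math.exp(-delta_u / kt)
    n = len(state.solutes[probe_name])
    zv = _activity(probe_name, state, params) * volume
    if kind == "insert":
        ratio = zv / (n + 1) * math.exp(-delta_u / kt)
    else:  # delete
        if n == 0:
            return False
        ratio = n / zv * math.exp(-delta_u / kt)
    return ratio >= 1.0 or rng.random() < ratio


def update_mu(
    mu_excess: float,
    concentration_trace: np.ndarray,
    params: GCMCParams,
) -> float:
    """Log-proportional μ controller with a step bound.

    The raw control law is μ <- μ - k_B T ln(c_obs / c_target), whose
    fixed point is c_obs = c_target.  c_obs is the mean concentration over
    the last ``mu_window`` cycles (at least one update period); because μ
    is retuned every few cycles against this slowly refreshing window,
    only ``mu_gain`` of the log error is applied per retune — at small box
    sizes the instantaneous particle count is a handful at most, and a
    full-gain three-cycle controller random-walks instead of regulating.
    The change is clipped to ±mu_step_bound and a floor replaces
    c_obs = 0 (empty box) so the logarithm stays finite.
    """
    trace = np.asarray(concentration_trace, dtype=float)
    if trace.size < params.mu_update_period:
        raise ValueError("need at least mu_update_period cycles of history")
    window = max(params.mu_update_period, min(params.mu_window, trace.size))
    c_obs = float(trace[-window:].mean())
    if c_obs <= 0:
        c_obs = params.target_concentration / 20.0
        log.info("empty-box concentration window; flooring c_obs to %g", c_obs)
    kt = K_B * params.temperature
    delta = -params.mu_gain * kt * math.log(c_obs / params.target_concentration)
    delta = max(-params.mu_step_bound, min(params.mu_step_bound, delta))
    return mu_excess + delta


# ---------------------------------------------------------------------------
# Single-site fast path (numba)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _field_u(x, y, z, term_c, term_d, term_w2inv, excl_c, excl_r2):
    for e in range(excl_c.shape[0]):
        dx = x - excl_c[e, 0]
        dy = y - excl_c[e, 1]
        dz = z - excl_c[e, 2]
        if dx * dx + dy * dy + dz * dz < excl_r2[e]:
            return 1e300
    u = 0.0
    for t in range(term_c.shape[0]):
        dx = x - term_c[t, 0]
        dy = y - term_c[t, 1]
        dz = z - term_c[t, 2]
        u += term_d[t] * math.exp(-(dx * dx + dy * dy + dz * dz) * term_w2inv[t])
    return u


@njit(cache=False)
def _gcmc_point_probe_chain(
    seed, n_cycles, steps_per_cycle, burn_in,
    lo, hi,
    term_c, term_d, term_w2inv, excl_c, excl_r2,
    kt, c_target_a3, mu0,
    p_insert, p_delete, p_translate,
    max_trans,
    mu_period, mu_window, mu_gain, mu_bound, c_floor_a3,
    positions, n0,
    out_coords, counts_trace,
):
    """Grand-canonical chain for one point-probe type.

    ``positions`` is a pre-allocated (capacity, 3) workspace holding ``n0``
    initial particles; ``out_coords`` collects (frame, x, y, z) rows for
    post-burn-in cycles; ``counts_trace`` receives the per-cycle particle
    count.  Returns (n_final, mu_final, rows_written).
    """
    np.random.seed(seed)
    n = n0
    mu = mu0
    cap = positions.shape[0]
    out_n = 0
    volume = (hi[0] - lo[0]) * (hi[1] - lo[1]) * (hi[2] - lo[2])
    for cycle in range(n_cycles):
        z_act = c_target_a3 * math.exp(mu / kt) * volume
        for _ in range(steps_per_cycle):
            u_kind = np.random.random()
            if u_kind < p_insert:
                if n >= cap:
                    continue
                x = lo[0] + np.random.random() * (hi[0] - lo[0])
                y = lo[1] + np.random.random() * (hi[1] - lo[1])
                z = lo[2] + np.random.random() * (hi[2] - lo[2])
                du = _field_u(x, y, z, term_c, term_d, term_w2inv, excl_c, excl_r2)
                if du >= 1e299:
                    continue
                ratio = z_act / (n + 1) * math.exp(-du / kt)
                if ratio >= 1.0 or np.random.random() < ratio:
                    positions[n, 0] = x
                    positions[n, 1] = y
                    positions[n, 2] = z
                    n += 1
            elif u_kind < p_insert + p_delete:
                if n == 0:
                    continue
                i = int(np.random.random() * n)
                if i == n:
                    i = n - 1
                u_i = _field_u(
                    positions[i, 0], positions[i, 1], positions[i, 2],
                    term_c, term_d, term_w2inv, excl_c, excl_r2,
                )
                ratio = n / z_act * math.exp(u_i / kt)
                if ratio >= 1.0 or np.random.random() < ratio:
                    positions[i, 0] = positions[n - 1, 0]
                    positions[i, 1] = positions[n - 1, 1]
                    positions[i, 2] = positions[n - 1, 2]
                    n -= 1
            elif u_kind < p_insert + p_delete + p_translate:
                if n == 0:
                    continue
                i = int(np.random.random() * n)
                if i == n:
                    i = n - 1
                dx = np.random.normal()
                dy = np.random.normal()
                dz = np.random.normal()
                norm = math.sqrt(dx * dx + dy * dy + dz * dz)
                if norm == 0.0:
                    continue
                r = max_trans * np.random.random() ** (1.0 / 3.0)
                x = positions[i, 0] + dx / norm * r
                y = positions[i, 1] + dy / norm * r
                z = positions[i, 2] + dz / norm * r
                if (
                    x < lo[0] or x >= hi[0]
                    or y < lo[1] or y >= hi[1]
                    or z < lo[2] or z >= hi[2]
                ):
                    continue
                u_new = _field_u(x, y, z, term_c, term_d, term_w2inv,
                                 excl_c, excl_r2)
                u_old = _field_u(
                    positions[i, 0], positions[i, 1], positions[i, 2],
                    term_c, term_d, term_w2inv, excl_c, excl_r2,
                )
                du = u_new - u_old
                if du <= 0.0 or np.random.random() < math.exp(-du / kt):
                    positions[i, 0] = x
                    positions[i, 1] = y
                    positions[i, 2] = z
            # else: rotation — a no-op for a point probe

        counts_trace[cycle] = n

        if mu_period <= n_cycles and (cycle + 1) % mu_period == 0:
            w = mu_window
            if w > cycle + 1:
                w = cycle + 1
            if w < mu_period:
                w = mu_period
            mean_n = 0.0
            for c in range(cycle + 1 - w, cycle + 1):
                mean_n += counts_trace[c]
            mean_n /= w
            c_obs = mean_n / volume  # particles per A^3
            if c_obs <= 0.0:
                c_obs = c_floor_a3
            delta = -mu_gain * kt * math.log(c_obs / c_target_a3)
            if delta > mu_bound:
                delta = mu_bound
            elif delta < -mu_bound:
                delta = -mu_bound
            mu += delta

        if cycle >= burn_in:
            for i in range(n):
                if out_n < out_coords.shape[0]:
                    out_coords[out_n, 0] = cycle
                    out_coords[out_n, 1] = positions[i, 0]
                    out_coords[out_n, 2] = positions[i, 1]
                    out_coords[out_n, 3] = positions[i, 2]
                    out_n += 1
    return n, mu, out_n


def _run_gcmc_point_probes(field, probes, params, collect_snapshots):
    """Kernel-backed sampler for sets of single-site probes."""
    lo = np.asarray(field.box.origin, dtype=float)
    hi = np.asarray(field.box.upper, dtype=float)
    volume = field.volume
    kt = K_B * params.temperature
    c_target_a3 = params.target_concentration * PARTICLES_PER_A3_PER_MOLAR
    burn_in = int(params.burn_in_fraction * params.n_cycles)
    n_out_frames = params.n_cycles - burn_in if collect_snapshots else 0
    expected_n = max(1.0, c_target_a3 * volume)

    if field.exclusions:
        excl_c = np.asarray([e.center for e in field.exclusions], dtype=float)
        excl_r2 = np.asarray([e.radius**2 for e in field.exclusions])
    else:
        excl_c = np.zeros((0, 3))
        excl_r2 = np.zeros(0)

    mu_period = params.mu_update_period
    if params.move_mix.get("insert", 0.0) <= 0:
        mu_period = params.n_cycles + 1  # controller needs exchanges

    frame_atoms: dict[int, list] = {}
    trace = {}
    mu_final_by_name = {}
    seed_seq = np.random.SeedSequence(params.seed)
    type_seeds = seed_seq.generate_state(len(probes))
    for probe, type_seed in zip(probes, type_seeds):
        _, types = probe.sites[0]
        term_c, term_d, term_w2inv = field._terms_for(types)
        positions = np.zeros((int(10 * expected_n + 64), 3))
        out_cap = max(1, int(n_out_frames * (expected_n * 6 + 8)))
        out_coords = np.zeros((out_cap, 4))
        counts_trace = np.zeros(params.n_cycles)
        _, mu_final, out_n = _gcmc_point_probe_chain(
            int(type_seed % (2**31)), params.n_cycles, params.steps_per_cycle,
            burn_in if collect_snapshots else params.n_cycles,
            lo, hi,
            np.ascontiguousarray(term_c), np.ascontiguousarray(term_d),
            np.ascontiguousarray(term_w2inv),
            excl_c, excl_r2,
            kt, c_target_a3, 0.0,
            params.move_mix.get("insert", 0.0),
            params.move_mix.get("delete", 0.0),
            params.move_mix.get("translate", 0.0),
            params.max_translation,
            mu_period, params.mu_window, params.mu_gain,
            params.mu_step_bound, c_target_a3 / 20.0,
            positions, 0,
            out_coords, counts_trace,
        )
        mu_final_by_name[probe.name] = float(mu_final)
        trace[probe.name] = counts_trace / (volume * PARTICLES_PER_A3_PER_MOLAR)
        for row in out_coords[:out_n]:
            frame_atoms.setdefault(int(row[0]), []).append(
                ((float(row[1]), float(row[2]), float(row[3])), types)
            )
    snapshots = []
    if collect_snapshots:
        for cycle in range(burn_in, params.n_cycles):
            snapshots.append(
                SoluteSnapshot(
                    frame_index=cycle, atoms=frame_atoms.get(cycle, [])
                )
            )
    state = GCMCState(
        solutes={p.name: [] for p in probes},
        mu_excess=mu_final_by_name,
        cycle=params.n_cycles - 1,
    )
    return snapshots, trace, state


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (axis-angle via quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _instance_energy(
    field: FieldDefinition,
    probe: ProbeSpec,
    position: np.ndarray,
    rotation: np.ndarray,
) -> float:
    u = 0.0
    for off, types in probe.sites:
        pt = position + rotation @ np.asarray(off, dtype=float)
        u += field.energy(pt, types)
        if math.isinf(u):
            return math.inf
    return u


def run_gcmc(
    field: FieldDefinition,
    probes=DEFAULT_PROBE_SET,
    params: GCMCParams = GCMCParams(),
    initial_state: GCMCState | None = None,
    collect_snapshots: bool = True,
):
    """Run the sampler and return ``(snapshots, trace, state)``.

    ``snapshots`` holds one :class:`SoluteSnapshot` per post-burn-in cycle
    (all probe sites with their map types); ``trace`` is a dict of probe
    name -> per-cycle instantaneous concentration (mol/L); the stream is
    deterministic for a given (seed, params).

    Point probes (all sites at the body origin) are independent of one
    another in this ideal-dilute model, so sets of single-site probes are
    dispatched to a compiled per-type chain; multi-site probes and runs
    started from an explicit state use the general loop below.
    """
    if field.volume <= 0:
        raise ValueError("field box has zero volume")
    if initial_state is None and all(p.n_sites == 1 for p in probes):
        return _run_gcmc_point_probes(field, probes, params, collect_snapshots)
    rng = np.random.default_rng(params.seed)
    lo = np.asarray(field.box.origin, dtype=float)
    hi = np.asarray(field.box.upper, dtype=float)
    volume = field.volume
    probe_by_name = {p.name: p for p in probes}
    if initial_state is None:
        state = GCMCState(
            solutes={p.name: [] for p in probes},
            mu_excess={p.name: 0.0 for p in probes},
        )
    else:
        state = initial_state

    kinds = [k for k in MOVE_KINDS if params.move_mix.get(k, 0.0) > 0]
    kind_p = np.asarray([params.move_mix[k] for k in kinds], dtype=float)
    kind_p /= kind_p.sum()
    names = list(probe_by_name)

    burn_in = int(params.burn_in_fraction * params.n_cycles)
    snapshots: list[SoluteSnapshot] = []
    trace = {name: np.zeros(params.n_cycles) for name in names}
    conv = volume * PARTICLES_PER_A3_PER_MOLAR  # particles per mol/L

    for cycle in range(params.n_cycles):
        state.cycle = cycle
        for _ in range(params.steps_per_cycle):
            name = names[rng.integers(len(names))] if len(names) > 1 else names[0]
            probe = probe_by_name[name]
            pop = state.solutes[name]
            kind = kinds[int(rng.choice(len(kinds), p=kind_p))]

            if kind == "insert":
                pos = lo + rng.random(3) * (hi - lo)
                rot = _random_rotation(rng) if probe.n_sites > 1 else np.eye(3)
                du = _instance_energy(field, probe, pos, rot)
                if metropolis_accept(du, kind, state, params, rng, name, volume):
                    pop.append(SoluteInstance(probe, pos, rot, du))
            elif kind == "delete":
                if not pop:
                    continue
                i = int(rng.integers(len(pop)))
                du = -pop[i].energy
                if metropolis_accept(du, kind, state, params, rng, name, volume):
                    pop[i] = pop[-1]
                    pop.pop()
            elif kind == "translate":
                if not pop:
                    continue
                i = int(rng.integers(len(pop)))
                inst = pop[i]
                step = rng.normal(size=3)
                norm = np.linalg.norm(step)
                if norm == 0:
                    continue
                radius = params.max_translation * rng.random() ** (1.0 / 3.0)
                new_pos = inst.position + step / norm * radius
                if np.any(new_pos < lo) or np.any(new_pos >= hi):
                    continue  # non-periodic box: reject moves leaving it
                u_new = _instance_energy(field, probe, new_pos, inst.rotation)
                du = u_new - inst.energy
                if metropolis_accept(du, kind, state, params, rng, name, volume):
                    inst.position = new_pos
                    inst.energy = u_new
            else:  # rotate
                if not pop:
                    continue
                i = int(rng.integers(len(pop)))
                inst = pop[i]
                if probe.n_sites == 1:
                    continue  # no-op for point probes
                rot = _random_rotation(rng) @ inst.rotation
                u_new = _instance_energy(field, probe, inst.position, rot)
                du = u_new - inst.energy
                if metropolis_accept(du, kind, state, params, rng, name, volume):
                    inst.rotation = rot
                    inst.energy = u_new

        for name in names:
            trace[name][cycle] = len(state.solutes[name]) / conv

        if (
            params.move_mix.get("insert", 0.0) > 0
            and (cycle + 1) % params.mu_update_period == 0
        ):
            for name in names:
                state.mu_excess[name] = update_mu(
                    state.mu_excess[name], trace[name][: cycle + 1], params
                )

        if collect_snapshots and cycle >= burn_in:
            atoms = []
            for name in names:
                for inst in state.solutes[name]:
                    coords = inst.site_coords()
                    for s, (_, types) in enumerate(inst.probe.sites):
                        atoms.append((tuple(coords[s]), types))
            snapshots.append(SoluteSnapshot(frame_index=cycle, atoms=atoms))

    return snapshots, trace, state
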