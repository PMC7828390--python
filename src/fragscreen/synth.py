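"""Synthetic two-homolog systems with planted ground truth.

Generates every input the screening pipeline consumes: a pair of
pseudo-protein interaction fields that share most favorable regions but
differ at planted sub-sites (mimicking two ~60%-identical homologs, here
called protein A and protein B), point-residue clouds lining those sites,
a small fragment set with known specificity labels, and matching HSQC
peak lists in which binders perturb the residues lining their planted
site, non-binders add only measurement noise, and aggregators broaden a
large fraction of the spectrum of both targets.

The pseudo-proteins are point-residue clouds over Gaussian interaction
wells, not atomic structures — sufficient for contact-based pose
selection and site labelling, and honest about what the closure tests can
and cannot show about real proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gcmc import FieldDefinition, GaussianTerm
from .grid import GENERIC_MAP_TYPES, GridSpec
from .ligand import Atom, Ligand
from .nmr import (
    CALL_A_SPECIFIC,
    CALL_AGGREGATOR,
    CALL_B_SPECIFIC,
    CALL_DUAL,
    CALL_NON_BINDER,
    PeakAssignment,
    PeakList,
)

PROTEIN_A = "A"
PROTEIN_B = "B"

SITE_SHARED = "shared"
SITE_A_ONLY = "A_only"
SITE_B_ONLY = "B_only"

#: Default per-peak measurement noise of a re-recorded HSQC spectrum:
#: (1H ppm, 15N ppm).
DEFAULT_PEAK_NOISE = (0.003, 0.02)


@dataclass(frozen=True)
class Site:
    """A planted binding sub-site."""

    label: str
    center: tuple[float, float, float]
    depths: dict[str, float]       # generic map type -> well depth (kcal/mol, <= 0)
    kind: str                      # shared | A_only | B_only
    width: float = 1.8             # Gaussian sigma, Å
    lining: tuple = ()             # residue keys lining the site

    def __post_init__(self) -> None:
        if self.kind not in (SITE_SHARED, SITE_A_ONLY, SITE_B_ONLY):
            raise ValueError(f"bad site kind {self.kind!r}")
        for t, d in self.depths.items():
            if t not in GENERIC_MAP_TYPES:
                raise ValueError(f"unknown map type {t!r} in site {self.label}")
            if not (-4.0 <= d <= 0.0):
                raise ValueError(
                    f"site {self.label}: depth {d} outside [-4, 0] kcal/mol"
                )

    def present_in(self, protein: str) -> bool:
        if self.kind == SITE_SHARED:
            return True
        return (self.kind == SITE_A_ONLY) == (protein == PROTEIN_A)


@dataclass
class SyntheticSystem:
    """Paired homolog fields with planted sites and residue clouds."""

    field_A: FieldDefinition
    field_B: FieldDefinition
    sites: list[Site]
    residue_map: dict              # protein -> {(chain, resid) -> np.ndarray}
    seed: int

    def field_for(self, protein: str) -> FieldDefinition:
        return self.field_A if protein == PROTEIN_A else self.field_B

    @property
    def extent(self) -> tuple[tuple, tuple]:
        box = self.field_A.box
        return box.origin, box.upper

    def site(self, label: str) -> Site:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass
class PlantedFragment:
    ligand: Ligand
    true_label: str                # one of the five specificity calls
    target_site: str | None       # site label, or None for non-binder/aggregator


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

#: Default site layout: two shared pockets (one of them the
#: dimer-interface-like site), one A-exclusive pocket with strong
#: hydrogen-bonding character, one purely hydrophobic B-exclusive pocket.
DEFAULT_SITES = (
    Site(
        label="site1", center=(5.5, 8.5, 8.5), kind=SITE_SHARED,
        depths={"APOLAR": -2.2, "HBACC": -1.5},
    ),
    Site(
        label="site2", center=(12.5, 8.5, 8.5), kind=SITE_A_ONLY,
        depths={"APOLAR": -2.0, "HBDON": -2.5, "HBACC": -2.5},
    ),
    Site(
        label="site3", center=(19.5, 8.5, 8.5), kind=SITE_B_ONLY,
        depths={"APOLAR": -3.0},
    ),
    Site(
        label="interface", center=(26.5, 8.5, 8.5), kind=SITE_SHARED,
        depths={"APOLAR": -2.0, "HBDON": -1.5},
    ),
)

DEFAULT_BOX = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(30, 16, 16))

_RESIDUE_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_N_RESIDUES = 84
_LINING_PER_SITE = 6
_LINING_RADIUS = 3.0  # Å from the site center


def make_system(
    seed: int = 7,
    sites=DEFAULT_SITES,
    box: GridSpec = DEFAULT_BOX,
    n_residues: int = _N_RESIDUES,
) -> SyntheticSystem:
    """Build the paired homolog system; fully reproducible per seed.

    Raises when two sites sit closer than twice their combined width
    (overlapping wells would blur the planted ground truth).
    """
    rng = np.random.default_rng(seed)
    sites = list(sites)
    kinds = {s.kind for s in sites}
    if not {SITE_SHARED, SITE_A_ONLY, SITE_B_ONLY} <= kinds:
        raise ValueError("need at least one shared, one A-only and one B-only site")
    for i, a in enumerate(sites):
        for b in sites[i + 1:]:
            d = math.dist(a.center, b.center)
            if d < 2.0 * max(a.width, b.width):
                raise ValueError(
                    f"sites {a.label} and {b.label} overlap (separation {d:.2f} Å)"
                )

    # Residues: a fixed number of lining residues per site (on a sphere
    # around the center), the rest scattered away from all sites.  The two
    # homologs share the fold, so residue coordinates coincide.
    residues: dict = {}
    sited: list[Site] = []
    next_index = 1
    lo = np.asarray(box.origin) + 1.0
    hi = np.asarray(box.upper) - 1.0
    for s in sites:
        keys = []
        for _ in range(_LINING_PER_SITE):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = np.asarray(s.center) + v * _LINING_RADIUS
            pos = np.clip(pos, lo, hi)
            key = ("A", next_index)
            residues[key] = pos
            keys.append(key)
            next_index += 1
        sited.append(Site(
            label=s.label, center=s.center, depths=dict(s.depths),
            kind=s.kind, width=s.width, lining=tuple(keys),
        ))
    site_centers = np.asarray([s.center for s in sites])
    while next_index <= n_residues:
        pos = lo + rng.random(3) * (hi - lo)
        if np.min(np.linalg.norm(site_centers - pos, axis=1)) < 5.0:
            continue  # keep filler residues clear of the planted sites
        residues[("A", next_index)] = pos
        next_index += 1

    def build_field(protein: str) -> FieldDefinition:
        terms = []
        for s in sited:
            if not s.present_in(protein):
                continue
            for map_type, depth in s.depths.items():
                terms.append(GaussianTerm(
                    center=s.center, depth=depth, width=s.width,
                    map_type=map_type,
                ))
        return FieldDefinition(box=box, terms=terms)

    residue_map = {
        PROTEIN_A: dict(residues),
        PROTEIN_B: {k: v.copy() for k, v in residues.items()},
    }
    return SyntheticSystem(
        field_A=build_field(PROTEIN_A),
        field_B=build_field(PROTEIN_B),
        sites=sited,
        residue_map=residue_map,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


def _ring_coords(n: int, radius: float, z: float = 0.0) -> list[tuple]:
    return [
        (radius * math.cos(2 * math.pi * i / n),
         radius * math.sin(2 * math.pi * i / n), z)
        for i in range(n)
    ]


def make_fragments(seed: int = 7) -> list[PlantedFragment]:
    """The shipped planted fragment set: one per specificity label.

    Chemistry mirrors the contrast seen in real homolog screens: the
    B-specific fragment is purely hydrophobic with no hydrogen-bond
    donors, the A-specific fragment carries a donor and several
    acceptors, the dual binder mixes apolar and acceptor character.
    All fragments stay within fragment-library size bounds (<= 22 heavy
    atoms; these are far smaller).
    """
    frags: list[PlantedFragment] = []

    # A-specific: donor + 4 acceptors + 2 apolar carbons around a ring.
    ring = _ring_coords(6, 1.25)
    atoms = [
        Atom("N", ring[0], classes=frozenset({"HBACC"})),
        Atom("N", ring[1], classes=frozenset({"HBACC"})),
        Atom("O", ring[2], classes=frozenset({"HBACC"})),
        Atom("N", ring[3], classes=frozenset({"HBACC"})),
        Atom("C", ring[4], classes=frozenset({"APOLAR"})),
        Atom("C", ring[5], classes=frozenset({"APOLAR"})),
        Atom("H", (ring[0][0], ring[0][1], 1.0), classes=frozenset({"HBDON"})),
    ]
    bonds = [(i, (i + 1) % 6, 1) for i in range(6)] + [(0, 6, 1)]
    frags.append(PlantedFragment(
        ligand=Ligand(id="FRG-A1", atoms=atoms, bonds=bonds),
        true_label=CALL_A_SPECIFIC,
        target_site="site2",
    ))

    # B-specific: compact all-carbon cluster, zero donor classes.
    ring = _ring_coords(5, 1.2)
    atoms = [Atom("C", xyz, classes=frozenset({"APOLAR"})) for xyz in ring]
    bonds = [(i, (i + 1) % 5, 1) for i in range(5)]
    frags.append(PlantedFragment(
        ligand=Ligand(id="FRG-B1", atoms=atoms, bonds=bonds),
        true_label=CALL_B_SPECIFIC,
        target_site="site3",
    ))

    # Dual binder: apolar core with two acceptors, matches the shared site.
    atoms = [
        Atom("C", (0.0, 0.0, 0.0), classes=frozenset({"APOLAR"})),
        Atom("C", (1.4, 0.0, 0.0), classes=frozenset({"APOLAR"})),
        Atom("C", (-0.7, 1.2, 0.0), classes=frozenset({"APOLAR"})),
        Atom("O", (2.1, 1.1, 0.0), classes=frozenset({"HBACC"})),
        Atom("O", (-0.7, -1.3, 0.0), classes=frozenset({"HBACC"})),
    ]
    bonds = [(0, 1, 1), (0, 2, 1), (1, 3, 1), (0, 4, 1)]
    frags.append(PlantedFragment(
        ligand=Ligand(id="FRG-D1", atoms=atoms, bonds=bonds),
        true_label=CALL_DUAL,
        target_site="site1",
    ))

    # Non-binder: a charged amine; neither field plants a MAMN well, so
    # its classified atoms experience no planted site.
    atoms = [
        Atom("N", (0.0, 0.0, 0.0), formal_charge=1, classes=frozenset({"MAMN"})),
        Atom("C", (1.5, 0.0, 0.0), classes=frozenset()),
        Atom("H", (-0.5, 0.9, 0.0), classes=frozenset()),
    ]
    bonds = [(0, 1, 1), (0, 2, 1)]
    frags.append(PlantedFragment(
        ligand=Ligand(id="FRG-N1", atoms=atoms, bonds=bonds),
        true_label=CALL_NON_BINDER,
        target_site=None,
    ))

    # Aggregator: chemistry is irrelevant — it broadens spectra of both
    # targets and is discarded before any map-based analysis.
    atoms = [
        Atom("C", (0.0, 0.0, 0.0), classes=frozenset({"APOLAR"})),
        Atom("C", (1.4, 0.0, 0.0), classes=frozenset({"APOLAR"})),
        Atom("C", (2.1, 1.2, 0.0), classes=frozenset({"APOLAR"})),
    ]
    bonds = [(0, 1, 1), (1, 2, 1)]
    frags.append(PlantedFragment(
        ligand=Ligand(id="FRG-G1", atoms=atoms, bonds=bonds),
        true_label=CALL_AGGREGATOR,
        target_site=None,
    ))
    return frags


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


def _reference_peaklist(
    system: SyntheticSystem, protein: str, rng: np.random.Generator
) -> PeakList:
    assignments = []
    for (chain, idx) in sorted(system.residue_map[protein]):
        assignments.append(PeakAssignment(
            residue_index=idx,
            residue_name=_RESIDUE_ALPHABET[int(rng.integers(len(_RESIDUE_ALPHABET)))],
            chain_id=chain,
            delta_H=float(rng.uniform(7.4, 9.4)),
            delta_N=float(rng.uniform(106.0, 130.0)),
            intensity=1.0e6,
        ))
    return PeakList.from_assignments(assignments, label="reference")


def _binds(fragment: PlantedFragment, protein: str) -> bool:
    if fragment.true_label == CALL_DUAL:
        return True
    if fragment.true_label == CALL_A_SPECIFIC:
        return protein == PROTEIN_A
    if fragment.true_label == CALL_B_SPECIFIC:
        return protein == PROTEIN_B
    return False


def make_peaklists(
    system: SyntheticSystem,
    fragments: list[PlantedFragment],
    noise_ppm: tuple[float, float] = DEFAULT_PEAK_NOISE,
    seed: int = 7,
    aggregation_fraction: float = 0.35,
) -> dict:
    """Reference and per-fragment peak lists for both proteins.

    Returns ``{protein: {"reference": PeakList, fragment_id: PeakList}}``.
    Residues lining a binder's target site receive strong planted CSPs
    (combined-shift magnitude 0.03–0.06 ppm, inside the strong band so
    recovery is threshold-robust) and every second lining residue an
    additional intensity drop in (0.5, 0.95]; aggregators broaden
    ``aggregation_fraction`` of the peaks of both proteins; everything
    else gets only per-peak measurement noise.
    """
    if noise_ppm[0] < 0 or noise_ppm[1] < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    out: dict = {}
    for protein in (PROTEIN_A, PROTEIN_B):
        ref = _reference_peaklist(system, protein, rng)
        out[protein] = {"reference": ref}
        for frag in fragments:
            peaks = {}
            perturbation: dict = {}
            if _binds(frag, protein) and frag.target_site is not None:
                site = system.site(frag.target_site)
                for i, key in enumerate(site.lining):
                    csp = rng.uniform(0.03, 0.06)
                    phi = rng.uniform(0.0, 2.0 * math.pi)
                    d_h = math.sqrt(2.0) * csp * math.cos(phi)
                    d_n = math.sqrt(2.0) * csp * math.sin(phi) / 0.14
                    drop = rng.uniform(0.5, 0.95) if i % 2 == 1 else 0.0
                    perturbation[key] = (d_h, d_n, drop)
            elif frag.true_label == CALL_AGGREGATOR:
                keys = sorted(ref.peaks)
                n_broad = math.ceil(aggregation_fraction * len(keys))
                chosen = rng.choice(len(keys), size=n_broad, replace=False)
                for ci in chosen:
                    drop = rng.uniform(0.5, 1.0)
                    perturbation[keys[ci]] = (0.0, 0.0, drop)

            for key, pk in ref.peaks.items():
                d_h, d_n, drop = perturbation.get(key, (0.0, 0.0, 0.0))
                intensity = pk.intensity * (1.0 - drop)
                if noise_ppm[0] > 0:
                    d_h += rng.normal(0.0, noise_ppm[0])
                    d_n += rng.normal(0.0, noise_ppm[1])
                    intensity *= max(0.0, 1.0 + rng.normal(0.0, 0.05))
                peaks[key] = PeakAssignment(
                    residue_index=pk.residue_index,
                    residue_name=pk.residue_name,
                    chain_id=pk.chain_id,
                    delta_H=pk.delta_H + d_h,
                    delta_N=pk.delta_N + d_n,
                    intensity=intensity,
                )
            out[protein][frag.ligand.id] = PeakList(
                peaks=peaks, label=frag.ligand.id
            )
    return out
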