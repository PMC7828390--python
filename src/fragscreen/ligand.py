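"""Fragment ligands: atoms, bonds, rotatable torsions and map-type classes.

A ligand is a small rigid-bond molecule whose non-hydrogen (and polar
hydrogen) atoms carry generic map classes (APOLAR, HBDON, HBACC, MAMN,
ACEO); the classes select which grid free energy map each atom is scored
against during docking.  Ligands can be built from an explicit JSON
schema (used by synthetic fixtures) or loaded from SDF/MOL via RDKit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .grid import GENERIC_MAP_TYPES

log = logging.getLogger(__name__)

KNOWN_ELEMENTS = {
    "H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
}

#: Elements for which the default typing rules assign no map class.
_UNCLASSIFIED_ELEMENTS = {"S", "P", "F", "Cl", "Br", "I"}


@dataclass(frozen=True)
class Atom:
    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0
    classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(GENERIC_MAP_TYPES)
        if bad:
            raise ValueError(f"unknown atom classes {sorted(bad)}")


@dataclass
class Ligand:
    """A fragment with coordinates, bond graph and per-atom map classes."""

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # i, j, order
    rotatable_torsions: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise ValueError("ligand needs at least one atom")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bad bond ({i}, {j})")
        if n > 1 and self.bonds and not self._connected():
            raise ValueError("bond graph must be connected")
        adj = self.adjacency()
        for a, b, c, d in self.rotatable_torsions:
            if not (b in adj[a] and c in adj[b] and d in adj[c]):
                raise ValueError(f"torsion atoms {(a, b, c, d)} not bonded in order")

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in self.atoms]
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Ligand":
        coords = np.asarray(coords, dtype=float)
        atoms = [
            replace(a, coords=tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Ligand(
            id=self.id, atoms=atoms, bonds=list(self.bonds),
            rotatable_torsions=list(self.rotatable_torsions),
        )

    def torsion_moved_atoms(self, torsion: tuple[int, int, int, int]) -> set[int]:
        """Atoms on the d-side of the rotatable b-c bond (rotated as a group)."""
        _, b, c, _ = torsion
        adj = self.adjacency()
        seen = {b, c}
        stack = [c]
        moved = {c}
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    moved.add(nb)
                    stack.append(nb)
        moved.discard(c)
        return moved

    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(GENERIC_MAP_TYPES, 0)
        for a in self.atoms:
            for c in a.classes:
                counts[c] += 1
        return counts


@dataclass
class Pose:
    """One docked configuration of a ligand with its grid free energy score."""

    ligand_id: str
    coords: np.ndarray             # (n_atoms, 3) Å
    lgfe: float                    # kcal/mol; sum of per_atom_gfe
    per_atom_gfe: np.ndarray       # kcal/mol per atom
    torsion_angles: tuple = ()     # degrees, one per rotatable torsion
    box_id: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.per_atom_gfe = np.asarray(self.per_atom_gfe, dtype=float)
        if not np.isclose(self.lgfe, float(self.per_atom_gfe.sum()), atol=1e-6):
            raise ValueError("lgfe must equal the sum of per-atom GFEs")

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------


def assign_atom_classes(ligand: Ligand) -> Ligand:
    """Assign generic map classes from elements, bonds and formal charges.

    Rules (in order, per atom):
      * H bonded to N or O                      -> HBDON
      * N with formal charge +1                 -> MAMN
      * carboxylate O (O on a C bearing 2 O's,
        group net negative)                     -> ACEO
      * N or O without positive formal charge   -> HBACC
      * C with fewer than two N/O neighbours    -> APOLAR
    Other atoms (apolar H, S, halogens, multi-polar carbons) get no class
    and contribute zero to the ligand grid free energy.
    """
    adj = ligand.adjacency()
    elements = [a.element for a in ligand.atoms]
    unknown = sorted({e for e in elements if e not in KNOWN_ELEMENTS})
    if unknown:
        raise ValueError(f"unknown element(s): {unknown}")

    def is_carboxylate_oxygen(i: int) -> bool:
        if elements[i] != "O":
            return False
        for c in adj[i]:
            if elements[c] != "C":
                continue
            oxy = [n for n in adj[c] if elements[n] == "O"]
            if len(oxy) >= 2:
                charge = ligand.atoms[i].formal_charge + sum(
                    ligand.atoms[o].formal_charge for o in oxy if o != i
                )
                if charge < 0:
                    return True
        return False

    new_atoms = []
    for i, atom in enumerate(ligand.atoms):
        el = atom.element
        classes: set[str] = set()
        if el == "H":
            if any(elements[j] in ("N", "O") for j in adj[i]):
                classes.add("HBDON")
        elif el == "N":
            classes.add("MAMN" if atom.formal_charge > 0 else "HBACC")
        elif el == "O":
            if is_carboxylate_oxygen(i):
                classes.add("ACEO")
            elif atom.formal_charge <= 0:
                classes.add("HBACC")
        elif el == "C":
            n_polar = sum(1 for j in adj[i] if elements[j] in ("N", "O"))
            if n_polar < 2:
                classes.add("APOLAR")
        elif el in _UNCLASSIFIED_ELEMENTS:
            log.debug("no typing rule for %s atom %d in %s", el, i, ligand.id)
        log.debug("%s atom %d (%s) -> %s", ligand.id, i, el, sorted(classes))
        new_atoms.append(replace(atom, classes=frozenset(classes)))

    untyped_heavy = [
        i for i, a in enumerate(new_atoms)
        if a.element != "H" and not a.classes
    ]
    if untyped_heavy:
        log.info(
            "%s: heavy atom(s) %s carry no map class and score 0",
            ligand.id, untyped_heavy,
        )
    return Ligand(
        id=ligand.id, atoms=new_atoms, bonds=list(ligand.bonds),
        rotatable_torsions=list(ligand.rotatable_torsions),
    )


# ---------------------------------------------------------------------------
# JSON schema
# ---------------------------------------------------------------------------


def ligand_to_json(ligand: Ligand, path: str | Path | None = None) -> str:
    doc = {
        "id": ligand.id,
        "atoms": [
            {
                "element": a.element,
                "coords": list(a.coords),
                "formal_charge": a.formal_charge,
                "classes": sorted(a.classes),
            }
            for a in ligand.atoms
        ],
        "bonds": [list(b) for b in ligand.bonds],
        "rotatable_torsions": [list(t) for t in ligand.rotatable_torsions],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def ligand_from_json(source: str | Path) -> Ligand:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.endswith(".json")):
        doc = json.loads(Path(source).read_text())
    else:
        doc = json.loads(source)
    atoms = [
        Atom(
            element=a["element"],
            coords=tuple(a["coords"]),
            formal_charge=int(a.get("formal_charge", 0)),
            classes=frozenset(a.get("classes", [])),
        )
        for a in doc["atoms"]
    ]
    return Ligand(
        id=doc["id"],
        atoms=atoms,
        bonds=[tuple(b) for b in doc.get("bonds", [])],
        rotatable_torsions=[tuple(t) for t in doc.get("rotatable_torsions", [])],
    )


# ---------------------------------------------------------------------------
# RDKit bridge (optional)
# ---------------------------------------------------------------------------


def ligand_from_rdkit(mol, ligand_id: str | None = None) -> Ligand:
    """Convert an RDKit Mol (with a 3D conformer) to a typed Ligand."""
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer; 3D coordinates required")
    conf = mol.GetConformer()
    atoms = []
    for at in mol.GetAtoms():
        p = conf.GetAtomPosition(at.GetIdx())
        atoms.append(
            Atom(
                element=at.GetSymbol(),
                coords=(p.x, p.y, p.z),
                formal_charge=at.GetFormalCharge(),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    rot_smarts = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")
    torsions = []
    for b, c in mol.GetSubstructMatches(rot_smarts):
        nb = [a.GetIdx() for a in mol.GetAtomWithIdx(b).GetNeighbors() if a.GetIdx() != c]
        nc = [a.GetIdx() for a in mol.GetAtomWithIdx(c).GetNeighbors() if a.GetIdx() != b]
        if nb and nc:
            torsions.append((nb[0], b, c, nc[0]))
    lig = Ligand(
        id=ligand_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "ligand"),
        atoms=atoms,
        bonds=bonds,
        rotatable_torsions=torsions,
    )
    return assign_atom_classes(lig)


def read_sdf(path: str | Path) -> list[Ligand]:
    """Read all molecules of an SDF file as typed Ligands (needs RDKit)."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    ligands = []
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("%s: molecule %d unparsable, skipped", path, i)
            continue
        ligands.append(ligand_from_rdkit(mol))
    return ligands
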