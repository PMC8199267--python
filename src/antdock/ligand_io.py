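"""Molecule container plus MOL2/PDBQT reading, writing and interconversion.

The shared currency of the whole toolkit is :class:`Molecule`: an ordered list
of atoms (element, Cartesian position, partial charge, Tripos-style atom type)
and a list of bonds (order, ring flag, rotatable flag).  MOL2 carries the full
picture in one text file; PDBQT carries positions, charges and AutoDock atom
types but no bond table, so a PDBQT ligand is completed by distance-based bond
perception followed by rule-based Tripos typing before it can be docked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ParseError, StructureError, TypingError

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "read_mol2",
    "write_mol2",
    "read_pdbqt",
    "write_pdbqt",
    "perceive_bonds",
    "assign_tripos_types",
    "convert_pdbqt_to_mol2",
    "detect_rotatable_bonds",
    "COVALENT_RADII",
    "AUTODOCK_TYPE_TO_ELEMENT",
]

# Single-bond covalent radii (Å), Cordero et al. consensus values.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "Br": 1.20, "I": 1.39,
}

# AutoDock atom type -> chemical element.  "A" is aromatic carbon; the D/S
# suffixed types mark H-bond donor/acceptor behaviour, not the element.
AUTODOCK_TYPE_TO_ELEMENT: dict[str, str] = {
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "H": "H", "HD": "H", "HS": "H",
    "F": "F", "CL": "Cl", "Cl": "Cl", "BR": "Br", "Br": "Br", "I": "I",
    "S": "S", "SA": "S", "P": "P",
    "MG": "Mg", "Mg": "Mg", "MN": "Mn", "Mn": "Mn", "ZN": "Zn", "Zn": "Zn",
    "CA": "Ca", "FE": "Fe", "Fe": "Fe",
}

#: Bond orders carried by MOL2; integers plus the aromatic/amide labels.
_MOL2_BOND_TYPES = {"1": 1, "2": 2, "3": 3, "ar": "ar", "am": "am",
                    "du": 1, "un": 1, "nc": 0}


@dataclass
class Atom:
    """One atom: 1-based index, element symbol, position (Å), partial charge
    (e) and an optional Tripos-style atom type such as ``C.3`` or ``N.am``."""

    index: int
    element: str
    position: np.ndarray
    partial_charge: float = 0.0
    type_label: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.index}: non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Bond:
    """A bond between atoms ``a`` and ``b`` (1-based indices).

    ``order`` is 1, 2, 3, ``"ar"`` (aromatic) or ``"am"`` (amide).
    """

    a: int
    b: int
    order: int | str = 1
    in_ring: bool = False
    rotatable: bool = False

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise StructureError(f"bond connects atom {self.a} to itself")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise StructureError(f"{self.name}: duplicate atom indices")
        index_set = set(indices)
        seen_pairs: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if bond.a not in index_set or bond.b not in index_set:
                raise StructureError(
                    f"{self.name}: bond {bond.a}-{bond.b} references a missing atom")
            if bond.pair in seen_pairs:
                raise StructureError(f"{self.name}: duplicate bond {bond.pair}")
            seen_pairs.add(bond.pair)

    # -- convenience views -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in atom order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of the molecule with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i]) for i, a in enumerate(self.atoms)]
        return Molecule(self.name, atoms, [replace(b) for b in self.bonds],
                        dict(self.metadata))

    def atom_by_index(self, index: int) -> Atom:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(index)

    def neighbor_map(self) -> dict[int, list[int]]:
        """Adjacency as {atom index: sorted neighbor indices}."""
        nbrs: dict[int, list[int]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            nbrs[b.a].append(b.b)
            nbrs[b.b].append(b.a)
        return {k: sorted(v) for k, v in nbrs.items()}

    def heavy_atom_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.is_heavy]

    def total_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def read_mol2(text: str) -> Molecule:
    """Parse a Tripos MOL2 record into a :class:`Molecule`.

    Requires ``@<TRIPOS>MOLECULE`` and ``@<TRIPOS>ATOM`` sections; the BOND
    section is optional.  Declared atom/bond counts must match the records
    actually present.
    """
    lines = text.splitlines()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            tag = line[len("@<TRIPOS>"):].strip()
            if not tag:
                raise ParseError(f"line {lineno}: malformed section header {line!r}")
            current = tag.upper()
            sections.setdefault(current, [])
            continue
        if line.startswith("#") or current is None:
            continue
        if line.strip():
            sections[current].append((lineno, line))

    if "MOLECULE" not in sections:
        raise ParseError("missing @<TRIPOS>MOLECULE section")
    if "ATOM" not in sections:
        raise ParseError("missing @<TRIPOS>ATOM section")

    mol_lines = sections["MOLECULE"]
    if len(mol_lines) < 2:
        raise ParseError("MOLECULE section needs a name line and a counts line")
    name = mol_lines[0][1].strip()
    counts_lineno, counts_line = mol_lines[1]
    counts = counts_line.split()
    try:
        declared_atoms = int(counts[0])
        declared_bonds = int(counts[1]) if len(counts) > 1 else 0
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {counts_lineno}: bad counts line {counts_line!r}") from exc

    atoms: list[Atom] = []
    for lineno, line in sections["ATOM"]:
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"line {lineno}: ATOM record needs >= 6 fields")
        try:
            idx = int(fields[0])
            x, y, z = (float(fields[2]), float(fields[3]), float(fields[4]))
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unparseable ATOM record") from exc
        type_label = fields[5]
        charge = float(fields[8]) if len(fields) > 8 else 0.0
        element = _element_from_tripos(type_label)
        atoms.append(Atom(index=idx, element=element, position=(x, y, z),
                          partial_charge=charge, type_label=type_label,
                          name=fields[1]))

    bonds: list[Bond] = []
    for lineno, line in sections.get("BOND", []):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: BOND record needs 4 fields")
        try:
            a, b = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unparseable BOND record") from exc
        order = _MOL2_BOND_TYPES.get(fields[3])
        if order is None:
            raise ParseError(f"line {lineno}: unknown bond type {fields[3]!r}")
        bonds.append(Bond(a=a, b=b, order=order))

    if len(atoms) != declared_atoms:
        raise StructureError(
            f"{name}: MOLECULE record declares {declared_atoms} atoms "
            f"but {len(atoms)} ATOM records found")
    if len(bonds) != declared_bonds:
        raise StructureError(
            f"{name}: MOLECULE record declares {declared_bonds} bonds "
            f"but {len(bonds)} BOND records found")

    mol = Molecule(name=name or "UNNAMED", atoms=atoms, bonds=bonds)
    _flag_ring_bonds(mol)
    return mol


def _element_from_tripos(type_label: str) -> str:
    base = type_label.split(".")[0]
    # Normalise two-letter symbols written in upper case (CL, BR ...).
    if len(base) == 2 and base.isupper():
        base = base[0] + base[1].lower()
    return base


def write_mol2(m: Molecule) -> str:
    """Serialise a molecule as a Tripos MOL2 record (SMALL / USER_CHARGES).

    Coordinates and charges are written with 4 decimal places, which is the
    precision the round-trip guarantees.
    """
    for atom in m.atoms:
        if not atom.type_label:
            raise TypingError(
                f"atom {atom.index} ({atom.element}) has no Tripos atom type; "
                "run assign_tripos_types first")
    out = ["@<TRIPOS>MOLECULE", m.name or "UNNAMED",
           f"{m.n_atoms} {m.n_bonds} 1 0 0", "SMALL", "USER_CHARGES", "",
           "@<TRIPOS>ATOM"]
    for atom in m.atoms:
        name = atom.name or f"{atom.element}{atom.index}"
        x, y, z = atom.position
        out.append(
            f"{atom.index:>7d} {name:<8s} {x:>9.4f} {y:>9.4f} {z:>9.4f} "
            f"{atom.type_label:<7s} 1 LIG {atom.partial_charge:>9.4f}")
    out.append("@<TRIPOS>BOND")
    for i, bond in enumerate(m.bonds, start=1):
        order = bond.order if isinstance(bond.order, str) else str(bond.order)
        out.append(f"{i:>6d} {bond.a:>5d} {bond.b:>5d} {order:>4s}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDBQT
# ---------------------------------------------------------------------------

def read_pdbqt(text: str) -> Molecule:
    """Parse PDBQT ATOM/HETATM records into a bond-less :class:`Molecule`.

    PDBQT carries no bond table; ``perceive_bonds`` reconstructs connectivity.
    ROOT/BRANCH/TORSDOF records are tolerated and summarised in
    ``metadata`` (keys ``torsdof`` and ``branch_count``).
    """
    atoms: list[Atom] = []
    metadata: dict = {}
    branch_count = 0
    name = "UNNAMED"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        rec = raw[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                x = float(raw[30:38])
                y = float(raw[38:46])
                z = float(raw[46:54])
                charge = float(raw[70:76])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: unparseable PDBQT atom record") from exc
            ad_type = raw[77:79].strip() or raw[76:].strip()
            element = AUTODOCK_TYPE_TO_ELEMENT.get(ad_type)
            if element is None:
                raise TypingError(
                    f"line {lineno}: unrecognized AutoDock atom type {ad_type!r}")
            atoms.append(Atom(index=len(atoms) + 1, element=element,
                              position=(x, y, z), partial_charge=charge,
                              name=raw[12:16].strip() or None))
        elif raw.startswith("TORSDOF"):
            metadata["torsdof"] = int(raw.split()[1])
        elif raw.startswith("BRANCH"):
            branch_count += 1
        elif rec == "REMARK" and "Name" in raw:
            name = raw.split("=")[-1].strip() or name
    if branch_count:
        metadata["branch_count"] = branch_count
    return Molecule(name=name, atoms=atoms, bonds=[], metadata=metadata)


def _autodock_type_for(atom: Atom, neighbors: Iterable[Atom]) -> str:
    """Element -> AutoDock type used when emitting PDBQT fixtures."""
    el = atom.element
    if el == "H":
        if any(n.element in ("N", "O", "S") for n in neighbors):
            return "HD"
        return "H"
    if el == "C":
        if atom.type_label == "C.ar":
            return "A"
        return "C"
    if el == "N":
        # nitrogens without attached hydrogens are treated as acceptors
        if not any(n.element == "H" for n in neighbors):
            return "NA"
        return "N"
    if el == "O":
        return "OA"
    if el == "S":
        return "SA"
    if el in ("Cl", "Br"):
        return el.upper()
    return el


def write_pdbqt(m: Molecule) -> str:
    """Minimal fixed-column PDBQT writer (rigid record set, no BRANCH tree).

    Used to emit synthetic ligand libraries; real receptor preparation is out
    of scope.
    """
    nbrs = m.neighbor_map()
    by_index = {a.index: a for a in m.atoms}
    lines = [f"REMARK  Name = {m.name}", "ROOT"]
    for i, atom in enumerate(m.atoms, start=1):
        neighbor_atoms = [by_index[j] for j in nbrs.get(atom.index, [])]
        ad_type = _autodock_type_for(atom, neighbor_atoms)
        name = (atom.name or f"{atom.element}{i}")[:4]
        x, y, z = atom.position
        lines.append(
            f"ATOM  {i:>5d} {name:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00    "
            f"{atom.partial_charge:6.3f} {ad_type:<2s}")
    lines.append("ENDROOT")
    lines.append(f"TORSDOF {len(detect_rotatable_bonds(m)) if m.bonds else 0}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bond perception, typing, rotatable bonds
# ---------------------------------------------------------------------------

def perceive_bonds(m: Molecule, scale: float = 1.2) -> Molecule:
    """Distance-based bond perception.

    Atoms i, j are bonded iff ``d(i,j) <= scale * (r_cov(i) + r_cov(j))``.
    H–H bonds are never created.  Very short C–O contacts (< 1.28 Å) are
    upgraded to double bonds so carbonyls survive the PDBQT round trip.
    """
    for atom in m.atoms:
        if atom.element not in COVALENT_RADII:
            raise TypingError(f"no covalent radius for element {atom.element!r}")
    coords = m.coords()
    radii = np.array([COVALENT_RADII[a.element] for a in m.atoms])
    n = m.n_atoms
    bonds: list[Bond] = []
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        cutoff = scale * (radii[:, None] + radii[None, :])
        for i in range(n):
            for j in range(i + 1, n):
                ai, aj = m.atoms[i], m.atoms[j]
                if ai.element == "H" and aj.element == "H":
                    continue
                if dist[i, j] <= cutoff[i, j]:
                    order: int | str = 1
                    pair_els = {ai.element, aj.element}
                    if pair_els == {"C", "O"} and dist[i, j] < 1.28:
                        order = 2
                    bonds.append(Bond(a=ai.index, b=aj.index, order=order))
    out = Molecule(m.name, [replace(a) for a in m.atoms], bonds, dict(m.metadata))
    _flag_ring_bonds(out)
    return out


def _flag_ring_bonds(m: Molecule) -> None:
    """Set ``in_ring`` on every bond: a bond is cyclic iff its endpoints stay
    connected when the bond is removed."""
    adjacency = m.neighbor_map()
    for bond in m.bonds:
        bond.in_ring = _connected_without(adjacency, bond.a, bond.b)


def _connected_without(adj: dict[int, list[int]], a: int, b: int) -> bool:
    seen = {a}
    stack = [a]
    while stack:
        node = stack.pop()
        for nbr in adj[node]:
            if node == a and nbr == b:
                continue  # skip the bond itself (single edge assumed)
            if nbr == b:
                return True
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return False


_MAX_VALENCE = {"H": 1, "C": 4, "N": 4, "O": 3, "S": 6, "P": 5,
                "F": 1, "Cl": 1, "Br": 1, "I": 1, "B": 4, "Si": 4}


def assign_tripos_types(m: Molecule) -> Molecule:
    """Rule-based Tripos atom typing from element + connectivity.

    Deterministic for a given molecule.  Covers the organic subset the
    toolkit generates and docks (C/N/O/S/P/H/halogens); anything else falls
    back to the bare element symbol.
    """
    out = Molecule(m.name, [replace(a) for a in m.atoms],
                   [replace(b) for b in m.bonds], dict(m.metadata))
    by_index = {a.index: a for a in out.atoms}
    bonds_of: dict[int, list[Bond]] = {a.index: [] for a in out.atoms}
    for bond in out.bonds:
        bonds_of[bond.a].append(bond)
        bonds_of[bond.b].append(bond)

    for atom in out.atoms:
        my_bonds = bonds_of[atom.index]
        degree = len(my_bonds)
        maxval = _MAX_VALENCE.get(atom.element)
        if maxval is not None and degree > maxval:
            raise TypingError(
                f"atom {atom.index} ({atom.element}) has {degree} bonds; "
                f"valence limit is {maxval}")
        orders = [b.order for b in my_bonds]
        aromatic = "ar" in orders
        amide = "am" in orders
        n_double = sum(1 for o in orders if o == 2)
        n_triple = sum(1 for o in orders if o == 3)
        el = atom.element
        if el == "H":
            label = "H"
        elif el == "C":
            if aromatic:
                label = "C.ar"
            elif n_triple or n_double >= 2:
                label = "C.1"
            elif n_double or amide:
                label = "C.2"
            else:
                label = "C.3"
        elif el == "N":
            if aromatic:
                label = "N.ar"
            elif amide or _is_amide_nitrogen(atom, my_bonds, bonds_of, by_index):
                label = "N.am"
            elif n_triple:
                label = "N.1"
            elif n_double:
                label = "N.2"
            elif degree == 4:
                label = "N.4"
            else:
                label = "N.3"
        elif el == "O":
            if n_double or aromatic:
                label = "O.2"
            else:
                label = "O.3"
        elif el == "S":
            o2_neighbors = sum(
                1 for b in my_bonds if b.order == 2
                and by_index[b.b if b.a == atom.index else b.a].element == "O")
            if o2_neighbors >= 2:
                label = "S.o2"
            elif n_double:
                label = "S.2"
            else:
                label = "S.3"
        elif el == "P":
            label = "P.3"
        else:
            label = el
        atom.type_label = label
    return out


def _is_amide_nitrogen(atom: Atom, my_bonds: list[Bond],
                       bonds_of: dict[int, list[Bond]],
                       by_index: dict[int, Atom]) -> bool:
    """N single-bonded to a carbon that carries a C=O double bond."""
    for bond in my_bonds:
        other = by_index[bond.b if bond.a == atom.index else bond.a]
        if other.element != "C" or bond.order not in (1, "am"):
            continue
        for cb in bonds_of[other.index]:
            third = by_index[cb.b if cb.a == other.index else cb.a]
            if cb.order == 2 and third.element == "O":
                return True
    return False


def detect_rotatable_bonds(m: Molecule, exclude_amide: bool = True) -> list[int]:
    """Indices (positions in ``m.bonds``, ascending) of rotatable bonds.

    A bond rotates iff it is a single acyclic bond between heavy atoms and
    both endpoints have at least one further heavy-atom neighbor (terminal
    bonds such as methyl C–H stubs carry no conformational freedom).  Amide
    C–N bonds are excluded by default for planarity.
    """
    by_index = {a.index: a for a in m.atoms}
    heavy_neighbors: dict[int, set[int]] = {a.index: set() for a in m.atoms}
    for bond in m.bonds:
        if by_index[bond.a].is_heavy and by_index[bond.b].is_heavy:
            heavy_neighbors[bond.a].add(bond.b)
            heavy_neighbors[bond.b].add(bond.a)
    result = []
    for pos, bond in enumerate(m.bonds):
        if bond.in_ring:
            continue
        if bond.order == "am":
            if exclude_amide:
                continue
        elif bond.order != 1:
            continue
        aa, ab = by_index[bond.a], by_index[bond.b]
        if not (aa.is_heavy and ab.is_heavy):
            continue
        if not (heavy_neighbors[bond.a] - {bond.b}):
            continue
        if not (heavy_neighbors[bond.b] - {bond.a}):
            continue
        result.append(pos)
    return result


def convert_pdbqt_to_mol2(text: str) -> str:
    """PDBQT ligand -> MOL2 text: parse, perceive bonds, type, serialise.

    Heavy-atom count, element multiset and per-atom charges are preserved.
    Component failures are re-raised with the pipeline stage named.
    """
    stages = (("read_pdbqt", read_pdbqt),
              ("perceive_bonds", perceive_bonds),
              ("assign_tripos_types", assign_tripos_types),
              ("write_mol2", write_mol2))
    value = text
    for stage_name, stage in stages:
        try:
            value = stage(value)
        except Exception as exc:
            raise type(exc)(f"[{stage_name}] {exc}") from exc
    return value
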