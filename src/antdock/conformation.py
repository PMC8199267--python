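"""Pose degrees of freedom, interval discretization and pose application.

A docking pose of a flexible ligand is the vector
``x = (tx, ty, tz, alpha, beta, gamma, phi_1 ... phi_k)``: three translations
of the ligand centroid relative to the docking-sphere center (Å), three Z–Y–Z
Euler angles (degrees) and one torsion angle per rotatable bond (degrees).
Each degree of freedom lives on a bounded interval that is partitioned into
finitely many sub-intervals; the characteristic (indicator) function of the
partition maps a continuous value to its interval index, which is the discrete
alphabet the ant-colony search operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, DomainError, StructureError
from .ligand_io import Molecule, detect_rotatable_bonds

__all__ = [
    "DockingSphere",
    "Partition",
    "DofSpec",
    "build_dof_spec",
    "assign_interval",
    "characteristic_indicator",
    "apply_pose",
]


@dataclass(frozen=True)
class DockingSphere:
    """Spherical search region: ligand centroid positions are confined to an
    axis-aligned box inscribed around this sphere."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("docking sphere radius must be positive")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


class Partition:
    """Strictly increasing boundaries ``a = z_0 < z_1 < ... < z_n = b``
    defining ``n`` closed sub-intervals ``[z_{l-1}, z_l]`` (1-based ``l``)."""

    def __init__(self, boundaries) -> None:
        boundaries = np.asarray(boundaries, dtype=float)
        if boundaries.ndim != 1 or boundaries.size < 2:
            raise ConfigurationError("a partition needs at least two boundaries")
        if not np.all(np.diff(boundaries) > 0):
            raise ConfigurationError("partition boundaries must strictly increase")
        self.boundaries = boundaries

    @classmethod
    def regular(cls, a: float, b: float, n_intervals: int) -> "Partition":
        return cls(np.linspace(a, b, n_intervals + 1))

    @property
    def a(self) -> float:
        return float(self.boundaries[0])

    @property
    def b(self) -> float:
        return float(self.boundaries[-1])

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    def lower(self, ell: int) -> float:
        return float(self.boundaries[ell - 1])

    def upper(self, ell: int) -> float:
        """The representative value z_l the indicator function maps into."""
        return float(self.boundaries[ell])

    def midpoint(self, ell: int) -> float:
        return 0.5 * (self.lower(ell) + self.upper(ell))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Partition([{self.a}, {self.b}], n={self.n_intervals})"


def assign_interval(x_i: float, p: Partition) -> int:
    """Interval index ``l`` (1-based) with ``x_i in [z_{l-1}, z_l]``.

    Interior boundary points belong to the lower-indexed interval; the lower
    bound ``a`` belongs to interval 1.  Values outside ``[a, b]`` raise
    :class:`DomainError`.
    """
    if not (p.a <= x_i <= p.b):
        raise DomainError(f"value {x_i} outside partition bounds [{p.a}, {p.b}]")
    ell = int(np.searchsorted(p.boundaries, x_i, side="left"))
    return max(ell, 1)


def characteristic_indicator(x_i: float, ell: int, p: Partition) -> int:
    """1 if ``x_i`` is assigned to interval ``ell``, else 0 (χ partition
    indicator with the lower-interval boundary convention)."""
    if not 1 <= ell <= p.n_intervals:
        raise DomainError(f"interval index {ell} outside 1..{p.n_intervals}")
    try:
        return int(assign_interval(x_i, p) == ell)
    except DomainError:
        return 0


@dataclass
class DofSpec:
    """Per-degree-of-freedom bounds, rotational flags and partitions.

    Layout: dofs 0–2 are translations (Å), 3–5 are Euler orientation angles,
    the remainder are torsions of the ligand's rotatable bonds in detection
    order.  Rotational dofs have bounds [0, 360] degrees.
    """

    bounds: list[tuple[float, float]]
    rotational: list[bool]
    partitions: list[Partition]
    rotatable_bonds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.bounds) == len(self.rotational) == len(self.partitions)):
            raise ConfigurationError("DofSpec component lengths disagree")
        for (a, b), rot in zip(self.bounds, self.rotational):
            if rot and (a, b) != (0.0, 360.0):
                raise ConfigurationError("rotational dofs must span [0, 360]")

    @property
    def n(self) -> int:
        return len(self.bounds)

    def wrap_clip(self, x: np.ndarray) -> np.ndarray:
        """Wrap rotational components modulo 360, clip the rest into bounds."""
        x = np.array(x, dtype=float)
        if x.shape != (self.n,):
            raise DomainError(f"pose vector length {x.shape} != dof count {self.n}")
        for i, rot in enumerate(self.rotational):
            if rot:
                x[i] = x[i] % 360.0
            else:
                a, b = self.bounds[i]
                x[i] = min(max(x[i], a), b)
        return x

    def midpoint_vector(self, cell: tuple[int, ...]) -> np.ndarray:
        """Continuous pose at the midpoints of the given interval indices."""
        if len(cell) != self.n:
            raise DomainError("cell tuple length mismatch")
        return np.array([p.midpoint(ell) for p, ell in zip(self.partitions, cell)])

    def cell_of(self, x: np.ndarray) -> tuple[int, ...]:
        return tuple(assign_interval(v, p) for v, p in zip(x, self.partitions))


def build_dof_spec(ligand: Molecule, sphere: DockingSphere,
                   angular_step: float = 1.0,
                   linear_step: float = 0.5) -> DofSpec:
    """Degree-of-freedom spec for docking ``ligand`` inside ``sphere``.

    Translations span the sphere's axis-aligned bounding box, ``[-r, r]`` per
    axis relative to the center, partitioned at ``linear_step`` Å; every
    angular dof spans [0, 360] partitioned at ``angular_step`` degrees, which
    must divide 360.
    """
    n_ang = 360.0 / angular_step
    if abs(n_ang - round(n_ang)) > 1e-9:
        raise ConfigurationError(
            f"angular_step {angular_step} does not divide 360")
    n_ang = int(round(n_ang))
    r = sphere.radius
    n_lin = max(1, int(math.ceil(2 * r / linear_step - 1e-9)))

    rot_bonds = detect_rotatable_bonds(ligand)
    bounds: list[tuple[float, float]] = []
    rotational: list[bool] = []
    partitions: list[Partition] = []
    for _ in range(3):
        bounds.append((-r, r))
        rotational.append(False)
        partitions.append(Partition.regular(-r, r, n_lin))
    for _ in range(3 + len(rot_bonds)):
        bounds.append((0.0, 360.0))
        rotational.append(True)
        partitions.append(Partition.regular(0.0, 360.0, n_ang))
    return DofSpec(bounds=bounds, rotational=rotational,
                   partitions=partitions, rotatable_bonds=rot_bonds)


# ---------------------------------------------------------------------------
# Pose application
# ---------------------------------------------------------------------------

def _torsion_branches(ligand: Molecule, rotatable_bonds: list[int]
                      ) -> list[tuple[int, int, np.ndarray]]:
    """For each rotatable bond: (fixed-atom row, moving-atom row, row mask of
    the moving branch).  The branch with fewer heavy atoms moves; ties move
    the branch containing the higher-indexed atom."""
    row_of = {a.index: i for i, a in enumerate(ligand.atoms)}
    adj = ligand.neighbor_map()
    heavy = {a.index for a in ligand.atoms if a.is_heavy}
    out = []
    for pos in rotatable_bonds:
        bond = ligand.bonds[pos]
        side_a = _component(adj, start=bond.a, blocked_edge=(bond.a, bond.b))
        side_b = _component(adj, start=bond.b, blocked_edge=(bond.b, bond.a))
        heavy_a = len(side_a & heavy)
        heavy_b = len(side_b & heavy)
        if heavy_a < heavy_b:
            move, fixed_atom, moving_atom = side_a, bond.b, bond.a
        elif heavy_b < heavy_a:
            move, fixed_atom, moving_atom = side_b, bond.a, bond.b
        elif max(side_a) > max(side_b):
            move, fixed_atom, moving_atom = side_a, bond.b, bond.a
        else:
            move, fixed_atom, moving_atom = side_b, bond.a, bond.b
        mask = np.zeros(ligand.n_atoms, dtype=bool)
        for idx in move:
            mask[row_of[idx]] = True
        mask[row_of[moving_atom]] = False  # axis atom stays put
        out.append((row_of[fixed_atom], row_of[moving_atom], mask))
    return out


def _component(adj: dict[int, list[int]], start: int,
               blocked_edge: tuple[int, int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr in adj[node]:
            if (node, nbr) == blocked_edge or (nbr, node) == blocked_edge:
                continue
            if nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return seen


def apply_pose(ligand: Molecule, x, sphere: DockingSphere,
               spec: DofSpec | None = None) -> np.ndarray:
    """Coordinates (Å) of ``ligand`` posed according to dof vector ``x``.

    Order of operations: each torsion rotates its moving branch about the
    bond axis (detection order); the whole ligand is then rotated about its
    centroid by Z–Y–Z Euler angles; finally the centroid is placed at
    ``sphere.center + (tx, ty, tz)``.  Rigid internal geometry (everything
    not spanning a rotatable bond) is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    if spec is None:
        rot_bonds = detect_rotatable_bonds(ligand)
    else:
        rot_bonds = spec.rotatable_bonds
    n_expected = 6 + len(rot_bonds)
    if x.shape != (n_expected,):
        raise DomainError(
            f"pose vector has length {x.size}, expected {n_expected}")
    coords = ligand.coords().copy()

    # torsions
    if rot_bonds:
        branches = _torsion_branches(ligand, rot_bonds)
        for (fixed_row, moving_row, mask), angle in zip(branches, x[6:]):
            if angle % 360.0 == 0.0 or not mask.any():
                continue
            axis_from = coords[fixed_row]
            axis_to = coords[moving_row]
            axis = axis_to - axis_from
            norm = np.linalg.norm(axis)
            if norm < 1e-12:
                raise StructureError("degenerate rotatable bond (zero length)")
            rot = Rotation.from_rotvec(np.deg2rad(angle) * axis / norm)
            coords[mask] = axis_to + rot.apply(coords[mask] - axis_to)

    # rigid-body orientation about the centroid, then translation
    centroid = coords.mean(axis=0)
    rot = Rotation.from_euler("ZYZ", x[3:6], degrees=True)
    coords = centroid + rot.apply(coords - centroid)
    target = sphere.center_array + x[:3]
    coords += target - centroid
    return coords
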