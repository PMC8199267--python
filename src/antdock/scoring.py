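"""Empirical protein–ligand scoring: plp, plp95 and chemplp.

All three scoring functions share the same structure.  Steric complementarity
between receptor and ligand heavy atoms is modelled by a piece-wise linear
distance potential with breakpoints ``A < B < C < D``: a linear clash penalty
below A, a linear descent to a flat attractive well on [B, C], a linear return
to zero at D and zero beyond.  Ligand strain is the sum of a repulsive-only
heavy-atom clash term over atom pairs at graph distance >= 4 bonds and a
cosine torsional potential over rotatable bonds.  chemplp adds an
angle-dependent hydrogen-bond term (product of linear "block" ramps in the
H···acceptor distance and the D–H···A angle, after the ChemScore family).

More negative totals mean stronger predicted binding.  The numeric parameter
values shipped here are this package's own parameterization and can be
overridden per scenario; the functional forms are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .conformation import DockingSphere, DofSpec, apply_pose
from .errors import ConfigurationError
from .ligand_io import Molecule, detect_rotatable_bonds

__all__ = [
    "PLPParams",
    "HBondParams",
    "TorsionParams",
    "TorsionTable",
    "ScoreBreakdown",
    "ScoringParams",
    "scoring_params",
    "plp_pair",
    "hbond_term",
    "torsion_energy",
    "internal_clash",
    "score_pose",
    "SCORING_FUNCTIONS",
]

SCORING_FUNCTIONS = ("plp", "plp95", "chemplp")


@dataclass(frozen=True)
class PLPParams:
    """Breakpoints (Å) and weights of one piece-wise linear interaction class."""

    A: float
    B: float
    C: float
    D: float
    well_depth: float
    clash_weight: float

    def __post_init__(self) -> None:
        if not (0 < self.A < self.B < self.C < self.D):
            raise ConfigurationError("PLP breakpoints must satisfy 0 < A < B < C < D")
        if self.well_depth > 0:
            raise ConfigurationError("well_depth must be <= 0")
        if self.clash_weight <= 0:
            raise ConfigurationError("clash_weight must be > 0")


@dataclass(frozen=True)
class HBondParams:
    """Ideal geometry and tolerances of the chemplp hydrogen-bond term.

    Distance is H···acceptor (Å); angle is the donor–H···acceptor angle
    (degrees, ideal 180 = linear).
    """

    ideal_distance: float = 1.9
    distance_tolerance: float = 0.45
    ideal_angle: float = 180.0
    angle_tolerance: float = 60.0
    hbond_weight: float = -3.0

    def __post_init__(self) -> None:
        if self.distance_tolerance <= 0 or self.angle_tolerance <= 0:
            raise ConfigurationError("H-bond tolerances must be positive")
        if self.hbond_weight > 0:
            raise ConfigurationError("hbond_weight must be <= 0")


@dataclass(frozen=True)
class TorsionParams:
    """One cosine torsion record: E(phi) = k (1 + cos(n phi - phi0))."""

    k: float
    n: int
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError("torsion barrier k must be >= 0")
        if self.n not in (1, 2, 3, 6):
            raise ConfigurationError("torsion periodicity must be 1, 2, 3 or 6")


class TorsionTable:
    """Torsion records keyed by the (sorted) Tripos types of the bond atoms,
    with a generic sp3–sp3 fallback."""

    def __init__(self, records: dict[tuple[str, str], TorsionParams] | None = None,
                 fallback: TorsionParams = TorsionParams(k=0.2, n=3, phi0=0.0)):
        self.records = dict(records or {})
        self.fallback = fallback

    def lookup(self, type_a: str | None, type_b: str | None) -> TorsionParams:
        key = tuple(sorted((type_a or "", type_b or "")))
        return self.records.get(key, self.fallback)


_DEFAULT_TORSION_TABLE = TorsionTable({
    ("C.3", "C.3"): TorsionParams(k=0.2, n=3, phi0=0.0),
    ("C.2", "C.3"): TorsionParams(k=0.12, n=6, phi0=0.0),
    ("C.3", "N.3"): TorsionParams(k=0.2, n=3, phi0=0.0),
    ("C.3", "O.3"): TorsionParams(k=0.12, n=3, phi0=0.0),
    ("C.ar", "C.3"): TorsionParams(k=0.12, n=6, phi0=0.0),
})


@dataclass
class ScoreBreakdown:
    steric: float
    hbond: float
    internal_clash: float
    torsion: float

    @property
    def total(self) -> float:
        return self.steric + self.hbond + self.internal_clash + self.torsion


@dataclass(frozen=True)
class ScoringParams:
    """Complete parameter set of one scoring function."""

    name: str
    steric: PLPParams
    hbond_pair: PLPParams
    hbond: HBondParams | None = None
    torsion_table: TorsionTable = field(default_factory=lambda: _DEFAULT_TORSION_TABLE)

    @property
    def max_cutoff(self) -> float:
        return max(self.steric.D, self.hbond_pair.D)


_STERIC_DEFAULT = PLPParams(A=3.4, B=3.6, C=4.5, D=5.5,
                            well_depth=-0.4, clash_weight=20.0)
_HBOND_PAIR_DEFAULT = PLPParams(A=2.3, B=2.6, C=3.1, D=3.4,
                                well_depth=-2.0, clash_weight=20.0)
# plp95 keeps the functional form and differs only in its steric breakpoints.
_STERIC_PLP95 = PLPParams(A=3.2, B=3.8, C=4.6, D=6.0,
                          well_depth=-0.4, clash_weight=20.0)


def scoring_params(name: str, overrides: dict | None = None) -> ScoringParams:
    """Named parameter set for ``plp``, ``plp95`` or ``chemplp``.

    ``overrides`` may replace any field of the steric / hbond-pair / hbond
    classes, e.g. ``{"steric": {"A": 3.2}, "hbond": {"hbond_weight": -4.0}}``.
    """
    if name == "plp":
        params = ScoringParams("plp", steric=_STERIC_DEFAULT,
                               hbond_pair=_HBOND_PAIR_DEFAULT)
    elif name == "plp95":
        params = ScoringParams("plp95", steric=_STERIC_PLP95,
                               hbond_pair=_HBOND_PAIR_DEFAULT)
    elif name == "chemplp":
        params = ScoringParams("chemplp", steric=_STERIC_DEFAULT,
                               hbond_pair=_HBOND_PAIR_DEFAULT,
                               hbond=HBondParams())
    else:
        raise ConfigurationError(
            f"unknown scoring_function {name!r}; choose from {SCORING_FUNCTIONS}")
    if overrides:
        fields = {}
        for cls_name in ("steric", "hbond_pair", "hbond"):
            if cls_name in overrides:
                base = getattr(params, cls_name)
                if base is None:
                    raise ConfigurationError(
                        f"{name} has no {cls_name} term to override")
                fields[cls_name] = replace(base, **overrides[cls_name])
        params = replace(params, **fields)
    return params


# ---------------------------------------------------------------------------
# Elementary terms
# ---------------------------------------------------------------------------

def plp_pair(r, p: PLPParams):
    """Piece-wise linear pair potential at distance(s) ``r`` (Å).

    clash_weight·(A−r) below A; 0 at A descending linearly to well_depth at B;
    flat well on [B, C]; back to 0 at D; 0 beyond.  Continuous everywhere.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    xp = np.array([0.0, p.A, p.B, p.C, p.D])
    fp = np.array([p.clash_weight * p.A, 0.0, p.well_depth, p.well_depth, 0.0])
    out = np.interp(r, xp, fp, right=0.0)
    return float(out) if out.ndim == 0 else out


def _block(deviation: float, tolerance: float) -> float:
    """Linear ramp: 1 at zero deviation, 0 at/beyond the tolerance."""
    return max(0.0, 1.0 - abs(deviation) / tolerance)


def hbond_term(donor_pos, hydrogen_pos, acceptor_pos, p: HBondParams) -> float:
    """Angle-dependent hydrogen-bond score for one D–H···A triple.

    ``hbond_weight × block(|d(H,A) − ideal_distance|) × block(|angle −
    ideal_angle|)``; 0 when either geometry deviation exceeds its tolerance,
    ``hbond_weight`` at ideal geometry.
    """
    d = np.asarray(donor_pos, dtype=float)
    h = np.asarray(hydrogen_pos, dtype=float)
    a = np.asarray(acceptor_pos, dtype=float)
    dist = float(np.linalg.norm(a - h))
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    return (p.hbond_weight
            * _block(dist - p.ideal_distance, p.distance_tolerance)
            * _block(angle - p.ideal_angle, p.angle_tolerance))


def torsion_energy(phi: float, t: TorsionParams) -> float:
    """Cosine torsion energy ``k (1 + cos(n phi − phi0))`` in score units;
    range [0, 2k], period 360/n degrees."""
    return t.k * (1.0 + math.cos(math.radians(t.n * phi - t.phi0)))


def _repulsive(r, p: PLPParams):
    """Repulsive-only branch: clash_weight·(A−r) below A, else 0."""
    r = np.asarray(r, dtype=float)
    out = np.where(r < p.A, p.clash_weight * (p.A - r), 0.0)
    return float(out) if out.ndim == 0 else out


def _bond_graph_distances(m: Molecule) -> np.ndarray:
    """All-pairs bond-graph distances between atom rows (BFS per atom;
    ligands are small)."""
    n = m.n_atoms
    row_of = {a.index: i for i, a in enumerate(m.atoms)}
    adj_rows: list[list[int]] = [[] for _ in range(n)]
    for b in m.bonds:
        adj_rows[row_of[b.a]].append(row_of[b.b])
        adj_rows[row_of[b.b]].append(row_of[b.a])
    dist = np.full((n, n), 10 ** 6, dtype=int)
    for src in range(n):
        dist[src, src] = 0
        queue = [src]
        while queue:
            nxt = []
            for node in queue:
                for nbr in adj_rows[node]:
                    if dist[src, nbr] > dist[src, node] + 1:
                        dist[src, nbr] = dist[src, node] + 1
                        nxt.append(nbr)
            queue = nxt
    return dist


def internal_clash(coords: np.ndarray, m: Molecule, p: PLPParams) -> float:
    """Ligand-internal clash penalty: repulsive-only PLP branch summed over
    heavy-atom pairs separated by at least 4 bonds.  Always >= 0."""
    coords = np.asarray(coords, dtype=float)
    heavy_rows = np.array([i for i, a in enumerate(m.atoms) if a.is_heavy])
    if heavy_rows.size < 2:
        return 0.0
    graph = _bond_graph_distances(m)
    total = 0.0
    for ii in range(len(heavy_rows)):
        for jj in range(ii + 1, len(heavy_rows)):
            i, j = heavy_rows[ii], heavy_rows[jj]
            if graph[i, j] < 4:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            total += _repulsive(r, p)
    return total


# ---------------------------------------------------------------------------
# Full pose score
# ---------------------------------------------------------------------------

def _is_polar(atom) -> bool:
    return atom.element in ("N", "O")


def _donor_triples(m: Molecule) -> list[tuple[int, int]]:
    """(heavy donor row, hydrogen row) pairs: H bonded to N or O."""
    row_of = {a.index: i for i, a in enumerate(m.atoms)}
    triples = []
    for b in m.bonds:
        aa = m.atom_by_index(b.a)
        ab = m.atom_by_index(b.b)
        if aa.element == "H" and _is_polar(ab):
            triples.append((row_of[ab.index], row_of[aa.index]))
        elif ab.element == "H" and _is_polar(aa):
            triples.append((row_of[aa.index], row_of[ab.index]))
    return triples


def _acceptor_rows(m: Molecule) -> list[int]:
    return [i for i, a in enumerate(m.atoms) if _is_polar(a)]


class PoseScorer:
    """Pre-indexed scorer binding one receptor/ligand/scenario triple.

    Receptor heavy atoms are held in a k-d tree so each pose only touches
    pairs within the potential cutoff.  Use :func:`score_pose` for the
    one-shot functional interface.
    """

    def __init__(self, receptor: Molecule, ligand: Molecule,
                 params: ScoringParams, sphere: DockingSphere,
                 spec: DofSpec | None = None):
        self.receptor = receptor
        self.ligand = ligand
        self.params = params
        self.sphere = sphere
        self.spec = spec
        rec_coords = receptor.coords()
        self._rec_heavy_rows = np.array(
            [i for i, a in enumerate(receptor.atoms) if a.is_heavy], dtype=int)
        self._rec_heavy_coords = rec_coords[self._rec_heavy_rows]
        self._rec_heavy_polar = np.array(
            [_is_polar(receptor.atoms[i]) for i in self._rec_heavy_rows])
        self._tree = (cKDTree(self._rec_heavy_coords)
                      if len(self._rec_heavy_coords) else None)
        self._lig_heavy_rows = np.array(
            [i for i, a in enumerate(ligand.atoms) if a.is_heavy], dtype=int)
        self._lig_heavy_polar = np.array(
            [_is_polar(ligand.atoms[i]) for i in self._lig_heavy_rows])
        # H-bond bookkeeping (chemplp only)
        self._lig_donors = _donor_triples(ligand)
        self._lig_acceptors = _acceptor_rows(ligand)
        self._rec_donors = _donor_triples(receptor)
        self._rec_acceptors = _acceptor_rows(receptor)
        self._rec_coords = rec_coords
        # ligand-internal pair eligibility (graph distance >= 4)
        graph = _bond_graph_distances(ligand)
        pairs = []
        hr = self._lig_heavy_rows
        for ii in range(len(hr)):
            for jj in range(ii + 1, len(hr)):
                if graph[hr[ii], hr[jj]] >= 4:
                    pairs.append((hr[ii], hr[jj]))
        self._clash_pairs = np.array(pairs, dtype=int).reshape(-1, 2)
        rot_bonds = (spec.rotatable_bonds if spec is not None
                     else detect_rotatable_bonds(ligand))
        self._torsion_records = [self._torsion_record(pos) for pos in rot_bonds]

    def _torsion_record(self, bond_pos: int):
        bond = self.ligand.bonds[bond_pos]
        aa = self.ligand.atom_by_index(bond.a)
        ab = self.ligand.atom_by_index(bond.b)
        rec = self.params.torsion_table.lookup(aa.type_label, ab.type_label)
        row_of = {a.index: i for i, a in enumerate(self.ligand.atoms)}
        nbrs = self.ligand.neighbor_map()
        heavy = {a.index for a in self.ligand.atoms if a.is_heavy}

        def _ref(center: int, exclude: int) -> int | None:
            cands = [n for n in nbrs[center] if n != exclude and n in heavy]
            if not cands:
                cands = [n for n in nbrs[center] if n != exclude]
            return min(cands) if cands else None

        ra = _ref(bond.a, bond.b)
        rb = _ref(bond.b, bond.a)
        if ra is None or rb is None:
            return None
        return (rec, row_of[ra], row_of[bond.a], row_of[bond.b], row_of[rb])

    # -- term evaluation ---------------------------------------------------

    def steric_score(self, lig_coords: np.ndarray) -> float:
        if self._tree is None or not len(self._lig_heavy_rows):
            return 0.0
        p = self.params
        cutoff = p.max_cutoff
        lig_heavy = lig_coords[self._lig_heavy_rows]
        total = 0.0
        neighbor_lists = self._tree.query_ball_point(lig_heavy, r=cutoff)
        for k, rec_rows in enumerate(neighbor_lists):
            if not rec_rows:
                continue
            rec_rows = np.asarray(rec_rows, dtype=int)
            d = np.linalg.norm(
                self._rec_heavy_coords[rec_rows] - lig_heavy[k], axis=1)
            hb_mask = self._rec_heavy_polar[rec_rows] & self._lig_heavy_polar[k]
            if hb_mask.any():
                total += float(np.sum(plp_pair(d[hb_mask], p.hbond_pair)))
            if (~hb_mask).any():
                total += float(np.sum(plp_pair(d[~hb_mask], p.steric)))
        return total

    def hbond_score(self, lig_coords: np.ndarray) -> float:
        hb = self.params.hbond
        if hb is None:
            return 0.0
        reach = hb.ideal_distance + hb.distance_tolerance
        total = 0.0
        # ligand donor -> receptor acceptor
        for donor_row, h_row in self._lig_donors:
            h = lig_coords[h_row]
            for acc_row in self._rec_acceptors:
                a = self._rec_coords[acc_row]
                if np.linalg.norm(a - h) <= reach:
                    total += hbond_term(lig_coords[donor_row], h, a, hb)
        # receptor donor -> ligand acceptor
        for donor_row, h_row in self._rec_donors:
            h = self._rec_coords[h_row]
            for acc_row in self._lig_acceptors:
                a = lig_coords[acc_row]
                if np.linalg.norm(a - h) <= reach:
                    total += hbond_term(self._rec_coords[donor_row], h, a, hb)
        return total

    def internal_clash_score(self, lig_coords: np.ndarray) -> float:
        if not len(self._clash_pairs):
            return 0.0
        d = np.linalg.norm(lig_coords[self._clash_pairs[:, 0]]
                           - lig_coords[self._clash_pairs[:, 1]], axis=1)
        return float(np.sum(_repulsive(d, self.params.steric)))

    def torsion_score(self, lig_coords: np.ndarray) -> float:
        total = 0.0
        for item in self._torsion_records:
            if item is None:
                continue
            rec, r0, r1, r2, r3 = item
            phi = _dihedral(lig_coords[r0], lig_coords[r1],
                            lig_coords[r2], lig_coords[r3])
            total += torsion_energy(phi, rec)
        return total

    def breakdown(self, x) -> ScoreBreakdown:
        lig_coords = apply_pose(self.ligand, x, self.sphere, self.spec)
        return ScoreBreakdown(
            steric=self.steric_score(lig_coords),
            hbond=self.hbond_score(lig_coords),
            internal_clash=self.internal_clash_score(lig_coords),
            torsion=self.torsion_score(lig_coords))

    def __call__(self, x) -> float:
        return self.breakdown(x).total


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / (np.linalg.norm(b1) + 1e-30))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def score_pose(receptor: Molecule, ligand: Molecule, x, scenario) -> ScoreBreakdown:
    """Score one pose of ``ligand`` against ``receptor`` under a scenario.

    ``scenario`` needs ``scoring_function``, ``sphere`` and (optionally)
    parameter overrides; the dof vector ``x`` is applied before scoring.
    Deterministic given its inputs.
    """
    params = scenario.resolved_scoring_params()
    spec = getattr(scenario, "dof_spec", None)
    scorer = PoseScorer(receptor, ligand, params, scenario.sphere, spec)
    return scorer.breakdown(x)
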