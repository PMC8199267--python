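"""Synthetic receptors, ligands, libraries and oracles.

Everything the test-bed needs is generated programmatically from a seed:

* small drug-like toy ligands built from a handful of functional-group
  templates (alkanes, an amide, an aromatic amine, an alcohol) with jittered
  geometry and charges — enough chemistry to exercise typing, torsions,
  clashes and hydrogen bonding without any external library;
* pocket-shaped toy receptors built *around* a planted ligand pose, so each
  complex has a known, verified optimum;
* hierarchical on-disk ligand libraries (meta-tranche / tranche / collection)
  in MOL2 or PDBQT with a manifest of expected ligand ids;
* an exhaustive-grid docking oracle and a desk-scale parameter-variation
  benchmark harness.
"""

from __future__ import annotations

import io
import math
import tarfile
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .aco_engine import ACOParams, optimize, resolve_defaults
from .config import DockingScenario
from .conformation import DockingSphere, DofSpec, apply_pose, build_dof_spec
from .errors import ConfigurationError
from .ligand_io import (Atom, Bond, Molecule, _flag_ring_bonds,
                        assign_tripos_types, detect_rotatable_bonds,
                        write_mol2, write_pdbqt)
from .scoring import PoseScorer, scoring_params
from .screening import LibraryHierarchy, library_size

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "BenchmarkGrid",
    "make_toy_complex",
    "make_fixture_library",
    "brute_force_dock",
    "run_benchmark",
    "generate_ligand",
    "template_names",
    "build_template",
    "table1_scenarios",
]


# ---------------------------------------------------------------------------
# Template molecules
# ---------------------------------------------------------------------------

_CC = 1.54      # sp3 C-C bond length, Å
_CH = 1.09
_NH = 1.01
_OH = 0.96

_TARGET_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def _zigzag_chain(n: int, bond: float = _CC, angle_deg: float = 111.0) -> np.ndarray:
    """Coordinates of an n-atom zig-zag chain in the xy plane."""
    half = math.radians(angle_deg) / 2.0
    dx = bond * math.sin(half)
    dy = bond * math.cos(half)
    return np.array([[i * dx, (i % 2) * dy, 0.0] for i in range(n)])


def _fill_hydrogens(atoms: list[Atom], bonds: list[Bond]) -> None:
    """Append hydrogens so C/N/O reach their target valence.

    H directions point away from the mean neighbor direction, splayed around
    it when more than one H is needed.  Geometry is approximate but clean
    enough for distance-based bond perception.
    """
    by_index = {a.index: a for a in atoms}
    nbrs: dict[int, list[int]] = {a.index: [] for a in atoms}
    for b in bonds:
        nbrs[b.a].append(b.b)
        nbrs[b.b].append(b.a)
    next_index = max(a.index for a in atoms) + 1
    for atom in list(atoms):
        target = _TARGET_VALENCE.get(atom.element)
        if target is None:
            continue
        order_sum = 0.0
        for b in bonds:
            if atom.index in (b.a, b.b):
                order_sum += {2: 2.0, 3: 3.0, "ar": 1.5}.get(b.order, 1.0)
        missing = int(round(target - order_sum))
        if missing <= 0:
            continue
        neighbor_vecs = [by_index[j].position - atom.position
                         for j in nbrs[atom.index]]
        if neighbor_vecs:
            away = -np.sum(neighbor_vecs, axis=0)
            if np.linalg.norm(away) < 1e-6:
                away = np.array([0.0, 0.0, 1.0])
        else:
            away = np.array([1.0, 0.0, 0.0])
        away = away / np.linalg.norm(away)
        # orthonormal frame around `away`
        helper = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(helper, away)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(away, helper)
        u /= np.linalg.norm(u)
        v = np.cross(away, u)
        length = {"C": _CH, "N": _NH, "O": _OH}[atom.element]
        tilt = math.radians(40.0) if missing > 1 else 0.0
        for k in range(missing):
            phi = 2.0 * math.pi * k / max(missing, 1)
            direction = (math.cos(tilt) * away
                         + math.sin(tilt) * (math.cos(phi) * u + math.sin(phi) * v))
            pos = atom.position + length * direction
            atoms.append(Atom(index=next_index, element="H", position=pos))
            bonds.append(Bond(a=atom.index, b=next_index, order=1))
            next_index += 1


def _assemble(name: str, heavy: list[tuple[str, tuple[float, float, float], float]],
              bond_spec: list[tuple[int, int, int | str]]) -> Molecule:
    atoms = [Atom(index=i + 1, element=el, position=np.array(pos, dtype=float),
                  partial_charge=q) for i, (el, pos, q) in enumerate(heavy)]
    bonds = [Bond(a=a, b=b, order=o) for a, b, o in bond_spec]
    _fill_hydrogens(atoms, bonds)
    mol = Molecule(name=name, atoms=atoms, bonds=bonds)
    _flag_ring_bonds(mol)
    return assign_tripos_types(mol)


def _butane() -> Molecule:
    chain = _zigzag_chain(4)
    heavy = [("C", tuple(p), 0.0) for p in chain]
    bonds = [(1, 2, 1), (2, 3, 1), (3, 4, 1)]
    return _assemble("butane", heavy, bonds)


def _isopentane() -> Molecule:
    chain = _zigzag_chain(4)
    branch = chain[1] + np.array([0.0, 1.26, 0.89])
    heavy = [("C", tuple(p), 0.0) for p in chain] + [("C", tuple(branch), 0.0)]
    bonds = [(1, 2, 1), (2, 3, 1), (3, 4, 1), (2, 5, 1)]
    return _assemble("isopentane", heavy, bonds)


def _n_methylacetamide() -> Molecule:
    heavy = [
        ("C", (-1.52, 0.00, 0.0), 0.05),    # methyl
        ("C", (0.00, 0.00, 0.0), 0.45),     # carbonyl C
        ("O", (0.61, 1.06, 0.0), -0.50),    # carbonyl O
        ("N", (0.67, -1.16, 0.0), -0.40),   # amide N
        ("C", (2.12, -1.25, 0.0), 0.05),    # N-methyl
    ]
    bonds = [(1, 2, 1), (2, 3, 2), (2, 4, "am"), (4, 5, 1)]
    return _assemble("n-methylacetamide", heavy, bonds)


def _propanol() -> Molecule:
    chain = _zigzag_chain(4)
    heavy = [("C", tuple(p), 0.0) for p in chain[:3]]
    heavy.append(("O", tuple(chain[3]), -0.38))
    bonds = [(1, 2, 1), (2, 3, 1), (3, 4, 1)]
    return _assemble("propan-1-ol", heavy, bonds)


def _chloroaniline() -> Molecule:
    """3-chloroaniline: a rigid asymmetric aromatic with an N-H donor."""
    ring_r = 1.39
    heavy: list[tuple[str, tuple[float, float, float], float]] = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        heavy.append(("C", (ring_r * math.cos(ang), ring_r * math.sin(ang), 0.0),
                      0.0))
    # N on ring atom 1 (angle 0), Cl on ring atom 3 (angle 120)
    n_pos = ((ring_r + 1.40) * math.cos(0.0), (ring_r + 1.40) * math.sin(0.0), 0.0)
    ang = math.radians(120.0)
    cl_pos = ((ring_r + 1.74) * math.cos(ang), (ring_r + 1.74) * math.sin(ang), 0.0)
    heavy.append(("N", n_pos, -0.35))
    heavy.append(("Cl", cl_pos, -0.10))
    bonds: list[tuple[int, int, int | str]] = [
        (1, 2, "ar"), (2, 3, "ar"), (3, 4, "ar"),
        (4, 5, "ar"), (5, 6, "ar"), (6, 1, "ar"),
        (1, 7, 1), (3, 8, 1),
    ]
    return _assemble("3-chloroaniline", heavy, bonds)


_TEMPLATES = {
    "butane": _butane,
    "isopentane": _isopentane,
    "n-methylacetamide": _n_methylacetamide,
    "propan-1-ol": _propanol,
    "3-chloroaniline": _chloroaniline,
}


def template_names() -> list[str]:
    return sorted(_TEMPLATES)


def build_template(name: str) -> Molecule:
    try:
        return _TEMPLATES[name]()
    except KeyError:
        raise ConfigurationError(
            f"unknown template {name!r}; known: {template_names()}") from None


def generate_ligand(rng: np.random.Generator, name: Optional[str] = None,
                    template: Optional[str] = None) -> Molecule:
    """A randomized toy ligand: template choice + rigid rotation + small
    coordinate and charge jitter (never enough to change connectivity)."""
    template = template or template_names()[rng.integers(len(_TEMPLATES))]
    mol = build_template(template)
    coords = mol.coords()
    coords = coords - coords.mean(axis=0)
    from scipy.spatial.transform import Rotation
    coords = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(2 ** 31)))).apply(coords)
    coords = coords + rng.normal(scale=0.02, size=coords.shape)
    mol = mol.with_coords(coords)
    # 3 decimals: representable exactly in both MOL2 and PDBQT charge columns
    for atom in mol.atoms:
        atom.partial_charge = round(atom.partial_charge
                                    + float(rng.normal(scale=0.01)), 3)
    if name:
        mol.name = name
    return mol


# ---------------------------------------------------------------------------
# Toy complexes with a planted optimum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a pocket/ligand pair with a known good pose."""

    seed: int = 0
    pocket_atoms: int = 24
    sphere_radius: float = 4.0
    ligand_template: str = "3-chloroaniline"
    scoring_function: str = "chemplp"
    planted_pose: Optional[tuple[float, ...]] = None
    # Discretization the complex is built for: the planted pose sits near a
    # cell midpoint of this grid and generation verifies the planted cell is
    # the grid's unique distinct optimum.  The default leaves each angle one
    # full-circle interval (orientation is sampled continuously within it and
    # refined by local search) so the translation cells carry the pheromone
    # learning.
    grid_angular_step: float = 360.0
    grid_linear_step: float = 1.0


@dataclass
class ToyComplex:
    receptor: Molecule
    ligand: Molecule
    sphere: DockingSphere
    planted_pose: np.ndarray
    planted_score: float


def make_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build a receptor pocket around a planted ligand pose.

    Pocket pseudo-atoms are placed in the flat well of the steric potential
    around randomly chosen ligand heavy atoms, plus one acceptor oxygen on
    the axis of a ligand N–H/O–H donor at ideal hydrogen-bond geometry.  At
    generation time the planted pose is verified to score negative and to
    beat poses displaced by >= 2 Å; on failure the next seed is tried (up to
    10 attempts).
    """
    last_error = None
    for attempt in range(10):
        seed = spec.seed + attempt
        try:
            return _build_toy_complex(spec, seed)
        except _GenerationFailure as exc:
            last_error = exc
    raise ConfigurationError(
        f"toy-complex generation failed for 10 consecutive seeds "
        f"starting at {spec.seed}: {last_error}")


class _GenerationFailure(Exception):
    pass


def _build_toy_complex(spec: ToyComplexSpec, seed: int) -> ToyComplex:
    rng = np.random.default_rng(seed)
    ligand = build_template(spec.ligand_template)
    sphere = DockingSphere(center=(0.0, 0.0, 0.0), radius=spec.sphere_radius)
    n_torsions = len(detect_rotatable_bonds(ligand))
    dof_spec = build_dof_spec(ligand, sphere,
                              angular_step=spec.grid_angular_step,
                              linear_step=spec.grid_linear_step)
    if spec.planted_pose is not None:
        planted = np.asarray(spec.planted_pose, dtype=float)
    else:
        # a random cell midpoint plus a small jitter (well below half a cell,
        # capped in absolute terms), so the planted basin lives inside one
        # identifiable grid cell whose midpoint nearly reproduces the pose
        planted = np.empty(6 + n_torsions)
        for i, partition in enumerate(dof_spec.partitions):
            ell = int(rng.integers(1, partition.n_intervals + 1))
            width = partition.upper(ell) - partition.lower(ell)
            cap = 5.0 if dof_spec.rotational[i] else 0.1
            jitter = min(0.1 * width, cap)
            planted[i] = partition.midpoint(ell) + rng.uniform(-jitter, jitter)
    lig_coords = apply_pose(ligand, planted, sphere)
    heavy_rows = [i for i, a in enumerate(ligand.atoms) if a.is_heavy]

    params = scoring_params(spec.scoring_function)
    well_lo, well_hi = params.steric.B, params.steric.C
    d_star = 0.5 * (well_lo + well_hi)
    min_sep = params.steric.A + 0.1

    atoms: list[Atom] = []
    index = 1
    attempts = 0
    while len(atoms) < spec.pocket_atoms and attempts < 4000:
        attempts += 1
        anchor = lig_coords[heavy_rows[rng.integers(len(heavy_rows))]]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + d_star * direction
        d_all = np.linalg.norm(lig_coords[heavy_rows] - pos, axis=1)
        if d_all.min() < min_sep:
            continue
        if atoms and min(np.linalg.norm(a.position - pos) for a in atoms) < 2.0:
            continue
        atoms.append(Atom(index=index, element="C", position=pos,
                          type_label="C.3"))
        index += 1
    if len(atoms) < spec.pocket_atoms:
        raise _GenerationFailure("could not place the requested pocket atoms")

    # one acceptor O on the axis of a ligand donor H (chemplp reward)
    donor = _first_donor(ligand)
    if donor is not None:
        d_row, h_row = donor
        h = lig_coords[h_row]
        axis = h - lig_coords[d_row]
        axis /= np.linalg.norm(axis)
        hb = params.hbond or scoring_params("chemplp").hbond
        pos = h + hb.ideal_distance * axis
        atoms.append(Atom(index=index, element="O", position=pos,
                          type_label="O.3"))
        index += 1

    receptor = Molecule(name=f"toy_pocket_seed{seed}", atoms=atoms, bonds=[])

    scorer = PoseScorer(receptor, ligand, params, sphere, dof_spec)
    planted_score = scorer(planted)
    if planted_score >= 0:
        raise _GenerationFailure(f"planted pose scores {planted_score:.2f} >= 0")
    for _ in range(20):
        offset = rng.normal(size=3)
        offset *= (2.0 + rng.uniform(0, 1.0)) / np.linalg.norm(offset)
        displaced = planted.copy()
        displaced[:3] = np.clip(planted[:3] + offset,
                                -spec.sphere_radius, spec.sphere_radius)
        if np.linalg.norm(displaced[:3] - planted[:3]) < 1.9:
            continue
        if scorer(displaced) <= planted_score:
            raise _GenerationFailure("a displaced pose beat the planted pose")
    # grid check: the planted cell must be the distinct optimum of the grid
    # the complex was built for (no competing pocket on a far cell)
    n_cells = int(np.prod([p.n_intervals for p in dof_spec.partitions]))
    if n_cells <= 5000:
        planted_cell = dof_spec.cell_of(dof_spec.wrap_clip(planted))
        best_cell, best = None, math.inf
        runner_up = math.inf
        shape = tuple(p.n_intervals for p in dof_spec.partitions)
        for raw in np.ndindex(*shape):
            cell = tuple(c + 1 for c in raw)
            score = scorer(dof_spec.midpoint_vector(cell))
            if score < best:
                best_cell, best = cell, score
            if score < runner_up and _cell_distance(cell, planted_cell) > 1:
                runner_up = score
        if best_cell != planted_cell:
            raise _GenerationFailure(
                f"grid optimum {best_cell} is not the planted cell {planted_cell}")
        if runner_up < 0.7 * best:
            raise _GenerationFailure(
                "a non-neighboring cell competes with the planted basin")
    return ToyComplex(receptor=receptor, ligand=ligand, sphere=sphere,
                      planted_pose=planted, planted_score=float(planted_score))


def _cell_distance(cell_a: tuple[int, ...], cell_b: tuple[int, ...]) -> int:
    return max(abs(a - b) for a, b in zip(cell_a, cell_b))


def _first_donor(m: Molecule):
    row_of = {a.index: i for i, a in enumerate(m.atoms)}
    for b in m.bonds:
        aa = m.atom_by_index(b.a)
        ab = m.atom_by_index(b.b)
        if aa.element == "H" and ab.element in ("N", "O"):
            return row_of[ab.index], row_of[aa.index]
        if ab.element == "H" and aa.element in ("N", "O"):
            return row_of[aa.index], row_of[ab.index]
    return None


# ---------------------------------------------------------------------------
# On-disk fixture libraries
# ---------------------------------------------------------------------------

def make_fixture_library(h: LibraryHierarchy, fmt: str, seed: int,
                         root: str | Path,
                         identical_collections: bool = True,
                         as_tar: bool = True) -> tuple[Path, list[str]]:
    """Write a hierarchical ligand library and return (root, manifest).

    Collections are tar archives (or plain directories) of per-ligand MOL2 or
    PDBQT files.  With ``identical_collections`` every collection holds the
    same compound set, mirroring the replicated-collection layout of large
    synthetic screening libraries; otherwise each collection gets fresh
    random ligands.  Requests above 10^4 total compounds are refused — the
    fixture generator is for desk-scale trees.
    """
    total = library_size(h)
    if total > 10_000:
        raise ConfigurationError(
            f"fixture library of {total} compounds refused; keep totals "
            "<= 10^4 (generate larger inputs at run time in chunks)")
    if fmt not in ("MOL2", "PDBQT"):
        raise ConfigurationError(f"unknown library format {fmt!r}")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    suffix = ".mol2" if fmt == "MOL2" else ".pdbqt"
    writer = write_mol2 if fmt == "MOL2" else write_pdbqt

    def _compound_files() -> list[tuple[str, str]]:
        files = []
        for m in range(h.n_compounds_per_collection):
            mol = generate_ligand(rng, name=f"ligand_{m:04d}")
            files.append((f"ligand_{m:04d}{suffix}", writer(mol)))
        return files

    shared = _compound_files() if identical_collections else None
    manifest: list[str] = []
    for i in range(h.n_meta_tranches):
        meta_dir = root / f"meta_{i:02d}"
        for j in range(h.n_tranches_per_meta):
            tranche_dir = meta_dir / f"tranche_{j:03d}"
            tranche_dir.mkdir(parents=True, exist_ok=True)
            for k in range(h.n_collections_per_tranche):
                files = shared if shared is not None else _compound_files()
                coll_name = f"collection_{k:04d}"
                if as_tar:
                    tar_path = tranche_dir / f"{coll_name}.tar"
                    with tarfile.open(tar_path, "w") as tar:
                        for fname, text in files:
                            data = text.encode()
                            info = tarfile.TarInfo(name=fname)
                            info.size = len(data)
                            info.mtime = 0
                            tar.addfile(info, io.BytesIO(data))
                else:
                    coll_dir = tranche_dir / coll_name
                    coll_dir.mkdir(exist_ok=True)
                    for fname, text in files:
                        (coll_dir / fname).write_text(text)
                for fname, _ in files:
                    manifest.append(
                        f"meta_{i:02d}_tranche_{j:03d}_{coll_name}_"
                        f"{Path(fname).stem}")
    (root / "manifest.txt").write_text("\n".join(manifest) + "\n")
    return root, manifest


# ---------------------------------------------------------------------------
# Exhaustive-grid oracle
# ---------------------------------------------------------------------------

def brute_force_dock(receptor: Molecule, ligand: Molecule, spec: DofSpec,
                     scenario) -> tuple[tuple[int, ...], float]:
    """Global minimum of the pose score over all interval-midpoint cells.

    Refuses grids above 10^6 cells.  Ties resolve to the lexicographically
    first cell, so the oracle is deterministic.
    """
    n_cells = 1
    for p in spec.partitions:
        n_cells *= p.n_intervals
    if n_cells > 10 ** 6:
        raise ConfigurationError(
            f"grid of {n_cells} cells refused; coarsen the partitions "
            "(the exhaustive oracle is for small problems)")
    scorer = PoseScorer(receptor, ligand, scenario.resolved_scoring_params(),
                        scenario.sphere, spec)
    best_cell: Optional[tuple[int, ...]] = None
    best_score = math.inf
    shape = tuple(p.n_intervals for p in spec.partitions)
    for raw in np.ndindex(*shape):
        cell = tuple(c + 1 for c in raw)
        score = scorer(spec.midpoint_vector(cell))
        if score < best_score:
            best_score = score
            best_cell = cell
    assert best_cell is not None
    return best_cell, float(best_score)


# ---------------------------------------------------------------------------
# Desk-scale parameter-variation benchmark
# ---------------------------------------------------------------------------

def table1_scenarios(sphere: DockingSphere,
                     base_iterations: int = 20,
                     local_search: bool = False,
                     angular_step: float = 60.0,
                     linear_step: float = 3.0) -> list[DockingScenario]:
    """The ten-scenario parameter-variation grid.

    Scenario 1 is the chemplp / speed-4 / all-defaults reference; 2–3 vary
    the speed, 4–5 the ant count (10, 50), 6–7 the evaporation rate (0.10,
    0.25), 8 the simplex scale (1), and 9–10 switch to plp / plp95.
    """
    common = dict(sphere=sphere, base_iterations=base_iterations,
                  local_search=local_search, stagnation_limit=None,
                  angular_step=angular_step, linear_step=linear_step)
    return [
        DockingScenario(name="scenario01", scoring_function="chemplp",
                        search_speed=4, **common),
        DockingScenario(name="scenario02", scoring_function="chemplp",
                        search_speed=2, **common),
        DockingScenario(name="scenario03", scoring_function="chemplp",
                        search_speed=1, **common),
        DockingScenario(name="scenario04", scoring_function="chemplp",
                        search_speed=4, n_ants=10, **common),
        DockingScenario(name="scenario05", scoring_function="chemplp",
                        search_speed=4, n_ants=50, **common),
        DockingScenario(name="scenario06", scoring_function="chemplp",
                        search_speed=4, rho=0.10, **common),
        DockingScenario(name="scenario07", scoring_function="chemplp",
                        search_speed=4, rho=0.25, **common),
        DockingScenario(name="scenario08", scoring_function="chemplp",
                        search_speed=4, sigma=1.0, **common),
        DockingScenario(name="scenario09", scoring_function="plp",
                        search_speed=4, **common),
        DockingScenario(name="scenario10", scoring_function="plp95",
                        search_speed=4, **common),
    ]


@dataclass
class BenchmarkGrid:
    """A benchmark: scenarios x ligand set against one toy receptor."""

    scenarios: list[DockingScenario]
    complex: ToyComplex
    n_ligands: int = 20
    seed: int = 0
    ave_n: int = 10
    ligands: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigurationError("benchmark grid needs scenarios")
        if not self.ligands:
            rng = np.random.default_rng(self.seed)
            self.ligands = [generate_ligand(rng, name=f"bench_{m:03d}")
                            for m in range(self.n_ligands)]


def run_benchmark(grid: BenchmarkGrid) -> pd.DataFrame:
    """Screen the ligand set under every scenario of the grid.

    Returns one row per scenario: the mean top-N score (AVE_N over the
    scenario's own ranking), mean score evaluations per ligand (the
    hardware-independent cost measure) and mean wall seconds per ligand
    (informational).  Deterministic for a given grid seed.
    """
    from .aco_engine import run_aco

    rows = []
    score_distributions: dict[str, list[float]] = {}
    for scenario in grid.scenarios:
        scores = []
        evals = []
        seconds = []
        for m, ligand in enumerate(grid.ligands):
            seed = (grid.seed * 100003 + m * 101
                    + zlib.crc32(scenario.name.encode())) % (2 ** 31)
            start = time.perf_counter()
            result = run_aco(grid.complex.receptor, ligand, scenario, seed=seed)
            seconds.append(time.perf_counter() - start)
            scores.append(result.best.f_s)
            evals.append(result.n_evaluations)
        scores_arr = np.sort(np.asarray(scores))
        n_top = min(grid.ave_n, len(scores_arr))
        rows.append({
            "scenario": scenario.name,
            "scoring_function": scenario.scoring_function,
            "search_speed": scenario.search_speed,
            "ave_n": float(scores_arr[:n_top].mean()),
            "mean_evaluations": float(np.mean(evals)),
            "mean_seconds": float(np.mean(seconds)),
        })
        score_distributions[scenario.name] = scores
    table = pd.DataFrame(rows)
    table.attrs["score_distributions"] = score_distributions
    table.attrs["ave_n"] = grid.ave_n
    return table
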