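"""Virtual-screening orchestration.

A screen is driven by a *control file* (plain ``key = value`` text) that
names the ligand library, its chemical format, the docking scenarios to run
and the worker count.  Every ligand in a hierarchical library
(meta-tranche / tranche / collection) is docked under every scenario;
per-scenario scores are combined into a consensus (arithmetic mean) and the
ranking is written as CSV.  Output files are partitioned into *result* and
*log* trees by filename patterns.  Ligands stored as PDBQT are converted to
MOL2 on the fly during traversal.
"""

from __future__ import annotations

import hashlib
import re
import tarfile
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .aco_engine import run_aco
from .config import DockingScenario, parse_scenario_config
from .conformation import apply_pose, build_dof_spec
from .errors import ConfigurationError, DomainError
from .ligand_io import (Molecule, assign_tripos_types, convert_pdbqt_to_mol2,
                        perceive_bonds, read_mol2, read_pdbqt, write_mol2)

__all__ = [
    "ControlFile",
    "LibraryHierarchy",
    "RankingEntry",
    "ScreenResult",
    "parse_control_file",
    "iterate_library",
    "library_size",
    "run_screen",
    "consensus_score",
    "classify_output_file",
    "top_n_average",
    "LOG_FILE_PATTERNS",
]

LIGAND_FORMATS = ("PDBQT", "MOL2")

#: Filename patterns marking log (as opposed to result) output files.
LOG_FILE_PATTERNS = (
    r".*log",
    r".*constraints.*",
    r".*correspondingNames.*",
    r".*descent.*",
    r".*optimizer.*",
    r".*plantsconfig.*",
    r".*skippedligands.*",
)
_LOG_RES = [re.compile(p) for p in LOG_FILE_PATTERNS]


@dataclass(frozen=True)
class LibraryHierarchy:
    """Level counts of a hierarchical screening library."""

    n_meta_tranches: int
    n_tranches_per_meta: int
    n_collections_per_tranche: int
    n_compounds_per_collection: int

    def __post_init__(self) -> None:
        for v in (self.n_meta_tranches, self.n_tranches_per_meta,
                  self.n_collections_per_tranche, self.n_compounds_per_collection):
            if v < 1:
                raise ConfigurationError("hierarchy level counts must be >= 1")


def library_size(h: LibraryHierarchy) -> int:
    """Total compound count: the product of the four level counts."""
    return (h.n_meta_tranches * h.n_tranches_per_meta
            * h.n_collections_per_tranche * h.n_compounds_per_collection)


@dataclass
class ControlFile:
    ligand_library_format: str
    scenarios: list[DockingScenario]
    library_root: Path
    output_root: Path
    workers: int = 1
    use_local_scratch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ligand_library_format not in LIGAND_FORMATS:
            raise ConfigurationError(
                f"ligand_library_format must be one of {LIGAND_FORMATS}, "
                f"got {self.ligand_library_format!r}")
        if not self.scenarios:
            raise ConfigurationError("a control file needs at least one scenario")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ConfigurationError("docking scenario names must be unique")


@dataclass
class RankingEntry:
    ligand_id: str
    per_scenario_scores: dict[str, float]
    dock_time: float = 0.0

    @property
    def consensus(self) -> float:
        return consensus_score(list(self.per_scenario_scores.values()))


def parse_control_file(text: str, base_dir: str | Path = ".") -> ControlFile:
    """Parse a ``key = value`` control file into a :class:`ControlFile`.

    Required keys: ``ligand_library_format``, ``docking_scenario_names``,
    ``library_root``, ``output_root``.  Scenario configuration is read from
    ``{input_files_root}/{scenario name}/config.txt``.  Unknown keys warn and
    are ignored; ``#`` starts a comment.
    """
    base_dir = Path(base_dir)
    known = {"ligand_library_format", "docking_scenario_names",
             "docking_scenario_programs", "library_root", "output_root",
             "input_files_root", "workers", "use_local_scratch", "seed"}
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        if key not in known:
            warnings.warn(f"line {lineno}: unknown control-file key {key!r} ignored")
            continue
        values[key] = value.strip()

    for required in ("ligand_library_format", "docking_scenario_names",
                     "library_root", "output_root"):
        if required not in values:
            raise ConfigurationError(f"missing required control-file key {required!r}")

    fmt = values["ligand_library_format"]
    if fmt not in LIGAND_FORMATS:
        raise ConfigurationError(
            f"ligand_library_format must be one of {LIGAND_FORMATS}, got {fmt!r}")

    input_root = base_dir / values.get("input_files_root", "input-files")
    scenarios = []
    for name in values["docking_scenario_names"].replace(",", " ").split():
        config_path = input_root / name / "config.txt"
        if not config_path.exists():
            raise ConfigurationError(
                f"scenario {name!r}: missing config file {config_path}")
        scenario = parse_scenario_config(config_path.read_text(), name=name)
        scenario.config_path = str(config_path)
        if scenario.receptor_file:
            receptor_path = Path(scenario.receptor_file)
            if not receptor_path.is_absolute():
                scenario.receptor_file = str(base_dir / receptor_path)
        scenarios.append(scenario)

    return ControlFile(
        ligand_library_format=fmt,
        scenarios=scenarios,
        library_root=base_dir / values["library_root"],
        output_root=base_dir / values["output_root"],
        workers=int(values.get("workers", "1")),
        use_local_scratch=values.get("use_local_scratch", "false").lower()
        in ("1", "true", "yes", "on"),
        seed=int(values.get("seed", "0")),
    )


# ---------------------------------------------------------------------------
# Library traversal
# ---------------------------------------------------------------------------

def _parse_ligand(text: str, fmt: str, name: str) -> Molecule:
    if fmt == "MOL2":
        mol = read_mol2(text)
    else:
        mol = read_mol2(convert_pdbqt_to_mol2(text))
    mol.name = name
    return mol


def iterate_library(root: str | Path, h: Optional[LibraryHierarchy] = None,
                    fmt: str = "MOL2",
                    timings: Optional[dict[str, float]] = None,
                    on_error=None) -> Iterator[tuple[str, Molecule]]:
    """Yield ``(ligand_id, Molecule)`` for every compound in a library tree.

    Traversal is lexicographic over meta-tranche directories, tranche
    directories and collections (tar archives or plain directories), so the
    order is deterministic.  When ``fmt`` is ``"PDBQT"`` each ligand is
    converted to MOL2 on the fly (per-ligand conversion seconds are recorded
    in ``timings`` when given).  Unreadable ligands or collections are
    skipped; ``on_error(ligand_id, exception)`` is called for each.
    """
    if fmt not in LIGAND_FORMATS:
        raise ConfigurationError(f"unknown ligand library format {fmt!r}")
    root = Path(root)
    suffix = ".mol2" if fmt == "MOL2" else ".pdbqt"
    for meta in sorted(p for p in root.iterdir() if p.is_dir()):
        for tranche in sorted(p for p in meta.iterdir() if p.is_dir()):
            for coll in sorted(tranche.iterdir()):
                prefix = f"{meta.name}_{tranche.name}"
                try:
                    members = _collection_members(coll, suffix)
                except Exception as exc:  # unreadable collection
                    if on_error is not None:
                        on_error(f"{prefix}_{coll.name}", exc)
                    continue
                for member_name, text in members:
                    ligand_id = f"{prefix}_{coll.stem}_{Path(member_name).stem}"
                    start = time.perf_counter()
                    try:
                        mol = _parse_ligand(text, fmt, ligand_id)
                    except Exception as exc:
                        if on_error is not None:
                            on_error(ligand_id, exc)
                        continue
                    if timings is not None:
                        timings[ligand_id] = time.perf_counter() - start
                    yield ligand_id, mol


def _collection_members(coll: Path, suffix: str) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    if coll.is_dir():
        for f in sorted(coll.iterdir()):
            if f.suffix == suffix:
                out.append((f.name, f.read_text()))
    elif coll.suffixes and coll.suffixes[-1] == ".tar":
        with tarfile.open(coll, "r") as tar:
            for member in sorted(tar.getmembers(), key=lambda m: m.name):
                if member.isfile() and member.name.endswith(suffix):
                    fh = tar.extractfile(member)
                    assert fh is not None
                    out.append((member.name, fh.read().decode()))
    return out


# ---------------------------------------------------------------------------
# Scoring aggregation
# ---------------------------------------------------------------------------

def consensus_score(scores: Sequence[float]) -> float:
    """Arithmetic mean of per-scenario docking scores."""
    if len(scores) == 0:
        raise DomainError("cannot form a consensus of zero scores")
    return float(np.mean(np.asarray(scores, dtype=float)))


def classify_output_file(filename: str) -> str:
    """``"log"`` if the filename matches any log pattern, else ``"result"``."""
    if not filename:
        raise DomainError("empty filename")
    name = Path(filename).name
    for regex in _LOG_RES:
        if regex.search(name):
            return "log"
    return "result"


def top_n_average(ranking: pd.DataFrame, n: int,
                  column: str = "consensus") -> float:
    """Mean of the ``n`` most negative scores in the ranking (AVE_N).

    Falls back to the mean of all entries (with a warning) when the table
    holds fewer than ``n``.
    """
    if ranking.empty:
        raise DomainError("ranking table is empty")
    if n < 1:
        raise DomainError("n must be >= 1")
    scores = ranking[column].to_numpy(dtype=float)
    if len(scores) < n:
        warnings.warn(f"ranking holds {len(scores)} entries < n={n}; "
                      "averaging all of them")
        n = len(scores)
    return float(np.sort(scores)[:n].mean())


# ---------------------------------------------------------------------------
# Screen execution
# ---------------------------------------------------------------------------

def _ligand_seed(global_seed: int, ligand_id: str, scenario_name: str) -> int:
    """Stable per-(ligand, scenario) seed, independent of traversal order
    and worker scheduling."""
    digest = hashlib.sha256(
        f"{global_seed}|{ligand_id}|{scenario_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class ScreenResult:
    ranking: pd.DataFrame
    failed: list[tuple[str, str]]
    results_dir: Path
    logs_dir: Path
    conversion_times: dict[str, float] = field(default_factory=dict)
    dock_times: dict[str, float] = field(default_factory=dict)


def _dock_one(receptors: dict[str, Molecule], scenarios: list[DockingScenario],
              global_seed: int, ligand_id: str, ligand: Molecule):
    scores: dict[str, float] = {}
    poses: dict[str, np.ndarray] = {}
    start = time.perf_counter()
    for scenario in scenarios:
        seed = _ligand_seed(global_seed, ligand_id, scenario.name)
        result = run_aco(receptors[scenario.name], ligand, scenario, seed=seed)
        scores[scenario.name] = result.best.f_s
        poses[scenario.name] = apply_pose(
            ligand, result.best.s, scenario.sphere, result.spec)
    return ligand_id, scores, poses, time.perf_counter() - start


def run_screen(cf: ControlFile, write_poses: bool = True) -> ScreenResult:
    """Dock every library ligand under every scenario of the control file.

    Produces ``ranking.csv`` (plus optional pose MOL2 files) in the result
    tree and a screen log / skipped-ligand list in the log tree.  Per-ligand
    seeds are derived from the control-file seed and the ligand id, so the
    ranking is identical for any worker count.  A failing ligand is logged
    and skipped; a missing scenario config or receptor aborts the screen
    before any docking.
    """
    receptors: dict[str, Molecule] = {}
    for scenario in cf.scenarios:
        if not scenario.receptor_file:
            raise ConfigurationError(
                f"scenario {scenario.name!r} does not name a protein_file")
        path = Path(scenario.receptor_file)
        if not path.exists():
            raise ConfigurationError(
                f"scenario {scenario.name!r}: receptor file {path} not found")
        receptors[scenario.name] = read_mol2(path.read_text())

    results_dir = Path(cf.output_root) / "results"
    logs_dir = Path(cf.output_root) / "logs"
    results_dir.mkdir(parents=True, exist_ok=True)
    logs_dir.mkdir(parents=True, exist_ok=True)

    failed: list[tuple[str, str]] = []
    conversion_times: dict[str, float] = {}
    ligands = list(iterate_library(
        cf.library_root, fmt=cf.ligand_library_format,
        timings=conversion_times,
        on_error=lambda lid, exc: failed.append((lid, str(exc)))))

    jobs = Parallel(n_jobs=max(cf.workers, 1), prefer="threads")(
        delayed(_dock_one)(receptors, cf.scenarios, cf.seed, lid, mol)
        for lid, mol in ligands)

    entries: list[RankingEntry] = []
    dock_times: dict[str, float] = {}
    pose_rows = []
    for ligand_id, scores, poses, elapsed in jobs:
        entries.append(RankingEntry(ligand_id=ligand_id,
                                    per_scenario_scores=scores,
                                    dock_time=elapsed))
        dock_times[ligand_id] = elapsed
        pose_rows.append((ligand_id, poses))

    scenario_names = [s.name for s in cf.scenarios]
    table = pd.DataFrame(
        [{"ligand_id": e.ligand_id,
          **{name: e.per_scenario_scores[name] for name in scenario_names},
          "consensus": e.consensus}
         for e in entries])
    if not table.empty:
        table = table.sort_values(["consensus", "ligand_id"],
                                  kind="mergesort").reset_index(drop=True)

    # ranking.csv holds only seed-determined quantities so identical seeds
    # give identical bytes regardless of worker count; wall times go to a
    # companion file.
    ranking_path = results_dir / "ranking.csv"
    table.to_csv(ranking_path, index=False)
    pd.DataFrame(sorted(dock_times.items()),
                 columns=["ligand_id", "dock_time_s"]).to_csv(
        results_dir / "dock_times.csv", index=False)

    if write_poses:
        ligand_by_id = dict(ligands)
        for ligand_id, poses in pose_rows:
            mol = ligand_by_id[ligand_id]
            for scenario_name, coords in poses.items():
                posed = mol.with_coords(coords)
                posed.name = f"{ligand_id}_{scenario_name}"
                out = results_dir / f"{ligand_id}_{scenario_name}_pose.mol2"
                out.write_text(write_mol2(posed))

    (logs_dir / "screen.log").write_text(
        "\n".join([f"ligands docked: {len(entries)}",
                   f"ligands failed: {len(failed)}",
                   f"scenarios: {', '.join(scenario_names)}",
                   f"workers: {cf.workers}"]) + "\n")
    (logs_dir / "skippedligands.txt").write_text(
        "".join(f"{lid}\t{reason}\n" for lid, reason in failed))
    for scenario in cf.scenarios:
        if scenario.config_path:
            copy = logs_dir / f"{scenario.name}_plantsconfig.txt"
            copy.write_text(Path(scenario.config_path).read_text())

    return ScreenResult(ranking=table, failed=failed,
                        results_dir=results_dir, logs_dir=logs_dir,
                        conversion_times=conversion_times,
                        dock_times=dock_times)
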