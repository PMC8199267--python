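"""Ant-colony optimizer over discretized pose degrees of freedom.

Each degree of freedom ``i`` carries a pheromone level ``tau_il`` per
partition interval ``l``.  An ant builds a pose by choosing, independently
per dof, interval ``l`` with probability ``tau_il / sum_k tau_ik`` and drawing
a continuous value inside the chosen interval; the pose is then refined by
Nelder–Mead simplex local search.  After each iteration every pheromone
evaporates by the factor ``(1 - rho)`` and the iteration-best refined
solution ``s`` deposits ``|f(s)|`` (if its score is negative) on a small
neighborhood of intervals around each of its components.  Pheromones are
clamped between running MAX-MIN bounds so no interval's selection probability
ever collapses to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .conformation import DofSpec, Partition, assign_interval, build_dof_spec
from .errors import ConfigurationError, DomainError
from .ligand_io import Molecule
from .scoring import PoseScorer

__all__ = [
    "ACOParams",
    "AntSolution",
    "ACOResult",
    "PheromoneMatrix",
    "init_pheromones",
    "select_interval",
    "sample_ant",
    "local_search",
    "deposit_indicator",
    "update_pheromones",
    "resolve_defaults",
    "optimize",
    "run_aco",
    "DEFAULTS_TABLE",
]

#: Colony defaults per (scoring_function, search_speed): (ants, evap, sigma).
DEFAULTS_TABLE: dict[tuple[str, int], tuple[int, float, float]] = {
    ("chemplp", 4): (20, 0.15, 0.25),
    ("chemplp", 2): (20, 0.20, 0.5),
    ("chemplp", 1): (20, 0.20, 1.25),
    ("plp", 4): (20, 0.2, 0.5),
    ("plp95", 4): (20, 0.2, 1.25),
}


@dataclass
class ACOParams:
    n_ants: int
    rho: float
    sigma: float
    search_speed: int = 4
    iterations: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError("evaporation rate rho must lie in [0, 1]")
        if self.n_ants < 1:
            raise ConfigurationError("need at least one ant")
        if self.iterations < 1:
            raise ConfigurationError("need at least one iteration")


@dataclass
class AntSolution:
    """A sampled pose ``x``, its locally refined version ``s`` and the score
    of the refined pose (never worse than the sampled one)."""

    x: np.ndarray
    s: np.ndarray
    f_s: float


@dataclass
class ACOResult:
    best: AntSolution
    trace: list[float]
    n_evaluations: int
    spec: DofSpec
    iterations_run: int


class PheromoneMatrix:
    """Pheromone levels ``tau[i][l]`` with per-dof MAX-MIN clamping bounds."""

    def __init__(self, spec: DofSpec, tau0: float = 1.0):
        self.spec = spec
        self.tau: list[np.ndarray] = [
            np.full(p.n_intervals, tau0, dtype=float) for p in spec.partitions]
        self.tau_max: np.ndarray = np.full(spec.n, tau0, dtype=float)
        self.tau_min: np.ndarray = np.array(
            [tau0 / (2.0 * p.n_intervals) for p in spec.partitions])
        self.t = 0
        self._best_deposit = 0.0

    def probabilities(self, i: int) -> np.ndarray:
        row = self.tau[i]
        return row / row.sum()

    def clamp(self) -> None:
        for i, row in enumerate(self.tau):
            np.clip(row, self.tau_min[i], self.tau_max[i], out=row)


def init_pheromones(spec: DofSpec, tau0: float = 1.0) -> PheromoneMatrix:
    """Uniform initial trails at an optimistic constant ``tau0`` (which also
    seeds the MAX-MIN bounds), so initial selection is uniform per dof."""
    return PheromoneMatrix(spec, tau0=tau0)


def select_interval(tau_row: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a 1-based interval index with probability proportional to its
    pheromone level."""
    tau_row = np.asarray(tau_row, dtype=float)
    total = tau_row.sum()
    if total <= 0 or not np.isfinite(total):
        raise DomainError("pheromone row has no positive mass")
    return int(rng.choice(len(tau_row), p=tau_row / total)) + 1


def sample_ant(ph: PheromoneMatrix, spec: DofSpec, rng: np.random.Generator,
               representative: Optional[str] = None) -> np.ndarray:
    """Sample one pose: per dof, pheromone-proportional interval choice, then
    a uniform draw within that interval.

    ``representative="midpoint"`` evaluates the interval midpoint instead of
    a uniform draw — the pure-discrete mode used when local search is off,
    which makes the search grid identical to the exhaustive-grid oracle's.
    """
    if len(ph.tau) != spec.n:
        raise DomainError("pheromone matrix / dof spec dimension mismatch")
    out = np.empty(spec.n)
    for i, partition in enumerate(spec.partitions):
        ell = select_interval(ph.tau[i], rng)
        if representative == "midpoint":
            out[i] = partition.midpoint(ell)
        else:
            out[i] = rng.uniform(partition.lower(ell), partition.upper(ell))
    return out


def local_search(x: np.ndarray, f: Callable[[np.ndarray], float],
                 sigma: float, spec: DofSpec,
                 budget: Optional[int] = None) -> AntSolution:
    """Nelder–Mead refinement of a sampled pose.

    The initial simplex displaces each dof by ``sigma * (b_i - a_i) / n_i``
    (one interval width scaled by sigma).  Rotational components are wrapped
    modulo 360 and the rest clipped into bounds before every evaluation, so
    the returned solution respects the box and never scores worse than the
    start point.
    """
    x = spec.wrap_clip(np.asarray(x, dtype=float))
    n = spec.n
    if budget is None:
        budget = 20 * (n + 1)
    budget = max(budget, n + 2)

    best = {"x": x.copy(), "f": None}

    def wrapped(y: np.ndarray) -> float:
        y = spec.wrap_clip(y)
        val = f(y)
        if best["f"] is None or val < best["f"]:
            best["f"] = val
            best["x"] = y.copy()
        return val

    f0 = wrapped(x)
    simplex = np.tile(x, (n + 1, 1))
    for i in range(n):
        a, b = spec.bounds[i]
        step = sigma * (b - a) / spec.partitions[i].n_intervals
        simplex[i + 1, i] += step if step > 0 else 1e-3
    minimize(wrapped, x, method="Nelder-Mead",
             options={"initial_simplex": simplex, "maxfev": budget,
                      "xatol": 1e-4, "fatol": 1e-6})
    s = spec.wrap_clip(best["x"])
    f_s = best["f"] if best["f"] is not None else f0
    return AntSolution(x=x, s=s, f_s=float(f_s))


def deposit_indicator(ell: int, s_component: float, p: Partition,
                      rotational: bool) -> int:
    """Neighborhood indicator for the pheromone deposit.

    Interval ``ell`` receives a deposit when the refined component falls in
    the boundary window ``[z_{ell-3}, z_{ell+2}]`` for rotational dofs
    (wrapping at 0/360; intervals ell-2 .. ell+2) or ``[z_{ell-2}, z_{ell+1}]``
    for non-rotational dofs (clipped at the box; intervals ell-1 .. ell+1).
    """
    if not 1 <= ell <= p.n_intervals:
        raise DomainError(f"interval index {ell} outside 1..{p.n_intervals}")
    try:
        m = assign_interval(s_component, p)
    except DomainError:
        return 0
    n = p.n_intervals
    if rotational:
        offset = (m - ell) % n
        return int(offset <= 2 or offset >= n - 2)
    return int(abs(m - ell) <= 1)


def update_pheromones(ph: PheromoneMatrix, best: AntSolution,
                      params: ACOParams) -> PheromoneMatrix:
    """One pheromone update from the iteration-best ant (in place).

    Every trail evaporates by ``(1 - rho)``; if the refined score is negative
    its magnitude is deposited on each indicator-selected interval of every
    dof.  The MAX-MIN bounds are then refreshed from the best deposit seen so
    far (``tau_max = deposit / rho``, ``tau_min = tau_max / (2 n_i)``) and all
    trails clamped into them.
    """
    rho = params.rho
    dtau = abs(best.f_s) if best.f_s < 0 else 0.0
    spec = ph.spec
    for i, partition in enumerate(spec.partitions):
        ph.tau[i] *= (1.0 - rho)
        if dtau > 0:
            s_i = float(best.s[i])
            for ell in range(1, partition.n_intervals + 1):
                if deposit_indicator(ell, s_i, partition, spec.rotational[i]):
                    ph.tau[i][ell - 1] += dtau
    if dtau > ph._best_deposit:
        ph._best_deposit = dtau
    if rho > 0 and ph._best_deposit > 0:
        ph.tau_max[:] = ph._best_deposit / rho
        ph.tau_min[:] = [ph.tau_max[i] / (2.0 * p.n_intervals)
                         for i, p in enumerate(spec.partitions)]
    ph.clamp()
    ph.t += 1
    return ph


def resolve_defaults(scoring_function: str, search_speed: int,
                     base_iterations: int = 100, seed: int = 0) -> ACOParams:
    """Colony defaults for a (scoring function, search speed) combination.

    aco_ants is 20 throughout; evaporation and simplex scale depend on the
    combination.  The iteration budget is ``ceil(base_iterations /
    search_speed)`` so higher speeds spend proportionally fewer evaluations.
    Unknown combinations raise a configuration error.
    """
    key = (scoring_function, search_speed)
    if key not in DEFAULTS_TABLE:
        raise ConfigurationError(
            f"no defaults for scoring_function={scoring_function!r} "
            f"search_speed={search_speed}; known: {sorted(DEFAULTS_TABLE)}")
    ants, rho, sigma = DEFAULTS_TABLE[key]
    iterations = math.ceil(base_iterations / search_speed)
    return ACOParams(n_ants=ants, rho=rho, sigma=sigma,
                     search_speed=search_speed, iterations=iterations,
                     seed=seed)


# ---------------------------------------------------------------------------
# Main loops
# ---------------------------------------------------------------------------

def optimize(objective: Callable[[np.ndarray], float], spec: DofSpec,
             params: ACOParams, use_local_search: bool = True,
             local_search_budget: Optional[int] = None,
             stagnation_limit: Optional[int] = 15,
             restart_after: Optional[int] = None) -> ACOResult:
    """Colony optimization of an arbitrary objective over a dof spec.

    Per iteration: sample ``n_ants`` poses from the pheromone distribution,
    refine each (or evaluate interval midpoints when local search is off),
    then update trails with the iteration-best refined solution.  The search
    stops early after ``stagnation_limit`` iterations without improvement of
    the global best.  ``restart_after`` instead reinitializes the trails to a
    uniform optimistic level after that many stagnant iterations (the
    MAX-MIN-style escape from premature convergence; the global best is
    kept).  Fully reproducible from ``params.seed``: per-ant RNG substreams
    are derived from (seed, iteration, ant).
    """
    for a, b in spec.bounds:
        if not b > a:
            raise ConfigurationError("zero-volume search box")
    evaluations = {"n": 0}

    def counted(x: np.ndarray) -> float:
        evaluations["n"] += 1
        return float(objective(x))

    ph = init_pheromones(spec)
    global_best: Optional[AntSolution] = None
    trace: list[float] = []
    stagnant = 0
    iterations_run = 0
    for t in range(params.iterations):
        iteration_best: Optional[AntSolution] = None
        for a in range(params.n_ants):
            rng = np.random.default_rng((params.seed, t, a))
            if use_local_search:
                x = sample_ant(ph, spec, rng)
                sol = local_search(x, counted, params.sigma, spec,
                                   budget=local_search_budget)
            else:
                x = sample_ant(ph, spec, rng, representative="midpoint")
                sol = AntSolution(x=x, s=x.copy(), f_s=counted(x))
            if iteration_best is None or sol.f_s < iteration_best.f_s:
                iteration_best = sol
        assert iteration_best is not None
        improved = global_best is None or iteration_best.f_s < global_best.f_s
        if improved:
            global_best = iteration_best
            stagnant = 0
        else:
            stagnant += 1
        update_pheromones(ph, iteration_best, params)
        trace.append(global_best.f_s)
        iterations_run = t + 1
        if restart_after is not None and stagnant >= restart_after:
            level = float(ph.tau_max.max())
            for row in ph.tau:
                row[:] = level
            stagnant = 0
        elif stagnation_limit is not None and stagnant >= stagnation_limit:
            break
    assert global_best is not None
    return ACOResult(best=global_best, trace=trace,
                     n_evaluations=evaluations["n"], spec=spec,
                     iterations_run=iterations_run)


def run_aco(receptor: Molecule, ligand: Molecule, scenario,
            seed: Optional[int] = None) -> ACOResult:
    """Dock one ligand under a scenario and return the best refined pose.

    Resolves colony defaults from the scenario's scoring function and search
    speed (explicit scenario settings win), builds the dof spec for this
    ligand inside the scenario's binding sphere, and runs the colony over the
    pose score.
    """
    defaults = resolve_defaults(scenario.scoring_function,
                                scenario.search_speed,
                                base_iterations=scenario.base_iterations)
    params = ACOParams(
        n_ants=scenario.n_ants if scenario.n_ants is not None else defaults.n_ants,
        rho=scenario.rho if scenario.rho is not None else defaults.rho,
        sigma=scenario.sigma if scenario.sigma is not None else defaults.sigma,
        search_speed=scenario.search_speed,
        iterations=defaults.iterations,
        seed=seed if seed is not None else (scenario.seed or 0),
    )
    spec = build_dof_spec(ligand, scenario.sphere,
                          angular_step=scenario.angular_step,
                          linear_step=scenario.linear_step)
    scorer = PoseScorer(receptor, ligand, scenario.resolved_scoring_params(),
                        scenario.sphere, spec)
    return optimize(scorer, spec, params,
                    use_local_search=scenario.local_search,
                    local_search_budget=scenario.local_search_budget,
                    stagnation_limit=scenario.stagnation_limit,
                    restart_after=getattr(scenario, "restart_after", None))
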