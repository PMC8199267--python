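"""Docking-scenario configuration: data model and config.txt parsing.

A docking scenario is one fully specified way of docking a ligand: a scoring
function, a binding sphere, the colony parameters (number of ants,
evaporation rate, simplex scale, search speed) and discretization steps.
Scenarios are written as plain ``keyword value`` text files::

    scoring_function chemplp
    search_speed 4
    bindingsite_center 17.0 66.0 31.0
    bindingsite_radius 13.0

Unset colony parameters are filled in from the per-scoring-function defaults
table when the scenario is resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .conformation import DockingSphere
from .errors import ConfigurationError
from .scoring import SCORING_FUNCTIONS, ScoringParams, scoring_params

__all__ = ["DockingScenario", "parse_scenario_config"]


@dataclass
class DockingScenario:
    """One docking scenario; unresolved colony parameters are ``None`` until
    :func:`antdock.aco_engine.resolve_defaults` fills them in."""

    name: str
    scoring_function: str
    sphere: DockingSphere
    search_speed: int = 4
    n_ants: Optional[int] = None
    rho: Optional[float] = None
    sigma: Optional[float] = None
    base_iterations: int = 100
    stagnation_limit: Optional[int] = 15
    restart_after: Optional[int] = None
    local_search: bool = True
    local_search_budget: Optional[int] = None
    angular_step: float = 45.0
    linear_step: float = 2.0
    seed: Optional[int] = None
    scoring_overrides: dict = field(default_factory=dict)
    output_dir: Optional[str] = None
    receptor_file: Optional[str] = None
    config_path: Optional[str] = None
    dof_spec = None  # populated per ligand by the engine

    def __post_init__(self) -> None:
        if self.scoring_function not in SCORING_FUNCTIONS:
            raise ConfigurationError(
                f"scenario {self.name!r}: unknown scoring_function "
                f"{self.scoring_function!r}")
        if self.search_speed not in (1, 2, 4):
            raise ConfigurationError(
                f"scenario {self.name!r}: search_speed must be 1, 2 or 4")

    def resolved_scoring_params(self) -> ScoringParams:
        return scoring_params(self.scoring_function, self.scoring_overrides or None)


_SCENARIO_KEYS = {
    "scoring_function", "search_speed", "aco_ants", "aco_evap", "aco_sigma",
    "aco_iterations", "bindingsite_center", "bindingsite_radius",
    "angular_step", "linear_step", "output_dir", "protein_file",
    "local_search", "local_search_budget", "stagnation_limit",
}


def parse_scenario_config(text: str, name: str = "scenario") -> DockingScenario:
    """Parse a keyword-value ``config.txt`` into a :class:`DockingScenario`.

    Lines are ``keyword value...``; ``#`` starts a comment; unknown keywords
    produce a warning comment in the returned scenario, not an error.
    """
    import warnings

    values: dict[str, list[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        key = parts[0].lower()
        if key not in _SCENARIO_KEYS:
            warnings.warn(f"line {lineno}: unknown scenario keyword {key!r} ignored")
            continue
        values[key] = parts[1:]

    def _one(key: str, default=None):
        if key not in values:
            return default
        if len(values[key]) != 1:
            raise ConfigurationError(f"keyword {key!r} expects a single value")
        return values[key][0]

    if "scoring_function" not in values:
        raise ConfigurationError("missing required keyword 'scoring_function'")
    if "bindingsite_center" not in values:
        raise ConfigurationError("missing required keyword 'bindingsite_center'")
    center_tokens = values["bindingsite_center"]
    if len(center_tokens) != 3:
        raise ConfigurationError("bindingsite_center expects three coordinates")
    try:
        center = tuple(float(v) for v in center_tokens)
        radius = float(_one("bindingsite_radius", "13.0"))
    except ValueError as exc:
        raise ConfigurationError(f"bad binding-site geometry: {exc}") from exc

    def _opt(key, cast, default=None):
        v = _one(key)
        return default if v is None else cast(v)

    local_search = _one("local_search", "1") not in ("0", "false", "off", "no")
    return DockingScenario(
        name=name,
        scoring_function=_one("scoring_function"),
        sphere=DockingSphere(center=center, radius=radius),
        search_speed=_opt("search_speed", int, 4),
        n_ants=_opt("aco_ants", int),
        rho=_opt("aco_evap", float),
        sigma=_opt("aco_sigma", float),
        base_iterations=_opt("aco_iterations", int, 100),
        stagnation_limit=_opt("stagnation_limit", int, 15),
        local_search=local_search,
        local_search_budget=_opt("local_search_budget", int),
        angular_step=_opt("angular_step", float, 45.0),
        linear_step=_opt("linear_step", float, 2.0),
        output_dir=_one("output_dir"),
        receptor_file=_one("protein_file"),
    )
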