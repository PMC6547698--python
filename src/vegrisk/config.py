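"""Run configuration: the constants of the analysis plus input locations.

A run is configured either by real input paths (occurrence CSV, climate
grids, vegetation map, name lookups) or by a synthetic
:class:`~vegrisk.synthetic.ScenarioConfig` — exactly one of the two.  The
fixed constants of the method live here with their defaults: percentile
levels 98/2, completeness threshold 0.7, 1000 null draws, z threshold
1.96, alpha 0.05, proportional MAP-reduction fractions {0.1, 0.5}, and a
100-km coarse cell edge.  Configs round-trip through YAML so every run is
self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .niche import PERCENTILE_RULE
from .synthetic import ScenarioConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # exactly one of the two input modes
    scenario: ScenarioConfig | None = None
    occurrences_path: str | None = None
    current_mat_path: str | None = None
    current_map_path: str | None = None
    future_mat_paths: list[str] = field(default_factory=list)
    future_map_paths: list[str] = field(default_factory=list)
    veg_map_path: str | None = None
    accepted_names_path: str | None = None
    exotic_names_path: str | None = None

    # method constants
    upper_pct: float = 98.0
    lower_pct: float = 2.0
    min_records: int = 1
    completeness_threshold: float = 0.7
    n_draws: int = 1000
    z_threshold: float = 1.96
    alpha: float = 0.05
    proportional_fractions: tuple[float, ...] = (0.1, 0.5)
    coarse_edge: float = 100.0
    min_land_fraction: float = 0.01
    pool_constraint: str = "compatible"
    excluded_veg_codes: tuple[int, ...] = ()
    seed: int = 0
    output_dir: str | None = None
    percentile_rule: str = PERCENTILE_RULE  # metadata: recorded, not tunable

    def validate(self) -> None:
        synthetic = self.scenario is not None
        real = self.occurrences_path is not None
        if synthetic == real:
            raise ValueError(
                "exactly one of a synthetic scenario or real input paths must be set"
            )
        if not (0 < self.lower_pct < self.upper_pct < 100):
            raise ValueError("percentile levels must satisfy 0 < lower < upper < 100")
        if not (0 < self.completeness_threshold <= 1):
            raise ValueError("completeness threshold must lie in (0, 1]")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.z_threshold <= 0 or not (0 < self.alpha < 1):
            raise ValueError("z threshold must be positive and alpha in (0, 1)")
        for f in self.proportional_fractions:
            if not (0 <= f <= 1):
                raise ValueError("proportional fractions must lie in [0, 1]")
        if self.coarse_edge <= 0:
            raise ValueError("coarse cell edge must be positive")
        if self.pool_constraint not in {"compatible", "literal"}:
            raise ValueError("pool_constraint must be 'compatible' or 'literal'")
        if synthetic:
            self.scenario.validate()


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    data = _to_plain(asdict(config))
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    scen = data.pop("scenario", None)
    cfg = RunConfig(**{k: v for k, v in data.items()
                       if k in {f.name for f in fields(RunConfig)}})
    if scen is not None:
        scen = {k: tuple(v) if isinstance(v, list) else v for k, v in scen.items()}
        cfg.scenario = ScenarioConfig(**scen)
    # YAML lists -> tuples where the dataclass expects them
    if isinstance(cfg.proportional_fractions, list):
        cfg.proportional_fractions = tuple(cfg.proportional_fractions)
    if isinstance(cfg.excluded_veg_codes, list):
        cfg.excluded_veg_codes = tuple(cfg.excluded_veg_codes)
    return cfg
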