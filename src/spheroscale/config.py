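"""Run configuration: schema, defaults, YAML/JSON loading.

Units at the configuration boundary: radii are given in μm (keys carry
the ``_um`` suffix) and converted to metres internally; everything else
is SI as declared in :class:`~spheroscale.params.KineticParams`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .params import (
    DEFAULT_Q2,
    LADDER_R_MAX,
    LADDER_R_MIN,
    LADDER_SIZE,
    KineticParams,
    hepatocyte_params,
    radius_ladder,
    stem_cell_params,
)

__all__ = ["RunConfig", "load_config", "DEFAULT_CELL_TYPES"]

DEFAULT_CELL_TYPES = {
    "stem": stem_cell_params,
    "hepatocyte": hepatocyte_params,
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    # size ladder
    ladder_r_min_um: float = LADDER_R_MIN * 1e6
    ladder_r_max_um: float = LADDER_R_MAX * 1e6
    ladder_size: int = LADDER_SIZE
    mean_radii_um: list[float] | None = None  # explicit ladder override

    # population
    q2: float = DEFAULT_Q2
    n_samples: int = 200
    n_samples_joint: int = 10_000
    seed: int = 1

    # kinetics
    cell_type: str = "stem"
    kinetics: dict = field(default_factory=dict)  # overrides for KineticParams

    # collapse settings
    n_bins: int = 30
    method: str = "distance"
    delta_grid: tuple[float, float, float] = (0.5, 1.3, 0.005)
    gamma_grid: tuple[float, float, float] = (0.8, 1.2, 0.01)
    joint_delta_grid: tuple[float, float, float] = (0.5, 1.3, 0.01)

    # thresholds
    ad_alpha: float = 0.05
    hz_alpha: float = 0.01
    joint_alpha: float = 0.01
    viability_phi_max: float = 10.0
    viability_rule: str = "mean"
    plateau_rel_tol: float = 0.10

    def __post_init__(self) -> None:
        if self.cell_type not in DEFAULT_CELL_TYPES and not self.kinetics:
            raise ValueError(
                f"unknown cell_type {self.cell_type!r} and no explicit kinetics given"
            )
        if self.n_samples < 1 or self.n_samples_joint < 1:
            raise ValueError("sample counts must be positive")
        if not 0 <= self.q2 < 1:
            raise ValueError("q2 must lie in [0, 1)")
        if self.method not in ("distance", "residual"):
            raise ValueError("method must be 'distance' or 'residual'")
        for name in ("ad_alpha", "hz_alpha", "joint_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    # -- derived objects ----------------------------------------------------

    def mean_radii(self) -> list[float]:
        """Ladder of mean radii in metres."""
        if self.mean_radii_um is not None:
            return [r * 1e-6 for r in self.mean_radii_um]
        return radius_ladder(
            self.ladder_r_min_um * 1e-6, self.ladder_r_max_um * 1e-6, self.ladder_size
        )

    def kinetic_params(self) -> KineticParams:
        if self.cell_type in DEFAULT_CELL_TYPES:
            return DEFAULT_CELL_TYPES[self.cell_type](**self.kinetics)
        return KineticParams(**self.kinetics)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("delta_grid", "gamma_grid", "joint_delta_grid"):
            d[key] = list(d[key])
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    for key in ("delta_grid", "gamma_grid", "joint_delta_grid"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
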