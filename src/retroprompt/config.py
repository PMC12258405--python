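"""Run configuration: a validated YAML-loadable model for planner runs."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .search import SearchConfig

STRATEGY_NAMES = ("standard", "route-ranking", "mo-search", "da", "da-mo")


class RunConfig(BaseModel):
    """Validated configuration for a planning or benchmark run."""

    library: Optional[str] = None
    stock: Optional[str] = None
    output: str = "routes.json"

    strategy: str = "standard"
    n_routes: int = Field(10, ge=1)

    target: Optional[str] = None
    break_bonds: list[tuple[int, int]] = Field(default_factory=list)
    freeze_bonds: list[tuple[int, int]] = Field(default_factory=list)

    max_depth: int = Field(6, ge=1)
    iteration_limit: int = Field(100, ge=1)
    time_limit: float = Field(300.0, gt=0)
    ucb_constant: float = Field(1.4, gt=0)
    expansion_k: int = Field(50, ge=1)
    beam: int = Field(5, ge=1)
    seed: int = 0

    @field_validator("strategy")
    @classmethod
    def _known_strategy(cls, value: str) -> str:
        if value not in STRATEGY_NAMES:
            raise ValueError(
                f"unknown strategy {value!r}; choose from {', '.join(STRATEGY_NAMES)}"
            )
        return value

    @model_validator(mode="after")
    def _break_needed(self) -> "RunConfig":
        if self.strategy != "standard" and not self.break_bonds:
            # tagged-SMILES targets may still carry the bonds; checked at run time
            pass
        return self

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    def search_config(self) -> SearchConfig:
        return SearchConfig(
            max_depth=self.max_depth,
            iteration_limit=self.iteration_limit,
            time_limit=self.time_limit,
            ucb_constant=self.ucb_constant,
            seed=self.seed,
            expansion_k=self.expansion_k,
            beam=self.beam,
        )
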