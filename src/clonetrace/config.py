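"""Run configuration: JSON schema for the composed pipeline.

The configuration is validated before any work starts; unknown keys are
rejected so typos fail loudly. Every design toggle (denominator
semantics, thresholds, quartile convention) lives here and is echoed
into the run log.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .capture import ConstructSpec
from .fate import OutputThresholds
from .simulate import DEFAULT_LINEAGES

__all__ = ["RunConfig", "load_run_config"]


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True, populate_by_name=True)

    construct_spec: ConstructSpec = Field(alias="construct")
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    hspc_label: str = "HSPC"
    lymphoid: tuple[str, ...] = ()
    myeloid: tuple[str, ...] = ()
    # output-class boundaries (strict inequalities)
    low_max: float = 0.4
    med_low: float = 0.8
    med_high: float = 1.2
    high_min: float = 2.0
    bias_threshold: float = 2.0
    min_clone_cells: int = 10
    max_mito_fraction: float = 0.10
    umi_fence: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.low_max <= self.med_low <= self.med_high <= self.high_min:
            raise ValueError("output thresholds must be ordered")
        groups = [*self.lymphoid, *self.myeloid]
        if groups:
            if sorted(groups) != sorted(self.lineages):
                raise ValueError(
                    "lymphoid + myeloid must partition the downstream lineages"
                )
        return self

    @property
    def construct(self) -> ConstructSpec:
        return self.construct_spec

    @property
    def thresholds(self) -> OutputThresholds:
        return OutputThresholds(
            low_max=self.low_max,
            med_low=self.med_low,
            med_high=self.med_high,
            high_min=self.high_min,
        )

    @property
    def groups(self) -> Optional[dict]:
        if not self.lymphoid:
            return None
        return {"lymphoid": list(self.lymphoid), "myeloid": list(self.myeloid)}


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))
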