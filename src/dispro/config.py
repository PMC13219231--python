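"""Validated run configuration for the command-line pipeline.

A run is fully described by a YAML file; the parsed and validated
config is echoed into the output directory so every output file can be
re-derived from the echo plus the input data.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from .case_processing import DEFAULT_WINDOW_START
from .vocabularies import SGLT2_INHIBITORS


class InputConfig(BaseModel):
    dialect: str = "faers"  # "faers" | "icsr"
    demo: str | None = None
    drug: str | None = None
    reac: str | None = None
    outc: str | None = None
    icsr: str | None = None

    @field_validator("dialect")
    @classmethod
    def _dialect(cls, v):
        if v not in {"faers", "icsr"}:
            raise ValueError("dialect must be 'faers' or 'icsr'")
        return v


class RunConfig(BaseModel):
    """Everything the `dispro run` pipeline needs."""

    input: InputConfig
    dictionary: str | None = None   # drug synonym CSV; package default if None
    event_list: str | None = None   # one term per line
    region_map: str | None = None
    window_start: date = DEFAULT_WINDOW_START
    drugs_of_interest: tuple[str, ...] = SGLT2_INHIBITORS
    role_filter: tuple[str, ...] = ("PS",)
    unit: str = "case"              # "case" | "version"
    mode: str = "lenient"           # parse mode; the library default is strict
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    correction_policy: str = "haldane_if_zero"
    ror_threshold: float = Field(default=2.0, gt=0.0)
    ci_low_threshold: float = Field(default=1.0, gt=0.0)
    bonferroni: bool = False
    trend_country: str | None = None  # e.g. "US" for a single-country trend

    @field_validator("unit")
    @classmethod
    def _unit(cls, v):
        if v not in {"case", "version"}:
            raise ValueError("unit must be 'case' or 'version'")
        return v

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in {"strict", "lenient"}:
            raise ValueError("mode must be 'strict' or 'lenient'")
        return v

    @field_validator("correction_policy")
    @classmethod
    def _policy(cls, v):
        if v not in {"none", "haldane_if_zero"}:
            raise ValueError("correction_policy must be 'none' or "
                             "'haldane_if_zero'")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            keys = ", ".join(".".join(str(p) for p in e["loc"])
                             for e in exc.errors())
            raise ValueError(f"invalid run config {Path(path).name}: "
                             f"bad key(s) {keys}") from exc

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
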