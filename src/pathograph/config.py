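"""Run configuration: defaults, TOML file loading, flag overrides."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .morphometrics import DEFAULT_FEATURE_SET


@dataclass
class RunConfig:
    overlap_threshold: float = 0.5
    feature_set: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURE_SET))
    dialect: str = "turtle"
    cumulative_definitions: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError(f"overlap_threshold must be in (0, 1], "
                             f"got {self.overlap_threshold}")
        if self.dialect not in ("turtle", "rdfxml"):
            raise ValueError(f"dialect must be turtle|rdfxml, got {self.dialect!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional TOML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data.update(tomllib.load(fh))
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
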