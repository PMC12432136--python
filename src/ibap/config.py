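"""Run configuration for the pipeline driver."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all seeds are recorded in the manifest."""

    out_dir: str = "ibap_out"
    measure: str = "CTh"
    # input paths; when morphometry is None the synthetic generator runs first
    morphometry: str | None = None
    expression: str | None = None
    marker_sets: str | None = None
    centroids: str | None = None
    # synthetic generator settings
    n_term: int = 300
    n_preterm: int = 150
    n_timepoints: int = 2
    # thresholds and replications
    lower_threshold: float = 0.05
    upper_threshold: float = 0.95
    n_spins: int = 1000
    n_boot_ci: int = 10_000
    n_boot_moderation: int = 5_000
    exclude_regions: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.lower_threshold < self.upper_threshold < 1.0):
            raise ValueError("need 0 < lower_threshold < upper_threshold < 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
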