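"""Pipeline configuration with YAML round-tripping.

Defaults reproduce the package's reference operating point: sigmoid slope 15
(50 on the toe channel), inflection 0.5, EMA smoothing coefficient 0.3,
linear-interpolation quantiles, 22 retained components, six folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of the gait-monitoring pipeline in one document."""

    # fuzzification
    slope: float = 15.0
    toe_slope: float = 50.0
    inflection: float = 0.5
    # acquisition
    filter_coefficient: float = 0.3
    quantile_method: str = "linear"
    # features / classifier
    feature_set: str = "mean-rms-domfreq"
    sequence_foot: str = "left"
    n_components: int = 22
    n_folds: int = 6
    # simulator
    cadence_spm: float = 100.0
    noise_sd: float = 0.05
    transition_ramp_ms: float = 60.0
    seed: int = 0
    # artifacts
    out_dir: str = "gaitmon_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        """Short stable hash stamped onto artifacts for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def membership_params(self):
        from .fuzzy import MembershipParams

        base = MembershipParams(self.inflection, self.slope)
        toe = MembershipParams(self.inflection, self.toe_slope)
        return {
            "fsr_heel": base,
            "fsr_5th": base,
            "fsr_1st": base,
            "fsr_toe": toe,
        }
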