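"""Run configuration: defaults, YAML round-trip, provenance echo."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .spectral_core import SpectralParams


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run.

    Defaults follow the method's conventions: scale a = 5, period b = 3,
    kernel length N = 1200, STFT window 180, calling threshold 0.2; the
    junction profile overrides N to 512 internally.
    """

    method: str = "mwt"  # "mwt" | "stft"
    N: int = 1200
    a: float = 5.0
    b: int = 3
    window: int = 180
    threshold: float = 0.2
    min_length: int = 50
    merge_gap: int = 30
    correct_6bp: str = "off"  # "subtract" | "flag" | "off"
    correct_9bp: bool = False
    normalize: bool = True
    seed: int = 0
    verbosity: int = 1

    @property
    def spectral_params(self) -> SpectralParams:
        return SpectralParams(N=self.N, a=self.a, b=self.b, window=self.window)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
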