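"""Pipeline configuration: every default equals the study's printed value.

535 trials/80 deviants per block with 5–11 standards between deviants;
1200 ms onset-to-onset; 1–20 Hz bandpass; 1800 ms epochs with an 800 ms
pre-stimulus baseline; ±300 µV screening then 100 µV / 75 µV trend / 5 SD
rules; MMN search window 100–250 ms post divergence; 100 ms amplitude
windows; 10,000 permutations judged at the 2.5th percentile per tail.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cluster import PermutationScheme
from .design import DesignParams
from .montage import DEFAULT_ADJACENCY_RAD
from .preprocess import RejectionRules
from .simulate import (
    ArtifactSpec,
    CohortJitter,
    EffectSpec,
    NoiseSpec,
    paper_pattern_effects,
)

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    design: DesignParams = field(default_factory=DesignParams)
    rotation_id: int = 1
    n_per_group: int = 20
    groups: tuple[str, ...] = ("control", "dissociation")

    effects_preset: str = "paper_pattern"   # 'paper_pattern' | 'none'
    strong_mmn_uv: float = -1.4
    weak_mmn_uv: float = -0.4
    p3a_uv: float = 1.2

    noise: NoiseSpec = field(default_factory=NoiseSpec)
    jitter: CohortJitter = field(default_factory=CohortJitter)

    bandpass_hz: tuple[float, float] = (1.0, 20.0)
    epoch_pre_ms: float = 800.0
    epoch_post_ms: float = 1000.0
    screening_uv: float = 300.0
    rejection: RejectionRules = field(default_factory=RejectionRules)

    mmn_window_ms: tuple[float, float] = (100.0, 250.0)
    amplitude_window_ms: float = 100.0
    measure_channel: str = "FCz"

    adjacency_rad: float = DEFAULT_ADJACENCY_RAD
    scheme: PermutationScheme = field(default_factory=PermutationScheme)
    cluster_crop_ms: tuple[float, float] | None = None  # relative to onset

    master_seed: int = 0
    out_dir: str = "tonemmn_out"

    def effects(self) -> EffectSpec:
        if self.effects_preset == "paper_pattern":
            return paper_pattern_effects(
                self.strong_mmn_uv, self.weak_mmn_uv, self.p3a_uv
            )
        if self.effects_preset == "none":
            return EffectSpec({})
        raise ValueError(f"unknown effects preset {self.effects_preset!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignParams(**d["design"])
        if "noise" in d:
            nd = dict(d["noise"])
            if "artifacts" in nd:
                nd["artifacts"] = ArtifactSpec(**nd["artifacts"])
            d["noise"] = NoiseSpec(**nd)
        if "jitter" in d:
            d["jitter"] = CohortJitter(**d["jitter"])
        if "rejection" in d:
            d["rejection"] = RejectionRules(**d["rejection"])
        if "scheme" in d:
            d["scheme"] = PermutationScheme(**d["scheme"])
        for key in ("bandpass_hz", "mmn_window_ms", "groups",
                    "cluster_crop_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False)
    )
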