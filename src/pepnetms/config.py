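"""End-to-end pipeline configuration.

Defaults equal the published workflow parameters wherever the source
workflow states them: networking at cosine 0.65 / more than 6 matched peaks
/ mutual top-10 with 0.02 Da fragment tolerance; MASST-style search with
+/-17 Da precursor exclusion, top-6 peaks per +/-50 Da window, 2.0 Da
precursor and 0.5 Da fragment tolerances, score above 0.2 with at least 3
matched peaks; MS1 feature matching below 10 ppm.  Annotation uses 15 ppm
(the reference product-ion table itself contains an 11.2 ppm assignment).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .analogues import AnalogueConfig
from .fragments import FragmentationConfig

__all__ = ["NetworkConfig", "MasstConfig", "PipelineConfig"]


@dataclass(frozen=True)
class NetworkConfig:
    min_cosine: float = 0.65
    min_matched: int = 7       # "more than 6 matched peaks"
    top_k: int = 10
    frag_tol: float = 0.02     # Da


@dataclass(frozen=True)
class MasstConfig:
    precursor_exclusion: float = 17.0  # Da
    window: float = 50.0               # Da
    window_top_n: int = 6
    prec_tol: float = 2.0              # Da
    frag_tol: float = 0.5              # Da
    min_score: float = 0.2
    min_matched: int = 3


@dataclass(frozen=True)
class PipelineConfig:
    annotation_tol_ppm: float = 15.0
    feature_match_tol_ppm: float = 10.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    masst: MasstConfig = field(default_factory=MasstConfig)
    analogues: AnalogueConfig = field(default_factory=AnalogueConfig)
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load overrides from a simple key-value YAML file; nested sections
        (``network:``, ``masst:``) override the corresponding sub-configs."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        simple = {f.name for f in fields(cls)} - {"network", "masst", "analogues", "fragmentation"}
        overrides = {k: v for k, v in data.items() if k in simple}
        if "network" in data:
            overrides["network"] = replace(cfg.network, **data["network"])
        if "masst" in data:
            overrides["masst"] = replace(cfg.masst, **data["masst"])
        unknown = set(data) - simple - {"network", "masst"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return replace(cfg, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)
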