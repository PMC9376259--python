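"""Analysis configuration: the thresholds and radii of the pipeline.

Defaults are the pipeline's reference operating point: 0.9/1.8 mm dividing
radii, 10 mm searchlights, 1.1 mm adjacency, decoding inference at
p < 1e-4 with FDR q = 0.01 and cluster > 10 labels, load regressions at
p < 0.05 with cluster > 10, GLM contrasts at element p < 0.01 with
cluster-wise p < 0.05, chance levels 0.5 (task) and 0.25 (load), 21
analysis frames.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    r: float = 0.9                       # inner dividing radius, mm
    R: float = 1.8                       # exclusion radius, mm (2r)
    searchlight_radius: float = 10.0     # mm
    adjacency_threshold: float = 1.1     # mm
    decode_p: float = 1e-4               # per-label t threshold (decoding)
    decode_fdr_q: float = 0.01
    min_cluster_labels: int = 10         # strict ">"
    regress_p: float = 0.05              # load regressions (amplitude, connectivity)
    glm_element_p: float = 0.01
    glm_cluster_p: float = 0.05
    chance_task: float = 0.5
    chance_load: float = 0.25
    n_frames: int = 21
    seed: int = 0

    def __post_init__(self):
        for name in ("r", "R", "searchlight_radius", "adjacency_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("decode_p", "decode_fdr_q", "regress_p", "glm_element_p", "glm_cluster_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 < self.chance_task < 1 or not 0 < self.chance_load < 1:
            raise ValueError("chance levels must lie in (0, 1)")
        if self.R < self.r:
            raise ValueError("R must be >= r")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
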