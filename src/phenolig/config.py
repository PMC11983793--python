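"""Pipeline configuration: one YAML file of thresholds with validated defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from phenolig.interactions import ProfilerConfig


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default.

    Distances in Å, angles in degrees.
    """

    site_radius: float = 7.5           # binding-site / pair-count cutoff
    rdf_bin_width: float = 0.1         # pair histogram bin width
    rdf_n_mode: str = "per_pair"       # normalization total: per_pair | global
    match_threshold: float = 0.90      # Tanimoto screening threshold
    fingerprint_bits: int = 1024
    fingerprint_max_path: int = 7
    hbond_distance: float = 3.5        # network donor-acceptor cutoff
    hbond_angle: float = 60.0          # max deviation from linearity (with H)
    max_bridge_waters: int = 3
    occupancy_threshold: float = 0.5
    dbscan_eps: float = 0.9
    dbscan_min_pts: int = 4
    cluster_min_size: int = 16
    cluster_min_conservation: float = 0.26
    linkage_method: str = "average"
    seed: int = 0
    profiler: ProfilerConfig = field(default_factory=ProfilerConfig)

    def validate(self) -> None:
        positive = (
            "site_radius", "rdf_bin_width", "match_threshold", "fingerprint_bits",
            "fingerprint_max_path", "hbond_distance", "dbscan_eps", "dbscan_min_pts",
            "cluster_min_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.match_threshold <= 1:
            raise ValueError("match_threshold must be in (0, 1]")
        if not 0 <= self.occupancy_threshold <= 1:
            raise ValueError("occupancy_threshold must be in [0, 1]")
        if not 0 <= self.hbond_angle <= 180:
            raise ValueError("hbond_angle must be in [0, 180]")
        if self.max_bridge_waters < 0:
            raise ValueError("max_bridge_waters must be non-negative")
        if self.rdf_n_mode not in ("per_pair", "global"):
            raise ValueError("rdf_n_mode must be 'per_pair' or 'global'")
        self.profiler.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        profiler = ProfilerConfig(**data.pop("profiler", {}))
        cfg = cls(profiler=profiler, **data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
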