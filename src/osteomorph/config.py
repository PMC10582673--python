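"""Run configuration.

Defaults reproduce the study conditions the pipeline was designed
around: 26 harmonics for the outline Fourier analysis, 9999 PERMANOVA
permutations, 5000 disparity bootstrap replicates, 5 alignment-
consistency repeats, and three candidate mesh resolutions.  The RNG
seed is recorded in every output artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    n_harmonics: int = 26
    n_permutations: int = 9999
    n_bootstrap: int = 5000
    n_alignment_repeats: int = 5
    target_face_counts: list[int] = field(
        default_factory=lambda: [200_000, 500_000, 800_000])
    rng_seed: int = 0
    scale_removal: bool = True
    excluded_pcs: list[int] = field(default_factory=list)
    n_sample_points: int = 2000

    def __post_init__(self):
        for name in ("n_harmonics", "n_permutations", "n_bootstrap",
                     "n_alignment_repeats", "n_sample_points"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(f < 1 for f in self.target_face_counts):
            raise ValueError("target_face_counts must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def provenance(self) -> dict:
        """Sidecar payload written next to every tabular output."""
        import osteomorph
        return {"config": self.to_dict(), "config_hash": self.config_hash(),
                "seed": self.rng_seed, "osteomorph_version": osteomorph.__version__}


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML config (all keys optional) with keyword overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
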