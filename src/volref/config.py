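"""Single-file pipeline configuration with lossless JSON round-tripping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .registration import RegistrationConfig
from .synthesis import SynthesisConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the pipeline end to end.

    ``cohort_csv`` may be empty, in which case a seeded phantom cohort of
    ``n_phantom_subjects`` subjects is generated in place of file inputs.
    """

    out_dir: str = "volref_out"
    cohort_csv: str = ""
    initial_subject: str = ""
    exclusions: list = field(default_factory=list)
    n_iters: int = 1
    seed: int = 0
    # phantom-cohort settings (used when cohort_csv is empty)
    n_phantom_subjects: int = 5
    phantom_shape: list = field(default_factory=lambda: [48, 48, 48])
    phantom_spacing: list = field(default_factory=lambda: [2.07, 2.07, 8.0])
    deform_magnitude_mm: float = 4.0
    # registration
    channel_weights: list = field(default_factory=lambda: [1.0, 1.0, 0.5])
    smoothness_weight: float = 1.0
    pyramid_levels: int = 3
    max_sweeps: int = 60
    # synthesis
    epsilon: float = 0.01
    synth_tol: float = 0.01
    synth_max_iter: int = 500
    # metrics
    mi_bins: int = 256

    def registration_config(self) -> RegistrationConfig:
        return RegistrationConfig(
            channel_weights=list(self.channel_weights),
            smoothness_weight=self.smoothness_weight,
            pyramid_levels=self.n_levels,
            max_sweeps=self.max_sweeps,
            seed=self.seed,
        )

    @property
    def n_levels(self) -> int:
        return self.pyramid_levels

    def synthesis_config(self, mask=None) -> SynthesisConfig:
        return SynthesisConfig(
            epsilon=self.epsilon,
            tol=self.synth_tol,
            max_iter=self.synth_max_iter,
            mask=mask,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
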