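"""Run configuration: one human-readable YAML file, strictly validated.

Unknown keys are rejected so a typo in a parameter name fails loudly instead
of silently running with a default.  All randomness in a run flows from the
single global ``seed``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_pairs: int = 10
    fraction_clustering: float = 0.6
    mean_separation_search: float = 11.5
    mean_separation_clustering: float = 8.0
    sd_search: float = 2.0
    reversion_time: float = 200.0
    onset_separation: float = 7.5
    motorized_duration: float = 900.0
    final_separation: float = 1.5
    frame_interval: float = 40.0
    n_frames: int = 120
    render_images: bool = False
    pixel_size_xy: float = 0.13
    z_spacing: float = 0.5
    n_z: int = 35
    n_y: int = 128
    n_x: int = 128
    noise_model: str = "poisson"
    spot_amplitude: float = 500.0
    background: float = 10.0


class TrackConfig(_Strict):
    anchor_spacing: int = 6
    mean_speed_um_s: float = 0.02
    frame_interval: float = 40.0
    seed_mode: str = "auto"              # auto | provided
    max_gap: int = 2


class AnalyzeConfig(_Strict):
    d_clustered: float = 2.0
    stability_window: int = 5
    stability_sd: float = 0.3
    msd_phase: str = "search"
    histogram_bin_um: float = 0.5
    rose_bin_deg: float = 10.0
    afm_max_depth_nm: float = 800.0
    afm_tip_half_angle_deg: float = 35.0
    afm_poisson_ratio: float = 0.5
    bootstrap_resamples: int = 1000


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    track: TrackConfig = Field(default_factory=TrackConfig)
    analyze: AnalyzeConfig = Field(default_factory=AnalyzeConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=False))

    def checksum(self) -> str:
        """Digest of the scientific parameters (paths and logging excluded)."""
        payload = json.dumps(self.model_dump(exclude={"out_dir", "log_level"}),
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
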