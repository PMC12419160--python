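"""Pipeline configuration: a validated, serializable description of a run.

A :class:`PipelineConfig` fully determines a simulate → segment → quantify
→ statistics run: geometry and kinetics of each experimental group, optics,
segmentation recipe, quantification choices, and the single seed from which
all randomness derives.  Configs round-trip losslessly through YAML and
reject unknown keys, so a saved config is an exact, re-runnable record; the
SHA-256 hash of its canonical JSON form stamps every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticsConfig(_Strict):
    phi0: float = 0.1
    delta_phi: float = 0.4
    tau_on: float = 60.0
    t_stim: float = 120.0
    t_rev: float | None = None
    tau_off: float | None = None


class SceneConfig(_Strict):
    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 160.0
    n_frames: int = 48
    frame_interval: float = 15.0
    cell_radius: float = 50.0
    nucleus_radius: float = 15.0
    pm_thickness: float = 3.0
    organelle: str = "pm"
    total_probe: float = 1.2e6
    marker_level: float = 600.0
    background_offset: float = 50.0
    nuclear_ratio: float = 1.0
    poisson_scale: float = 1.0
    read_sigma: float = 2.0
    blur_sigma_px: float = 0.0


class OpticsConfig(_Strict):
    wavelength: float = 640.0  # nm, far-red membrane marker emission
    numerical_aperture: float = 1.45


class SegmentationConfig(_Strict):
    preset: str = "pm"
    threshold_factor: float = 0.5
    dilation_cycles: int = 1
    mode: str = "per-frame"  # or "fixed"
    mask_source: str = "wavelet"  # or "ground-truth"


class QuantifyConfig(_Strict):
    denominator: str = "cytosol"  # or "whole_cell"
    roi_source: str = "ground-truth"  # or a path to a ROI file
    baseline_window: tuple[int, int] | None = None
    response_window: tuple[int, int] | None = None


class GroupConfig(_Strict):
    name: str
    n_reps: int = 3
    cells_per_rep: int = 3
    kinetics: KineticsConfig = Field(default_factory=KineticsConfig)


class StatsConfig(_Strict):
    test: str = "anova"  # "anova" | "t" | "one-sample-t"
    reference_group: str | None = None


class PipelineConfig(_Strict):
    seed: int = 0
    scene: SceneConfig = Field(default_factory=SceneConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    quantify: QuantifyConfig = Field(default_factory=QuantifyConfig)
    groups: list[GroupConfig] = Field(
        default_factory=lambda: [GroupConfig(name="control")]
    )
    stats: StatsConfig = Field(default_factory=StatsConfig)


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON form (first 16 hex digits)."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(raw)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
    return path
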