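"""Pipeline configuration: schema-checked, YAML-loadable, snapshot-emitting."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

STAGES = ("simulate", "fit", "register", "cluster", "msi", "histology", "validate")


@dataclass
class PipelineConfig:
    """All pipeline settings with study-protocol defaults.

    Unknown keys are rejected at load time; every run writes the resolved
    configuration alongside its outputs so results are reproducible.
    """

    seed: int = 0
    # cohort / phantom geometry
    n_subjects: int = 8
    n_timepoints: int = 2
    grid_dims: tuple[int, int, int] = (64, 64, 10)
    spacing: tuple[float, float, float] = (0.53, 0.53, 1.0)
    n_habitats: int = 5
    necrotic_fraction: float = 0.37
    # acquisition
    b_values: tuple[float, ...] = (0.0, 150.0, 500.0, 800.0)
    tr_list: tuple[float, ...] = (255.0, 400.0, 800.0, 1500.0, 3000.0, 5500.0)
    dce_temporal_resolution: float = 6.4
    n_precontrast_frames: int = 20
    n_dce_frames: int = 70
    relaxivity: float = 4.5
    injected_dose: float = 3700.0
    body_weight: float = 25.0
    noise_sd_dwi: float = 20.0
    noise_sd_vtr: float = 10.0
    noise_sd_dce: float = 7.5
    pet_noise_sd: float = 5.0
    pet_psf_fwhm: float = 1.5
    # registration
    misalign_pet: bool = True
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 3.0
    registration_iterations: int = 100
    # clustering
    k: int | None = None
    k_range: tuple[int, int] = (2, 8)
    ranges: dict | None = None
    # spatial interaction
    msi_connectivity: int = 6
    msi_n_randomizations: int = 1000
    # histology
    histology_kernel_px: int = 10
    histology_px_per_voxel: int = 4
    histology_target_px_um: float = 265.0
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_dims", "spacing", "b_values", "tr_list", "k_range"):
            d[key] = list(d[key])
        return d

    def snapshot(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file; unknown keys raise.  ``overrides`` win."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("grid_dims", "spacing", "b_values", "tr_list", "k_range"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)
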