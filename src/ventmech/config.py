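"""Run configuration: defaulted, nested, strict about unknown keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class ImagingConfig:
    denoise_method: str = "median"       # median | nonlocal_means | none
    denoise_radius: int = 1
    n_classes: int = 4
    kmeans_seed: int = 0
    background_region: str = "corners"   # corners | none
    corner_size: int = 4
    sd_ddof: int = 0                     # 0 = population SD in the CV
    fill_holes: bool = True
    superior_fraction: float = 0.12
    midline_fraction: float = 0.14
    airway_dilate: int = 1
    airway_max_volume_fraction: float = 0.10


@dataclass
class MechanicsConfig:
    fundamental_hz: float = 0.1
    f_min: float = 0.1
    f_max: float = 8.0
    count: int = 7
    growth_factor: float = 1.8
    tidal_volume_l: float = 0.5
    fs_hz: float = 40.0
    duration_s: float = 40.0
    amplitude_profile: str = "equal_volume"
    optimizer_restarts: int = 6


@dataclass
class CohortConfig:
    n_healthy: int = 4
    n_asthmatic: int = 9
    coupling: float = 1.0
    noise_sigma: float = 4.0
    pc20_min: float = 0.05
    pc20_max: float = 25.0
    image_shape: tuple[int, int, int] = (48, 32, 8)


@dataclass
class AnalysisConfig:
    log_pc20: bool = False
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _build(cls, data, "")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, prefix: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)
        ):
            sub_cls = f.default_factory
            if not isinstance(value, dict):
                raise ValueError(f"config section {prefix + name!r} must be a mapping")
            kwargs[name] = _build(sub_cls, value, f"{prefix}{name}.")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)
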