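"""Run configuration: one YAML-serializable object covering every stage.

The configuration round-trips losslessly through YAML, and every stochastic
stage draws from a named substream of the single top-level seed, so a run
is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .synthetic import CorrelativeDatasetParams, MovieParams


@dataclass
class DetectionConfig:
    baseline_percentile: float = 20.0
    k_sigma: float = 3.8
    smooth_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_halfwidth_um: float = 4.0
    fwhm_bounds_um: tuple[float, float] = (0.5, 2.0)
    r2_min: float = 0.5
    mass_cubic: bool = False


@dataclass
class RenderConfig:
    pixel_size_nm: float = 5.0
    n_jitter: int = 10
    pad_nm: float = 250.0
    clip_percentile: float = 99.9


@dataclass
class PunctaConfig:
    threshold_frac: float = 1.0
    min_area_nm2: float = 100.0


@dataclass
class AlignConfig:
    coarse_dx_nm: float = 0.0
    coarse_dy_nm: float = 0.0
    search_radius_nm: float = 2000.0
    target_fwhm_nm: float = 250.0
    reference_n_frames: int = 10


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    With ``simulate=True`` the input movie and localization table are
    generated from ``simulation``; otherwise ``movie_path`` and
    ``localizations_path`` must point at existing files.
    """

    seed: int = 0
    outdir: str = "run_output"
    simulate: bool = True
    movie_path: str | None = None
    localizations_path: str | None = None
    cell_mask_path: str | None = None
    simulation: CorrelativeDatasetParams = field(default_factory=CorrelativeDatasetParams)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    save_figures: bool = False


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    return obj


_NESTED = {
    "simulation": CorrelativeDatasetParams,
    "detection": DetectionConfig,
    "render": RenderConfig,
    "puncta": PunctaConfig,
    "align": AlignConfig,
    "movie": MovieParams,
}

_TUPLE_FIELDS = {
    "smooth_sigma",
    "fwhm_bounds_um",
    "frame_shape",
    "fwhm_range_um",
    "amplitude_range",
    "shift_nm",
}


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _from_plain(_NESTED[f.name], v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> RunConfig:
    return _from_plain(RunConfig, data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
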