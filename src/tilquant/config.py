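"""Pipeline configuration.

A single flat dataclass holds every tunable of the image pipeline, with a
YAML loader that understands the dotted key layout used in config files
(``pyramid.downsample_factor``, ``tissue.block_size``, ...).  All defaults
are declared here and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

#: Ruifrok-style optical-density unit vectors for haematoxylin and eosin.
DEFAULT_STAIN_H = (0.650, 0.704, 0.286)
DEFAULT_STAIN_E = (0.072, 0.990, 0.105)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the tile-to-catalogue pipeline.

    Lengths are in pixels at full resolution (L0) unless stated otherwise;
    ``mpp`` is microns per pixel at L0.
    """

    # pyramid
    downsample_factor: int = 4
    mpp: float = 0.5

    # tissue detection on L3
    block_size: int = 16
    t_lum: float = 220.0      # luminance at/above which a pixel can be background
    t_sat: float = 0.08       # HSV saturation at/below which a pixel can be background
    min_tissue_fraction: float = 0.25

    # stain separation
    stain_h: tuple[float, float, float] = DEFAULT_STAIN_H
    stain_e: tuple[float, float, float] = DEFAULT_STAIN_E

    # nucleus segmentation
    k_sigma: float = 3.0          # detection threshold: background + k*sigma (H OD)
    bg_grid: int = 64             # coarse-grid cell size for background estimation
    min_seed_separation: int = 5  # px between watershed seeds
    min_area: int = 15            # px^2, at 0.5 um/px
    max_area: int = 2000
    min_solidity: float = 0.7

    # block stitching
    overlap_margin: int = 8       # px of L0 overlap between adjacent blocks
    dedup_radius: float = 4.0     # centroids closer than this across blocks are merged

    # spatial metrics
    k_neighbours: int = 50


# dotted YAML key -> dataclass field
_YAML_KEYS = {
    "pyramid.downsample_factor": "downsample_factor",
    "image.mpp": "mpp",
    "tissue.block_size": "block_size",
    "tissue.t_lum": "t_lum",
    "tissue.t_sat": "t_sat",
    "tissue.min_fraction": "min_tissue_fraction",
    "stains.h": "stain_h",
    "stains.e": "stain_e",
    "segmentation.k_sigma": "k_sigma",
    "segmentation.bg_grid": "bg_grid",
    "segmentation.min_seed_separation": "min_seed_separation",
    "segmentation.min_area": "min_area",
    "segmentation.max_area": "max_area",
    "segmentation.min_solidity": "min_solidity",
    "segmentation.overlap_margin": "overlap_margin",
    "segmentation.dedup_radius": "dedup_radius",
    "metrics.k": "k_neighbours",
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for key, val in d.items():
        dotted = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten(val, dotted + "."))
        else:
            out[dotted] = val
    return out


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file plus keyword overrides.

    Unknown dotted keys in the file raise ``KeyError`` so typos do not pass
    silently.  ``overrides`` use the dataclass field names directly.
    """
    cfg = PipelineConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        updates = {}
        for dotted, val in _flatten(raw).items():
            if dotted not in _YAML_KEYS:
                raise KeyError(f"unknown config key: {dotted!r}")
            name = _YAML_KEYS[dotted]
            if name in ("stain_h", "stain_e"):
                val = tuple(float(v) for v in val)
            updates[name] = val
        cfg = replace(cfg, **updates)
    if overrides:
        valid = {f.name for f in fields(PipelineConfig)}
        bad = set(overrides) - valid
        if bad:
            raise KeyError(f"unknown config overrides: {sorted(bad)}")
        cfg = replace(cfg, **overrides)
    return cfg
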