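"""Experiment configuration: one flat dataclass, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """Everything a full experiment needs, with scaled-down defaults.

    The defaults describe a desk-scale analogue of the physical study: a
    60-pearl cohort sampled once per minute over 3-6 week acquisitions,
    5% relative sensor noise, the tiny-cnn backbone and a 10-repeat grouped
    holdout.  All randomness derives from ``seed``.
    """

    # simulation
    n_pearls: int = 60
    class_probs: tuple[float, float, float] = (0.276, 0.213, 0.511)
    speed_mean: float = 0.69
    speed_sd: float = 0.13
    culture_day_range: tuple[int, int] = (365, 545)
    acquisition_weeks: tuple[int, int] = (3, 6)
    sample_interval_s: float = 60.0
    noise_frac: float = 0.05
    offset_frac: float = 0.0
    seed: int = 0
    # signal pipeline
    smooth_window: int = 9
    pole_cut: float = 0.95
    speed_lag_s: float = 600.0
    # imaging
    image_size: int = 224
    n_views: int = 6
    view_step: float = 60.0
    point_radius: int = 2
    colormap: str = "viridis"
    wireframe: bool = True
    # model
    backbone: str = "tiny-cnn"
    dense_widths: tuple[int, ...] = (256,)
    dropout_rates: tuple[float, ...] = (0.5,)
    lr: float = 1e-3
    epochs: int = 30
    batch: int = 16
    patience: int = 10
    use_metadata: bool = True
    # evaluation
    n_repeats: int = 10
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    variants: tuple[str, ...] = ("full", "week", "day")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML has no tuple type; restore tuples for tuple-typed fields
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
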