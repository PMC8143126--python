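"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .albedo import SNOW_REFERENCE_ALBEDO
from .thermal import (
    DEFAULT_DROP_PREFERENCE,
    DEFAULT_RADIATION_CANDIDATES,
    DEFAULT_WEATHER_CANDIDATES,
)

#: Neutral provenance notes for defaults that are study conventions rather
#: than arbitrary implementation choices; emitted into the run manifest.
DEFAULT_PROVENANCE = {
    "snow_ref": "study default: assumed albedo of the fresh-snow in-scene reference",
    "correlation_threshold": "study default: |r| cutoff for same-source covariate pruning",
    "alpha": "study default: significance level for group and slope comparisons",
    "emissivity": "study default: infrared-thermometer emissivity setting (0.93)",
}


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end pipeline, with serialized defaults.

    Attributes
    ----------
    snow_ref : assumed albedo of the snow reference (unitless).
    gray_rule : RGB-to-gray conversion, "mean" or "luminance".
    arcsine_variant : proportion transform; only "arcsin_sqrt" is implemented.
    correlation_threshold : |r| above which same-source covariates are pruned.
    drop_preference : which member of a flagged correlated pair is dropped.
    alpha : significance level for the albedo and slope comparisons.
    seed : master seed; per-stage seeds are derived from it (see manifest).
    n_observations : rows in each synthetic thermal table.
    noise_sd : residual SD (degC) of the model-mode surface temperature.
    slope_noise_sd : residual SD (degC) of the slope-mode dT.
    image_noise_sd : pixel noise SD (gray levels) of the synthetic scenes.
    n_replicate_images : replicate winter scenes for albedo estimation.
    out_dir : run directory for all stage outputs.
    """

    snow_ref: float = SNOW_REFERENCE_ALBEDO
    gray_rule: str = "mean"
    arcsine_variant: str = "arcsin_sqrt"
    correlation_threshold: float = 0.7
    drop_preference: list[str] = field(default_factory=lambda: list(DEFAULT_DROP_PREFERENCE))
    alpha: float = 0.05
    seed: int = 0
    weather_candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_WEATHER_CANDIDATES)
    )
    radiation_candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_RADIATION_CANDIDATES)
    )
    n_observations: int = 638
    noise_sd: float = 5.0
    slope_noise_sd: float = 3.0
    image_noise_sd: float = 5.0
    n_replicate_images: int = 3
    out_dir: str = "bovitherm_run"

    def validate(self) -> None:
        if not 0 < self.snow_ref <= 1:
            raise ValueError("snow_ref must lie in (0, 1]")
        if self.gray_rule not in ("mean", "luminance"):
            raise ValueError("gray_rule must be 'mean' or 'luminance'")
        if self.arcsine_variant != "arcsin_sqrt":
            raise ValueError("only the arcsin_sqrt transform variant is implemented")
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_replicate_images < 1:
            raise ValueError("need at least one replicate image")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config
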