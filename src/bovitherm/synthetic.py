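"""Ground-truth synthetic data for the albedo and thermal-ecology pipeline.

Two generators make every downstream stage testable without field data:

* :func:`generate_winter_image` renders an 8-bit winter scene — a snow field
  of known base brightness containing rectangular hide patches of known
  absolute albedo — together with a labeled region mask and a record of every
  injected parameter. Patch brightness is linear in albedo
  (``patch_gray = snow_gray * albedo / snow_ref``), the unique brightness
  model under which the snow-referenced ratio estimator is unbiased.

* :func:`generate_thermal_observations` draws paired animal-surface /
  ambient-temperature observations with daily weather and radiation
  covariates. Covariates are drawn through a Gaussian copula so that declared
  pairs (earth skin temperature with long- and short-wave radiation, humidity
  with wind, vapor-pressure deficit with dewpoint) are strongly correlated
  (|r| > 0.7), then mapped to their declared marginal ranges by a monotone
  power map whose exponent is chosen so each marginal's expectation equals its
  declared mean. In *model mode* the cow surface temperature follows a linear
  model in ambient temperature, clear-sky insolation index and hide albedo;
  in *slope mode* the temperature difference dT is generated directly from
  per-hide-color slopes against ambient temperature, the fixture needed for
  slope-heterogeneity analyses (the model-mode design implies equal slopes).

What the generators emulate — and what they do not — is discussed in
``docs/methods.md``; notably there are no photorealistic animal shapes, no
weather time-series dynamics, and one observation per synthetic day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .albedo import RegionMaskSet, SNOW_REFERENCE_ALBEDO

# ---------------------------------------------------------------------------
# Winter-image generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchSpec:
    """One rectangular hide patch: color label, true albedo, geometry."""

    label: str
    albedo: float
    x: int
    y: int
    width: int
    height: int

    def overlaps(self, other: "PatchSpec") -> bool:
        return not (
            self.x + self.width <= other.x
            or other.x + other.width <= self.x
            or self.y + self.height <= other.y
            or other.y + other.height <= self.y
        )


def _default_patches() -> tuple[PatchSpec, ...]:
    # three hide colors at the study's estimated albedos
    return (
        PatchSpec("white", 0.69, 20, 20, 60, 60),
        PatchSpec("red", 0.16, 120, 20, 60, 60),
        PatchSpec("black", 0.04, 220, 20, 60, 60),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic winter scene.

    ``snow_gray`` is the noise-free brightness of snow pixels; each patch is
    rendered at ``snow_gray * albedo / snow_ref`` (rounded to the nearest gray
    level) before additive Gaussian pixel noise. ``shadow_fraction`` darkens a
    random subset of snow pixels, emulating surface shadows.
    """

    width: int = 320
    height: int = 240
    snow_gray: int = 200
    patches: tuple[PatchSpec, ...] = field(default_factory=_default_patches)
    noise_sd: float = 0.0
    shadow_fraction: float = 0.0
    snow_ref: float = SNOW_REFERENCE_ALBEDO
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.snow_gray <= 255:
            raise ValueError("snow base gray must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0.0 <= self.shadow_fraction <= 1.0:
            raise ValueError("shadow fraction must lie in [0, 1]")
        for patch in self.patches:
            if not 0.0 <= patch.albedo <= self.snow_ref:
                raise ValueError(
                    f"patch {patch.label!r}: true albedo {patch.albedo} exceeds "
                    f"the snow reference {self.snow_ref}"
                )
            if (
                patch.x < 0
                or patch.y < 0
                or patch.x + patch.width > self.width
                or patch.y + patch.height > self.height
                or patch.width <= 0
                or patch.height <= 0
            ):
                raise ValueError(f"patch {patch.label!r} does not fit in the image")
        for i, a in enumerate(self.patches):
            for b in self.patches[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"patches {a.label!r} and {b.label!r} overlap")
        labels = [p.label for p in self.patches]
        if len(set(labels)) != len(labels):
            raise ValueError("patch labels must be unique")


def generate_winter_image(spec: SceneSpec) -> tuple[np.ndarray, RegionMaskSet, dict]:
    """Render a synthetic winter scene with ground-truth masks.

    Returns ``(image, masks, truth)`` where ``image`` is a 2-D uint8 array,
    ``masks`` labels the snow region (label 1) and one region per patch
    (labels 2, 3, ...), and ``truth`` records every injected parameter,
    including the quantized gray level each patch was actually rendered at.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    clean = np.full((spec.height, spec.width), float(spec.snow_gray))
    labels = np.ones((spec.height, spec.width), dtype=np.int64)
    names = {1: "snow"}
    patch_grays = {}
    for i, patch in enumerate(spec.patches, start=2):
        gray = float(np.floor(spec.snow_gray * patch.albedo / spec.snow_ref + 0.5))
        sl = (slice(patch.y, patch.y + patch.height), slice(patch.x, patch.x + patch.width))
        clean[sl] = gray
        labels[sl] = i
        names[i] = patch.label
        patch_grays[patch.label] = gray
    if spec.shadow_fraction > 0:
        snow_idx = np.flatnonzero(labels.ravel() == 1)
        n_shadow = int(round(spec.shadow_fraction * snow_idx.size))
        shadowed = rng.choice(snow_idx, size=n_shadow, replace=False)
        flat = clean.ravel()
        flat[shadowed] = np.floor(flat[shadowed] * 0.6 + 0.5)
        clean = flat.reshape(clean.shape)
    noisy = clean
    if spec.noise_sd > 0:
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    image = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)
    truth = {
        "snow_gray": spec.snow_gray,
        "snow_ref": spec.snow_ref,
        "noise_sd": spec.noise_sd,
        "shadow_fraction": spec.shadow_fraction,
        "seed": spec.seed,
        "patch_albedos": {p.label: p.albedo for p in spec.patches},
        "patch_grays": patch_grays,
    }
    return image, RegionMaskSet(labels=labels, names=names), truth


# ---------------------------------------------------------------------------
# Thermal observation / covariate generation
# ---------------------------------------------------------------------------

#: Declared marginal (mean, min, max) of every covariate, matching the
#: study-scale summary the generator reproduces. Units: degC for temperatures,
#: % for humidity, hPa for VPD, km/h for wind, kW hr m^-2 day^-1 for
#: radiation, unitless 0-1 for the clear-sky insolation index.
COVARIATE_RANGES: dict[str, tuple[float, float, float]] = {
    "temp_amb": (4.4, -32.8, 35.6),
    "temp_dew": (-10.0, -27.6, 7.1),
    "humidity": (56.7, 9.0, 84.0),
    "vpd": (13.5, 0.6, 32.5),
    "wind_speed": (29.0, 11.3, 53.1),
    "temp_earth": (-0.1, -24.6, 23.0),
    "ktclear": (0.6, 0.3, 0.8),
    "rad_lw": (5.9, 3.6, 8.7),
    "rad_sw": (3.9, 1.3, 8.5),
}

#: Gaussian-copula correlations. The four declared high-correlation pairs are
#: set to 0.85 (> the 0.7 pruning threshold after the marginal maps); the
#: LW/SW radiation entry is implied — it must exceed 2*0.85^2 - 1 for a valid
#: correlation matrix, and 0.6 keeps its sample correlation below 0.7 so it is
#: never flagged by source-group pruning.
DEFAULT_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("temp_earth", "rad_lw", 0.85),
    ("temp_earth", "rad_sw", 0.85),
    ("rad_lw", "rad_sw", 0.6),
    ("humidity", "wind_speed", 0.85),
    ("vpd", "temp_dew", 0.85),
)

#: Hide-color composition of the study herd (counts 183/158/297 of 638).
DEFAULT_COLOR_PROPORTIONS: dict[str, float] = {
    "white": 183 / 638,
    "red": 158 / 638,
    "black": 297 / 638,
}

#: Absolute winter albedo assigned to each hide color.
ALBEDO_BY_COLOR: dict[str, float] = {"white": 0.69, "red": 0.16, "black": 0.04}

#: Generating coefficients of the cow-surface-temperature model.
DEFAULT_TEMP_COW_COEFFICIENTS: dict[str, float] = {
    "temp_amb": 0.1770,
    "ktclear": 19.172,
    "albedo": -27.026,
}

#: Per-hide-color slopes of dT against ambient temperature (slope mode).
DEFAULT_SLOPES_BY_COLOR: dict[str, float] = {
    "white": -0.45,
    "red": -0.92,
    "black": -1.07,
}

#: Mean cow surface temperature the model-mode intercept is calibrated to.
MEAN_TEMP_COW = 32.4
#: Overall mean dT the slope-mode intercepts are calibrated to.
MEAN_DELTA_T = 28.0


@dataclass(frozen=True)
class ThermalGenParams:
    """Parameters of the thermal observation/covariate generator."""

    n: int = 638
    mode: str = "model"  # "model" or "slope"
    color_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COLOR_PROPORTIONS)
    )
    albedo_by_color: Mapping[str, float] = field(
        default_factory=lambda: dict(ALBEDO_BY_COLOR)
    )
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TEMP_COW_COEFFICIENTS)
    )
    intercept: float | None = None  # None -> calibrated, see calibrated_intercept()
    noise_sd: float = 5.0
    slopes_by_color: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES_BY_COLOR)
    )
    covariate_ranges: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(COVARIATE_RANGES)
    )
    correlations: Sequence[tuple[str, str, float]] = DEFAULT_CORRELATIONS
    seed: int = 0

    def validate(self) -> None:
        colors = list(self.color_proportions)
        if self.n < 2 * len(colors):
            raise ValueError("n must be at least twice the number of colors")
        if self.mode not in ("model", "slope"):
            raise ValueError("mode must be 'model' or 'slope'")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if abs(sum(self.color_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("color proportions must sum to 1")
        for a, b, r in self.correlations:
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation ({a}, {b}) = {r} not in (-1, 1)")
        for name, (mean, lo, hi) in self.covariate_ranges.items():
            if not lo < mean < hi:
                raise ValueError(f"{name}: mean {mean} outside ({lo}, {hi})")
        missing = set(self.albedo_by_color) ^ set(self.color_proportions)
        if missing:
            raise ValueError(f"albedo/proportion color sets differ: {missing}")


def calibrated_intercept(params: ThermalGenParams) -> float:
    """Model-mode intercept making E[Temp_cow] equal its declared mean.

    Solves ``mean_response = b0 + beta . mean_covariates`` at the declared
    covariate means, with the mean albedo taken as the proportion-weighted
    average of the per-color albedos.
    """
    if params.intercept is not None:
        return float(params.intercept)
    mean_albedo = sum(
        params.color_proportions[c] * params.albedo_by_color[c]
        for c in params.color_proportions
    )
    means = {name: params.covariate_ranges[name][0] for name in params.covariate_ranges}
    means["albedo"] = mean_albedo
    return MEAN_TEMP_COW - sum(
        beta * means[name] for name, beta in params.coefficients.items()
    )


def _correlation_matrix(
    names: Sequence[str], pairs: Sequence[tuple[str, str, float]]
) -> np.ndarray:
    corr = np.eye(len(names))
    index = {name: i for i, name in enumerate(names)}
    for a, b, r in pairs:
        corr[index[a], index[b]] = corr[index[b], index[a]] = r
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin < -1e-10:
        raise ValueError(
            "declared correlations do not form a positive semi-definite "
            f"matrix (smallest eigenvalue {eigmin:.3g})"
        )
    return corr


def _power_exponent(mean: float, lo: float, hi: float) -> float:
    # u ~ U(0,1); x = lo + (hi-lo) * u**p has E[x] = lo + (hi-lo)/(p+1)
    return (hi - lo) / (mean - lo) - 1.0


def _color_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    # largest-remainder apportionment: exact totals, deterministic
    quotas = {c: n * p for c, p in proportions.items()}
    counts = {c: int(np.floor(q)) for c, q in quotas.items()}
    short = n - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_thermal_observations(
    params: ThermalGenParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a synthetic observation table and matching daily covariate table.

    Returns ``(observations, covariates, truth)``. Observations carry one row
    per animal measurement (``date_index``, ``color``, ``albedo``,
    ``temp_cow``, ``temp_amb``, ``delta_t``); covariates carry one row per
    synthetic day. ``truth`` records the injected coefficients, noise and
    seed. ``delta_t`` is the signed difference ``temp_cow - temp_amb``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    names = list(params.covariate_ranges)
    corr = _correlation_matrix(names, params.correlations)
    # Gaussian copula: correlated normals -> uniforms -> power-mapped marginals
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((params.n, len(names))) @ chol.T
    u = norm.cdf(z)
    data = {}
    for j, name in enumerate(names):
        mean, lo, hi = params.covariate_ranges[name]
        p = _power_exponent(mean, lo, hi)
        data[name] = lo + (hi - lo) * u[:, j] ** p
    cov = pd.DataFrame(data)
    cov.insert(0, "date_index", np.arange(params.n))

    counts = _color_counts(params.n, params.color_proportions)
    color = np.concatenate([[c] * k for c, k in counts.items()])
    color = color[rng.permutation(params.n)]
    albedo = np.array([params.albedo_by_color[c] for c in color])
    noise = rng.normal(0.0, params.noise_sd, size=params.n) if params.noise_sd > 0 else 0.0

    temp_amb = cov["temp_amb"].to_numpy()
    truth: dict = {
        "mode": params.mode,
        "n": params.n,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
        "color_counts": counts,
        "albedo_by_color": dict(params.albedo_by_color),
    }
    if params.mode == "model":
        b0 = calibrated_intercept(params)
        design = {"temp_amb": temp_amb, "ktclear": cov["ktclear"].to_numpy(), "albedo": albedo}
        temp_cow = b0 + noise
        for name, beta in params.coefficients.items():
            temp_cow = temp_cow + beta * design[name]
        delta_t = temp_cow - temp_amb
        truth["intercept"] = b0
        truth["coefficients"] = dict(params.coefficients)
    else:
        slopes = params.slopes_by_color
        mean_amb = params.covariate_ranges["temp_amb"][0]
        intercepts = {c: MEAN_DELTA_T - m * mean_amb for c, m in slopes.items()}
        delta_t = (
            np.array([intercepts[c] for c in color])
            + np.array([slopes[c] for c in color]) * temp_amb
            + noise
        )
        temp_cow = delta_t + temp_amb
        truth["slopes_by_color"] = dict(slopes)
        truth["intercepts_by_color"] = intercepts

    obs = pd.DataFrame(
        {
            "date_index": np.arange(params.n),
            "color": color,
            "albedo": albedo,
            "temp_cow": temp_cow,
            "temp_amb": temp_amb,
            "delta_t": delta_t,
        }
    )
    # temp_amb is a field measurement: it lives with the observations, the
    # remaining covariates form the daily table keyed by date_index
    cov = cov.drop(columns=["temp_amb"])
    return obs, cov, truth


# ---------------------------------------------------------------------------
# File plumbing
# ---------------------------------------------------------------------------

def write_truth(path: str | Path, truth: Mapping) -> None:
    """Write a truth record as a flat key=value text file."""
    lines = []

    def emit(prefix: str, value) -> None:
        if isinstance(value, Mapping):
            for k, v in value.items():
                emit(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            lines.append(f"{prefix}={value}")

    emit("", dict(truth))
    Path(path).write_text("\n".join(lines) + "\n")


def scene_spec_record(spec: SceneSpec) -> dict:
    """Flatten a SceneSpec to a plain dict (for manifests and truth files)."""
    record = asdict(spec)
    record["patches"] = {p.label: asdict(p) for p in spec.patches}
    return record
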