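"""Snow-referenced albedo estimation from winter digital images.

A fresh-snow surface in an 8-bit photograph provides a brightness reference of
known albedo (0.85 is the standard fresh-snow value). The albedo of any other
region in the same scene — here, patches of animal hide — is estimated from
pixel gray values in two steps:

* relative albedo: the ratio of the target region's mean brightness to the
  snow region's mean brightness, ``albedo_rel = bright_target / bright_snow``;
* absolute albedo: the relative albedo rescaled by the snow reference,
  ``albedo_abs = albedo_rel * snow_ref``.

Regions are supplied as label images (reproducible, scriptable masks) rather
than interactive selections. This estimator is valid only when a common
illumination reference is present in-frame; it performs no shadow correction
and no spectral (per-band) analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from sklearn.base import BaseEstimator

#: Standard albedo of fresh snow used as the in-scene reference constant.
SNOW_REFERENCE_ALBEDO = 0.85

#: ITU-R 601 luma weights, the common alternative to the unweighted mean.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RegionMaskSet:
    """Labeled pixel regions over one image.

    ``labels`` is an integer label image (0 = background / unlabeled); ``names``
    maps each positive label value to a region name such as ``"snow"`` or
    ``"black"``. Exactly one region should be named ``"snow"`` for estimation.
    """

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"label values without a name: {sorted(missing)}")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("region names must be unique")

    @property
    def region_names(self) -> list[str]:
        return [self.names[v] for v in sorted(self.names)]

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the region called ``name``."""
        for value, region in self.names.items():
            if region == name:
                return self.labels == value
        raise KeyError(f"no region named {name!r}")


@dataclass(frozen=True)
class PixelSummary:
    """Brightness summary of one masked region of a gray image."""

    mean: float
    sd: float
    minimum: int
    maximum: int
    histogram: np.ndarray  # 256 integer bins, one per gray level
    n_pixels: int


@dataclass(frozen=True)
class AlbedoEstimate:
    """Snow-referenced albedo of one region in one image."""

    label: str
    albedo_rel: float
    albedo_abs: float
    snow_ref: float = SNOW_REFERENCE_ALBEDO
    image_id: str | None = None


def to_gray(image: np.ndarray, weights: Sequence[float] | None = None) -> np.ndarray:
    """Collapse a 3-channel 8-bit image to gray values in [0, 255].

    By default each pixel's gray value is the unweighted mean of its three
    channels, rounded half-up — the convention of common image-analysis tools.
    Pass ``weights`` (e.g. :data:`LUMINANCE_WEIGHTS`) for a weighted rule.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected a (H, W, 3) image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    if weights is None:
        gray = arr.mean(axis=2)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (3,):
            raise ValueError("weights must have length 3")
        gray = arr @ (w / w.sum())
    # round half-up, then clip: np.round would round halves to even
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)


def pixel_summary(image: np.ndarray, mask: np.ndarray) -> PixelSummary:
    """Summarize gray values over the masked pixels of an image.

    Returns the arithmetic mean, sample SD, min, max and the 256-bin gray
    histogram over exactly the masked pixels.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    values = image[mask]
    if values.size == 0:
        raise ValueError("mask selects no pixels")
    if values.min() < 0 or values.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    hist = np.bincount(values.astype(np.int64).ravel(), minlength=256)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return PixelSummary(
        mean=float(values.mean()),
        sd=sd,
        minimum=int(values.min()),
        maximum=int(values.max()),
        histogram=hist,
        n_pixels=int(values.size),
    )


def relative_albedo(bright_target: float, bright_reference: float) -> float:
    """Relative albedo: target mean brightness over reference mean brightness.

    Values above 1 (target brighter than the snow reference) are physically
    suspect; they are retained for diagnostics but a warning is emitted.
    """
    if bright_reference <= 0:
        raise ValueError("reference brightness must be positive")
    if bright_target < 0:
        raise ValueError("target brightness must be non-negative")
    rel = bright_target / bright_reference
    if rel > 1.0:
        warnings.warn(
            f"relative albedo {rel:.4f} exceeds 1: target region is brighter "
            "than the snow reference",
            stacklevel=2,
        )
    return rel


def absolute_albedo(rel: float, snow_ref: float = SNOW_REFERENCE_ALBEDO) -> float:
    """Absolute albedo: relative albedo rescaled by the snow reference."""
    if rel < 0:
        raise ValueError("relative albedo must be non-negative")
    if not 0 < snow_ref <= 1:
        raise ValueError("snow reference albedo must lie in (0, 1]")
    return rel * snow_ref


def estimate_image_albedos(
    image: np.ndarray,
    masks: RegionMaskSet,
    snow_ref: float = SNOW_REFERENCE_ALBEDO,
    image_id: str | None = None,
) -> list[AlbedoEstimate]:
    """Estimate the absolute albedo of every labeled region in one image.

    The region named ``"snow"`` supplies the reference brightness; an estimate
    is returned for every region, including the snow region itself (which by
    construction recovers ``snow_ref`` exactly — a useful self-check).
    """
    names = masks.region_names
    if "snow" not in names:
        raise ValueError("mask set must contain a region named 'snow'")
    if len(names) < 2:
        raise ValueError("mask set must contain at least one target region")
    reference = pixel_summary(image, masks.mask("snow")).mean
    estimates = []
    for name in names:
        summary = pixel_summary(image, masks.mask(name))
        rel = relative_albedo(summary.mean, reference)
        estimates.append(
            AlbedoEstimate(
                label=name,
                albedo_rel=rel,
                albedo_abs=absolute_albedo(rel, snow_ref),
                snow_ref=snow_ref,
                image_id=image_id,
            )
        )
    return estimates


def summarize_replicates(estimates: Iterable[AlbedoEstimate] | pd.DataFrame) -> pd.DataFrame:
    """Per-color mean and standard error over replicate images.

    Accepts either :class:`AlbedoEstimate` objects or a DataFrame with
    ``label`` and ``albedo_abs`` columns. With a single replicate the mean is
    returned and the SE is NaN (flagged undefined).
    """
    if isinstance(estimates, pd.DataFrame):
        df = estimates
    else:
        df = estimates_to_frame(list(estimates))
    if df.empty:
        raise ValueError("no estimates to summarize")
    grouped = df.groupby("label")["albedo_abs"]
    out = grouped.agg(k="count", mean="mean", sd=lambda v: v.std(ddof=1))
    out["se"] = out["sd"] / np.sqrt(out["k"])
    return out.reset_index()[["label", "k", "mean", "se"]]


def estimates_to_frame(estimates: Sequence[AlbedoEstimate]) -> pd.DataFrame:
    """Tabulate albedo estimates (one row per region per image)."""
    return pd.DataFrame(
        {
            "image_id": [e.image_id for e in estimates],
            "label": [e.label for e in estimates],
            "albedo_rel": [e.albedo_rel for e in estimates],
            "albedo_abs": [e.albedo_abs for e in estimates],
            "snow_ref": [e.snow_ref for e in estimates],
        }
    )


class SnowReferencedAlbedo(BaseEstimator):
    """Estimator wrapper around snow-referenced albedo scoring.

    Parameters
    ----------
    snow_ref : float, default 0.85
        Assumed albedo of the in-scene fresh-snow reference.
    gray_weights : sequence of 3 floats or None, default None
        Channel weights for RGB-to-gray conversion; ``None`` means the
        unweighted channel mean.

    Attributes
    ----------
    estimates_ : list of AlbedoEstimate
        One estimate per labeled region per fitted image.
    summaries_ : dict
        ``(image_id, region)`` -> :class:`PixelSummary`.
    replicate_summary_ : pandas.DataFrame
        Per-color mean and SE across the fitted images.
    """

    def __init__(self, snow_ref: float = SNOW_REFERENCE_ALBEDO, gray_weights=None):
        self.snow_ref = snow_ref
        self.gray_weights = gray_weights

    def fit(self, images, masks, image_ids=None):
        """Estimate albedos for one image or a list of replicate images.

        ``images`` may be a single 2-D gray (or 3-channel) array or a sequence
        of them; ``masks`` a matching :class:`RegionMaskSet` or sequence.
        """
        if isinstance(images, np.ndarray):
            images = [images]
            masks = [masks]
        if image_ids is None:
            image_ids = [f"image{i}" for i in range(len(images))]
        if not len(images) == len(masks) == len(image_ids):
            raise ValueError("images, masks and image_ids must have equal length")
        self.estimates_ = []
        self.summaries_ = {}
        for image, mask_set, image_id in zip(images, masks, image_ids):
            image = np.asarray(image)
            if image.ndim == 3:
                image = to_gray(image, self.gray_weights)
            self.estimates_.extend(
                estimate_image_albedos(image, mask_set, self.snow_ref, image_id)
            )
            for name in mask_set.region_names:
                self.summaries_[(image_id, name)] = pixel_summary(
                    image, mask_set.mask(name)
                )
        self.replicate_summary_ = summarize_replicates(self.estimates_)
        return self


# ---------------------------------------------------------------------------
# File plumbing: 8-bit PNG/TIFF images and label-mask PNGs with a YAML sidecar
# ---------------------------------------------------------------------------

def read_image(path: str | Path, gray_weights=None) -> np.ndarray:
    """Read a PNG/TIFF image as a 2-D gray array, converting RGB if needed."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = to_gray(arr[..., :3], gray_weights)
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a 2-D uint8 array as an 8-bit grayscale PNG/TIFF."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def read_mask_set(label_path: str | Path, mapping_path: str | Path) -> RegionMaskSet:
    """Read a label-image PNG plus its YAML label->name sidecar."""
    with Image.open(label_path) as img:
        labels = np.asarray(img).astype(np.int64)
    with open(mapping_path) as fh:
        names = {int(k): str(v) for k, v in yaml.safe_load(fh).items()}
    return RegionMaskSet(labels=labels, names=names)


def write_mask_set(label_path: str | Path, mapping_path: str | Path, masks: RegionMaskSet) -> None:
    """Write a label image (8-bit PNG) and its YAML sidecar."""
    if masks.labels.max() > 255:
        raise ValueError("more than 255 regions cannot be stored as 8-bit labels")
    write_image(label_path, masks.labels.astype(np.uint8))
    with open(mapping_path, "w") as fh:
        yaml.safe_dump({int(k): v for k, v in masks.names.items()}, fh, sort_keys=True)
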