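"""Nuclear-channel tissue maps and in/out-of-tissue intensity statistics.

A fluorescence field is split into RGB channels on a 0-1 scale.  The blue
(nuclear, DAPI) channel is converted into a binary "tissue map": percentile
contrast stretch, intensity threshold, removal of small non-nuclei debris,
then morphological closing (dilation followed by erosion) with a disk
structuring element so neighbouring nuclei merge into an approximation of
the underlying tissue.  Signal channels are then averaged inside and outside
that map by logical indexing, and normalized either by tissue area or by a
reference channel's in-tissue mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import exposure, morphology

CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass
class TissueMap:
    """Binary tissue mask plus the parameters that produced it."""

    mask: np.ndarray
    threshold: float
    min_size: int
    disk_radius: int
    stretch_percentiles: tuple[float, float] = (1.0, 99.0)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionIntensity:
    """Mean channel intensity inside/outside a tissue mask (0-1 scale).

    An empty region is flagged undefined (mean NaN) rather than raising.
    """

    inside_mean: float
    outside_mean: float
    inside_pixels: int
    outside_pixels: int

    @property
    def inside_defined(self) -> bool:
        return self.inside_pixels > 0

    @property
    def outside_defined(self) -> bool:
        return self.outside_pixels > 0


def split_channels(
    image: np.ndarray, channel_map: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Split an RGB image into {red, green, blue} float arrays in [0, 1].

    Integer images are divided by their dtype maximum (255 for 8-bit, 65535
    for 16-bit).  ``channel_map`` overrides the channel -> index assignment,
    e.g. for stacks stored in a different order.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an HxWxC image with at least 3 channels")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(image.dtype).max
    else:
        arr = arr.astype(float)
    mapping = dict(channel_map or CHANNEL_INDEX)
    out = {name: arr[:, :, idx] for name, idx in mapping.items()}
    shapes = {a.shape for a in out.values()}
    if len(shapes) != 1:
        raise ValueError("channel shapes do not match")
    return out


def build_dapi_map(
    blue_channel: np.ndarray,
    threshold: float = 0.15,
    min_size: int = 50,
    disk_radius: int = 25,
    stretch_percentiles: tuple[float, float] = (1.0, 99.0),
) -> TissueMap:
    """Tissue map from the nuclear channel.

    Pipeline: percentile contrast stretch (saturation balance) -> binarize
    at ``threshold`` -> drop connected components smaller than ``min_size``
    (8-connectivity) -> morphological closing (dilate then erode) with a
    disk of ``disk_radius`` to connect nuclei blobs into a tissue
    approximation.
    """
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    chan = np.asarray(blue_channel, dtype=float)
    lo, hi = np.percentile(chan, stretch_percentiles)
    if hi > lo:
        stretched = exposure.rescale_intensity(chan, in_range=(lo, hi), out_range=(0.0, 1.0))
    else:  # flat channel: nothing to stretch, threshold the raw values
        stretched = np.clip(chan, 0.0, 1.0)
    binary = stretched > threshold
    if min_size > 0:
        try:  # skimage >= 0.26 renamed the size threshold (inclusive semantics)
            binary = morphology.remove_small_objects(
                binary, max_size=min_size - 1, connectivity=2
            )
        except TypeError:  # pragma: no cover - older scikit-image
            binary = morphology.remove_small_objects(
                binary, min_size=min_size, connectivity=2
            )
    if disk_radius > 0:
        binary = morphology.closing(binary, morphology.disk(disk_radius)).astype(bool)
    return TissueMap(
        mask=binary,
        threshold=threshold,
        min_size=min_size,
        disk_radius=disk_radius,
        stretch_percentiles=tuple(stretch_percentiles),
    )


def binarize_stretched(
    blue_channel: np.ndarray,
    threshold: float,
    stretch_percentiles: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """The pre-morphology stage of the tissue map (stretch + threshold).

    Exposed separately because thresholding is monotone: raising the
    threshold can only remove pixels before the morphology steps.
    """
    tm = build_dapi_map(
        blue_channel, threshold, min_size=0, disk_radius=0,
        stretch_percentiles=stretch_percentiles,
    )
    return tm.mask


def region_mean_intensity(channel: np.ndarray, tissue_map: TissueMap) -> RegionIntensity:
    """Arithmetic channel means inside and outside the tissue mask."""
    chan = np.asarray(channel, dtype=float)
    mask = tissue_map.mask
    if chan.shape != mask.shape:
        raise ValueError(
            f"channel shape {chan.shape} does not match mask shape {mask.shape}"
        )
    n_in = int(mask.sum())
    n_out = int(mask.size - n_in)
    inside = float(chan[mask].mean()) if n_in else float("nan")
    outside = float(chan[~mask].mean()) if n_out else float("nan")
    return RegionIntensity(inside, outside, n_in, n_out)


def normalized_signal(
    region: RegionIntensity,
    reference: TissueMap | RegionIntensity,
    mode: str = "area",
) -> float:
    """Normalize an in-tissue signal by tissue area or a reference channel.

    ``mode='area'``: summed in-tissue signal / tissue area — identical to
    the in-tissue mean.  ``mode='reference'``: in-tissue mean(signal) /
    in-tissue mean(reference channel).  A zero or empty reference yields
    NaN (flagged undefined) rather than raising.
    """
    if mode == "area":
        if not isinstance(reference, TissueMap):
            raise TypeError("mode='area' requires a TissueMap reference")
        if reference.area == 0 or not region.inside_defined:
            return float("nan")
        return region.inside_mean
    if mode == "reference":
        if not isinstance(reference, RegionIntensity):
            raise TypeError("mode='reference' requires a RegionIntensity reference")
        if not reference.inside_defined or reference.inside_mean == 0:
            return float("nan")
        return region.inside_mean / reference.inside_mean
    raise ValueError(f"unknown normalization mode {mode!r}")


def paired_region_report(
    images: Sequence[np.ndarray],
    masks: Sequence[TissueMap],
    channels: Sequence[str] = ("red", "green"),
    image_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-image in/out mean intensities for paired testing.

    One row per (image, channel, region); ``undefined`` flags empty
    regions.  Feed the (in - out) pairs to a paired t-test downstream.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    ids = list(image_ids) if image_ids is not None else [f"image_{i}" for i in range(len(images))]
    rows = []
    for image_id, image, tissue in zip(ids, images, masks):
        split = split_channels(image)
        for channel in channels:
            region = region_mean_intensity(split[channel], tissue)
            for name, mean, defined in (
                ("inside", region.inside_mean, region.inside_defined),
                ("outside", region.outside_mean, region.outside_defined),
            ):
                rows.append(
                    {
                        "image": image_id,
                        "channel": channel,
                        "region": name,
                        "mean_intensity": mean,
                        "undefined": not defined,
                    }
                )
    return pd.DataFrame(rows)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap between two binary masks (1.0 when both are empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
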