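"""Nuclei segmentation from H&E patches.

The pipeline mirrors classical marker-controlled watershed segmentation of
hematoxylin-dark nuclei: the hematoxylin single-stain image (from
:mod:`nucleiclust.stains`) is converted to HSI color space, the saturation
channel — where chromatin is the most salient structure — is contrast
stretched and thresholded with Otsu's method, touching nuclei are split by a
watershed seeded at distance-transform maxima, and small artifacts are removed
with a closing/opening cleanup. The result is a labeled mask plus per-nucleus
centroids, which downstream modules treat as graph vertices.

All stage parameters live in :class:`SegmentationConfig`; the composition is
deterministic for a fixed input and config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import closing, disk, opening
from skimage.segmentation import watershed

from .stains import StainMatrix, StainStats, deconvolve_stains, normalize_stain, reconstruct_stain_image, rgb_to_od


class SegmentationError(ValueError):
    pass


@dataclass
class NucleusSet:
    """Segmented nuclei: integer label mask plus centroids and areas.

    ``label_mask`` uses 0 for background and 1..n for nuclei; ``centroids``
    is an (n, 2) array of (row, col) pixel-center coordinates, 0-based;
    ``areas[k]`` is the pixel count of label k+1.
    """

    label_mask: np.ndarray
    centroids: np.ndarray
    areas: np.ndarray

    def __len__(self) -> int:
        return len(self.centroids)

    @classmethod
    def from_label_mask(cls, label_mask: np.ndarray) -> "NucleusSet":
        """Relabel consecutively and compute centroids/areas."""
        label_mask = np.asarray(label_mask)
        props = regionprops(label_mask)
        out = np.zeros_like(label_mask, dtype=np.int32)
        centroids, areas = [], []
        for new_label, p in enumerate(props, start=1):
            out[label_mask == p.label] = new_label
            centroids.append(p.centroid)
            areas.append(p.area)
        return cls(
            label_mask=out,
            centroids=np.asarray(centroids, dtype=float).reshape(-1, 2),
            areas=np.asarray(areas, dtype=int),
        )


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation stages.

    contrast_low/high: percentile limits of the linear stretch (default 1/99).
    min_area: objects below this pixel count are discarded (default 30 px).
    se_radius: disc structuring-element radius of closing/opening (default 2).
    min_peak_separation: minimum pixel distance between watershed markers
        (distance-transform maxima, default 7).
    stain_matrix: H&E color matrix used to isolate the hematoxylin channel.
    """

    contrast_low: float = 1.0
    contrast_high: float = 99.0
    min_area: int = 30
    se_radius: int = 2
    min_peak_separation: int = 7
    stain_matrix: StainMatrix = field(default_factory=StainMatrix.default)


def rgb_to_hsi(rgb_image: np.ndarray) -> np.ndarray:
    """Classical HSI conversion.

    Returns a float array with H in degrees [0, 360), S in [0, 1], and I in
    the units of the input (e.g. 0-255 for uint8). For achromatic pixels
    (R=G=B) H and S are 0; a fully black pixel also has S = 0.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise SegmentationError(f"expected RGB image, got shape {rgb.shape}")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    intensity = total / 3.0

    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        cos_t = np.where(den > 0, num / den, 1.0)
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    hue = np.where(b <= g, theta, 360.0 - theta)
    hue = np.where(den > 0, hue, 0.0)
    return np.stack([hue, sat, intensity], axis=-1)


def adjust_contrast(
    channel_image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Linear percentile stretch of a single-channel 8-bit image.

    The low/high percentile intensities map to 0/255; values outside clip.
    A constant image is returned unchanged (no stretch is possible).
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise SegmentationError("require 0 <= low_pct < high_pct <= 100")
    img = np.asarray(channel_image, dtype=float)
    lo, hi = np.percentile(img, [low_pct, high_pct])
    if hi <= lo:
        return np.asarray(channel_image)
    stretched = (img - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(stretched), 0, 255).astype(np.uint8)


def global_threshold(channel_image: np.ndarray) -> np.ndarray:
    """Binarize with Otsu's criterion; foreground = above-threshold pixels.

    Nuclei are the high-saturation structures of the hematoxylin image, so
    foreground polarity is bright. A constant image yields an empty mask
    (with a warning) since no threshold separates anything.
    """
    img = np.asarray(channel_image)
    if img.min() == img.max():
        warnings.warn("constant image: empty foreground", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def split_touching_nuclei(binary_mask: np.ndarray, min_peak_separation: int = 7) -> np.ndarray:
    """Separate touching objects with a marker-controlled watershed.

    Markers are local maxima of the Euclidean distance transform (minimum
    separation ``min_peak_separation``); the watershed floods the negated
    distance transform within the foreground. Every foreground pixel receives
    exactly one label; components that produced no marker (smaller than the
    peak footprint) keep a single label of their own.
    """
    mask = np.asarray(binary_mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    components, _ = ndi.label(mask)
    peaks = peak_local_max(
        distance,
        min_distance=min_peak_separation,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers=markers, mask=mask).astype(np.int32)
    # components whose peak footprint was empty: keep them as whole objects
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover)
        labels[leftover] = extra[leftover] + labels.max()
    return labels


def clean_mask(label_mask: np.ndarray, min_area: int = 30, se_radius: int = 2) -> NucleusSet:
    """Remove small objects and smooth boundaries per object.

    Objects with area < ``min_area`` are discarded; each survivor is closed
    then opened with a disc of radius ``se_radius`` within its own padded
    bounding box (so adjacent objects cannot merge), then the area filter is
    re-applied and labels are renumbered consecutively.
    """
    label_mask = np.asarray(label_mask)
    selem = disk(se_radius)
    pad = se_radius + 1
    out = np.zeros_like(label_mask, dtype=np.int32)
    next_label = 0
    for p in regionprops(label_mask):
        if p.area < min_area:
            continue
        r0, c0, r1, c1 = p.bbox
        box = np.zeros((r1 - r0 + 2 * pad, c1 - c0 + 2 * pad), dtype=bool)
        box[pad:-pad, pad:-pad] = p.image
        smoothed = opening(closing(box, selem), selem)
        smoothed = smoothed[pad:-pad, pad:-pad]
        if smoothed.sum() < min_area:
            continue
        next_label += 1
        rows, cols = np.nonzero(smoothed)
        target = out[r0:r1, c0:c1]
        target[rows, cols] = next_label
    return NucleusSet.from_label_mask(out)


def segment_nuclei(
    rgb_patch: np.ndarray,
    config: SegmentationConfig | None = None,
    reference_stats: StainStats | None = None,
) -> NucleusSet:
    """Full segmentation pipeline on one RGB patch.

    Stages: (optional) stain normalization against ``reference_stats`` →
    OD transform → hematoxylin deconvolution → single-stain re-rendering →
    HSI saturation channel → percentile contrast stretch → Otsu threshold →
    pre-watershed small-object removal → marker-controlled watershed →
    closing/opening cleanup with the area filter re-applied.
    """
    config = config or SegmentationConfig()
    rgb = np.asarray(rgb_patch)
    if reference_stats is not None:
        rgb = normalize_stain(rgb, reference_stats)
    od = rgb_to_od(rgb)
    conc_h, _ = deconvolve_stains(od, config.stain_matrix)
    h_image = reconstruct_stain_image(conc_h, config.stain_matrix.row_h)
    saturation = rgb_to_hsi(h_image)[..., 1]
    sat_u8 = np.clip(np.rint(saturation * 255.0), 0, 255).astype(np.uint8)
    adjusted = adjust_contrast(sat_u8, config.contrast_low, config.contrast_high)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # blank patches are a valid input
        binary = global_threshold(adjusted)
    # small artifacts are removed both before and after the watershed
    binary = _remove_small(binary, config.min_area)
    labels = split_touching_nuclei(binary, config.min_peak_separation)
    return clean_mask(labels, config.min_area, config.se_radius)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labeled, n = ndi.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(labeled.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labeled]
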