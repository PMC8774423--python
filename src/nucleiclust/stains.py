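"""Stain-color preprocessing for H&E histopathology patches.

Two operations live here. The first is a modified Reinhard color transfer:
source and reference images are taken to CIE LAB, and each source channel is
rescaled by the ratio of reference to source standard deviation and re-centred
on the average of the pixel value and the reference channel mean,

    out = (x - mean_src) * (std_ref / std_src) + (x + mean_ref) / 2.

Note the last term: it mixes the *pixel value* with the reference mean instead
of substituting the reference mean outright, so — unlike classical Reinhard —
normalizing an image against its own statistics is NOT the identity map. This
is deliberate and matches the transfer rule this pipeline is built around;
callers who want classical behaviour should use a different tool.

The second is optical-density stain separation (color deconvolution): RGB
intensities are converted to optical density, OD = -log10(I / 255), and each
pixel's OD vector is decomposed onto known hematoxylin and eosin stain color
vectors by least squares. Single-stain images are re-rendered through the
Beer-Lambert law, I_c = 255 * 10^(-conc * stain_c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor

#: Background brightfield intensity (8-bit white).
IO = 255.0

#: Default H&E stain color matrix (rows are unit-norm RGB OD directions).
DEFAULT_STAIN_MATRIX = np.array(
    [
        [0.587, 0.754, 0.294],  # hematoxylin
        [0.136, 0.833, 0.536],  # eosin
    ]
)


class StainError(ValueError):
    """Raised for degenerate images or stain matrices."""


@dataclass(frozen=True)
class StainStats:
    """Per-channel LAB means and standard deviations of an image.

    LAB conversion follows the CIE LAB / D65 convention of scikit-image;
    L is in [0, 100], a and b are roughly in [-128, 127].
    """

    mean_l: float
    mean_a: float
    mean_b: float
    std_l: float
    std_a: float
    std_b: float

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_l, self.mean_a, self.mean_b])

    @property
    def stds(self) -> np.ndarray:
        return np.array([self.std_l, self.std_a, self.std_b])


@dataclass(frozen=True)
class StainMatrix:
    """Hematoxylin and eosin RGB optical-density color vectors."""

    row_h: np.ndarray
    row_e: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_h", np.asarray(self.row_h, dtype=float))
        object.__setattr__(self, "row_e", np.asarray(self.row_e, dtype=float))
        if self.row_h.shape != (3,) or self.row_e.shape != (3,):
            raise StainError("stain rows must be 3-vectors of RGB OD components")
        m = np.stack([self.row_h, self.row_e])
        if np.linalg.matrix_rank(m) < 2:
            raise StainError("stain rows are collinear; deconvolution is singular")

    @classmethod
    def default(cls) -> "StainMatrix":
        return cls(DEFAULT_STAIN_MATRIX[0], DEFAULT_STAIN_MATRIX[1])

    def as_array(self) -> np.ndarray:
        return np.stack([self.row_h, self.row_e])


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise StainError(f"expected an H x W x 3 RGB image, got shape {image.shape}")
    return image


def compute_lab_stats(rgb_image: np.ndarray) -> StainStats:
    """Channel means and standard deviations of an RGB image in LAB space.

    Standard deviations are population (ddof=0) values over all pixels.
    """
    rgb = _check_rgb(rgb_image)
    lab = _skcolor.rgb2lab(rgb).reshape(-1, 3)
    means = lab.mean(axis=0)
    stds = lab.std(axis=0)
    stds[np.ptp(lab, axis=0) == 0] = 0.0  # constant channels have no spread
    return StainStats(*means, *stds)


def normalize_stain(source_rgb: np.ndarray, reference_stats: StainStats) -> np.ndarray:
    """Transfer the reference image's LAB statistics onto a source image.

    Per channel X: out = (X - mean_src) * (std_ref/std_src) + (X + mean_ref)/2,
    channels re-stacked and converted back to 8-bit RGB with clipping.

    Raises :class:`StainError` if any source channel has zero spread (the
    rescaling is undefined on a constant channel).
    """
    rgb = _check_rgb(source_rgb)
    if rgb.size == 0:
        raise StainError("empty source image")
    src = compute_lab_stats(rgb)
    if np.any(src.stds == 0):
        raise StainError("source image has a constant LAB channel; cannot normalize")
    if np.any(reference_stats.stds <= 0):
        raise StainError("reference stats must have strictly positive stds")

    lab = _skcolor.rgb2lab(rgb)
    gain = src.stds  # broadcast below
    out = (lab - src.means) * (reference_stats.stds / gain) + (lab + reference_stats.means) / 2.0
    with warnings.catch_warnings():
        # out-of-gamut LAB values are clipped by design
        warnings.filterwarnings("ignore", message=".*negative Z values.*")
        rgb_out = _skcolor.lab2rgb(out)
    return np.clip(np.rint(rgb_out * 255.0), 0, 255).astype(np.uint8)


def transfer_channel(
    x: np.ndarray | float,
    mean_src: float,
    std_src: float,
    mean_ref: float,
    std_ref: float,
) -> np.ndarray | float:
    """The per-channel transfer rule, exposed for direct evaluation.

    out = (x - mean_src) * (std_ref/std_src) + (x + mean_ref)/2
    """
    if std_src == 0:
        raise StainError("source channel has zero standard deviation")
    return (x - mean_src) * (std_ref / std_src) + (x + mean_ref) / 2.0


def rgb_to_od(rgb_image: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB intensities to optical density.

    OD = -log10(clamp(I, 1, 255) / 255). The clamp at 1 bounds the OD of a
    fully dark pixel at -log10(1/255) ~ 2.4065 instead of infinity.
    """
    rgb = _check_rgb(rgb_image).astype(float)
    clamped = np.clip(rgb, 1.0, IO)
    return -np.log10(clamped / IO)


def deconvolve_stains(
    od: np.ndarray, matrix: StainMatrix | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split an OD image into hematoxylin and eosin concentration maps.

    Each pixel's OD 3-vector is projected onto the two stain color vectors by
    least squares: (c_H, c_E) minimizes ||c_H row_H + c_E row_E - OD||^2.
    Returns ``(conc_h, conc_e)`` with the spatial shape of ``od``.
    """
    matrix = matrix or StainMatrix.default()
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise StainError("OD image must have 3 channels")
    # pinv of the 3x2 mixing matrix gives the per-pixel least-squares solution
    mixing = matrix.as_array().T  # 3 x 2
    solver = np.linalg.pinv(mixing)  # 2 x 3
    conc = od.reshape(-1, 3) @ solver.T
    conc = conc.reshape(od.shape[:-1] + (2,))
    return conc[..., 0], conc[..., 1]


def reconstruct_stain_image(conc: np.ndarray, stain_row: np.ndarray) -> np.ndarray:
    """Render a single-stain RGB image from a concentration map.

    Beer-Lambert with the base-10 OD convention: I_c = 255 * 10^(-conc * row_c),
    clipped to [0, 255]. Negative concentrations (least-squares artifacts) are
    clipped to 0 first.
    """
    conc = np.clip(np.asarray(conc, dtype=float), 0.0, None)
    row = np.asarray(stain_row, dtype=float).reshape(3)
    image = IO * np.power(10.0, -conc[..., None] * row)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)
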