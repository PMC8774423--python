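"""Synthetic H&E-like patches and cluster-feature tables.

The patch generator emulates the geometry this pipeline measures: elliptical
hematoxylin-dark nuclei grouped in spatial clusters on an eosin-pink
background, with ground-truth label masks and centroids. Colors are rendered
through the same Beer-Lambert stain model the deconvolution stage inverts
(nuclei at hematoxylin concentration ~1, background at a weak eosin
concentration), so the stain stages are exercised meaningfully. Grade presets
vary cluster count, density and compactness qualitatively — grade 3 as few
loose clusters, grade 4 as more and denser clusters, grade 5 as many dense
sheets; they emulate architectural trends, not real tissue.

The feature-table generator draws 26-dimensional per-class Gaussians with a
controllable per-feature effect size, for testing the selection and
classification stages without any image processing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .features import feature_names
from .stains import DEFAULT_STAIN_MATRIX, IO


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PatchSpec:
    """Geometry, color and noise of one synthetic patch.

    Distances in pixels. ``cluster_spread`` is the cluster radius: member
    nuclei are placed uniformly in a disc of this radius around the cluster
    center, so two clusters whose centers are >= separation apart have no
    member pair closer than separation - 2*spread.
    ``min_cluster_separation`` keeps cluster centers apart. ``hematoxylin_conc``/``eosin_conc`` set nucleus
    and background color through the Beer-Lambert stain model. With
    ``allow_overlap=False`` nuclei are rejection-sampled to stay disjoint.
    The seed fully determines the output.
    """

    size: int = 512
    n_clusters: int = 5
    nuclei_per_cluster: tuple[int, int] = (6, 10)
    cluster_spread: float = 32.0
    min_cluster_separation: float = 160.0
    radius_range: tuple[float, float] = (5.0, 9.0)
    hematoxylin_conc: float = 1.0
    eosin_conc: float = 0.25
    noise_sigma: float = 4.0
    allow_overlap: bool = False
    max_tries: int = 5000
    seed: int = 0


#: Qualitative grade presets (documentation aids, not claims about tissue).
GRADE_PRESETS: dict[str, PatchSpec] = {
    "grade3": PatchSpec(n_clusters=4, nuclei_per_cluster=(6, 10), cluster_spread=36.0,
                        min_cluster_separation=180.0),
    "grade4": PatchSpec(n_clusters=7, nuclei_per_cluster=(6, 9), cluster_spread=30.0,
                        min_cluster_separation=150.0, radius_range=(4.0, 8.0)),
    "grade5": PatchSpec(n_clusters=10, nuclei_per_cluster=(7, 10), cluster_spread=24.0,
                        min_cluster_separation=120.0, radius_range=(4.0, 6.0)),
}


def grade_preset(name: str, **overrides) -> PatchSpec:
    if name not in GRADE_PRESETS:
        raise GenerationError(f"unknown preset {name!r}; choose from {sorted(GRADE_PRESETS)}")
    return replace(GRADE_PRESETS[name], **overrides)


def _stain_color(conc_h: float, conc_e: float) -> np.ndarray:
    od = conc_h * DEFAULT_STAIN_MATRIX[0] + conc_e * DEFAULT_STAIN_MATRIX[1]
    return IO * np.power(10.0, -od)


def generate_patch(spec: PatchSpec) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render one synthetic patch.

    Returns ``(rgb, label_mask, centroids)``: an 8-bit RGB image, an integer
    ground-truth mask (0 background, k = nucleus k), and a centroid table
    with columns label, row, col, cluster.

    Cluster centers are sampled uniformly in-bounds with minimum pairwise
    separation; member nuclei are rotated filled ellipses placed uniformly
    in a disc around their center. Raises :class:`GenerationError` when the
    requested geometry cannot be packed within ``max_tries`` rejections.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    background = _stain_color(0.0, spec.eosin_conc)
    nucleus_color = _stain_color(spec.hematoxylin_conc, spec.eosin_conc * 0.4)

    rgb = np.ones((size, size, 3)) * background
    mask = np.zeros((size, size), dtype=np.int32)
    records = []

    margin = spec.radius_range[1] + 2
    centers = []
    tries = 0
    while len(centers) < spec.n_clusters:
        if tries > spec.max_tries:
            raise GenerationError("could not place cluster centers with the requested separation")
        tries += 1
        cand = rng.uniform(margin + spec.cluster_spread, size - margin - spec.cluster_spread, 2)
        if all(np.linalg.norm(cand - c) >= spec.min_cluster_separation for c in centers):
            centers.append(cand)

    label = 0
    placed: list[tuple[np.ndarray, float]] = []  # (center, radius) of placed nuclei
    for cluster_id, center in enumerate(centers):
        n_members = int(rng.integers(spec.nuclei_per_cluster[0], spec.nuclei_per_cluster[1] + 1))
        members = 0
        tries = 0
        while members < n_members:
            if tries > spec.max_tries:
                raise GenerationError(
                    f"could not pack {n_members} disjoint nuclei in cluster {cluster_id}"
                )
            tries += 1
            radius = spec.cluster_spread * np.sqrt(rng.uniform())
            angle = rng.uniform(0.0, 2.0 * np.pi)
            pos = center + radius * np.array([np.cos(angle), np.sin(angle)])
            r_a = rng.uniform(*spec.radius_range)
            r_b = rng.uniform(*spec.radius_range)
            rad = max(r_a, r_b)
            if not (margin <= pos[0] < size - margin and margin <= pos[1] < size - margin):
                continue
            if not spec.allow_overlap and any(
                np.linalg.norm(pos - p) < rad + pr + 1.0 for p, pr in placed
            ):
                continue
            rot = rng.uniform(0.0, np.pi)
            rr, cc = ellipse(pos[0], pos[1], r_a, r_b, shape=(size, size), rotation=rot)
            if len(rr) == 0:
                continue
            label += 1
            mask[rr, cc] = label
            rgb[rr, cc] = nucleus_color
            placed.append((pos, rad))
            records.append(
                {"label": label, "row": float(rr.mean()), "col": float(cc.mean()), "cluster": cluster_id}
            )
            members += 1

    rgb = rgb + rng.normal(0.0, spec.noise_sigma, rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    centroids = pd.DataFrame(records, columns=["label", "row", "col", "cluster"])
    return rgb, mask, centroids


def generate_feature_table(
    n_per_class: int,
    class_means: np.ndarray,
    class_sds: np.ndarray,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw balanced per-class Gaussian feature tables.

    ``class_means``/``class_sds`` are (n_classes, 26); rows are clipped at 0
    (distances, areas and counts are non-negative). Returns a DataFrame with
    the 26 canonical feature columns and an integer grade label per row.
    """
    means = np.atleast_2d(np.asarray(class_means, dtype=float))
    sds = np.atleast_2d(np.asarray(class_sds, dtype=float))
    if means.shape != sds.shape or means.shape[1] != 26:
        raise GenerationError("class_means and class_sds must both be (n_classes, 26)")
    if n_per_class < 1:
        raise GenerationError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c in range(means.shape[0]):
        blocks.append(np.clip(rng.normal(means[c], sds[c], size=(n_per_class, 26)), 0.0, None))
        labels.extend([c] * n_per_class)
    table = pd.DataFrame(np.vstack(blocks), columns=feature_names())
    return table, np.asarray(labels)


#: Baseline feature magnitudes for a 512 px patch: distances tens-to-hundreds
#: of px, areas thousands of px^2, ~8 clusters. One value per feature family.
_BASE_MEANS = {
    "distance_total": 600.0,
    "distance_avg": 60.0,
    "area_total": 20000.0,
    "area_single": 3000.0,
    "count": 8.0,
}


def default_class_means(
    effect_size: float, n_classes: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class mean/sd matrices with a given per-feature effect size.

    Each feature's baseline mean depends on its family (totals, averages,
    areas, count) with sd = 15% of the baseline; class c's mean is shifted by
    ``c * effect_size * sd`` — a monotone grade effect with univariate
    Cohen's d = ``effect_size`` between adjacent grades in every feature.
    ``effect_size=0`` gives identically distributed classes.
    """
    base = []
    for name in feature_names():
        if name == "number of clusters":
            base.append(_BASE_MEANS["count"])
        elif "total" in name and "area" not in name:
            base.append(_BASE_MEANS["distance_total"])
        elif name == "total cluster area":
            base.append(_BASE_MEANS["area_total"])
        elif "area" in name:
            base.append(_BASE_MEANS["area_single"])
        else:
            base.append(_BASE_MEANS["distance_avg"])
    base = np.asarray(base)
    sds = 0.15 * base
    means = np.stack([base + c * effect_size * sds for c in range(n_classes)])
    return means, np.tile(sds, (n_classes, 1))
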