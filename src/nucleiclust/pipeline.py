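"""End-to-end orchestration: images in, classification report out.

``run_pipeline`` ties the stages together — stain normalization, hematoxylin
deconvolution, nuclei segmentation, MST cluster analysis, the 26-feature
descriptor, majority-voting feature selection and (when labels are present)
supervised + unsupervised classification. Every intermediate artifact (masks,
centroid tables, graph edge lists, cluster assignments, vote matrix, metric
tables) is persisted in the output directory, and a manifest records the
config hash, seeds and per-stage counts so any stage can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import classify as _classify
from .features import extract_features, feature_names
from .mstcluster import build_mst, cut_edges
from .segment import SegmentationConfig, segment_nuclei
from .select import DEFAULT_K_SELECT, DEFAULT_MIN_VOTES, build_vote_matrix, tally_votes
from .stains import DEFAULT_STAIN_MATRIX, StainMatrix, compute_lab_stats

CONFIG_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, image_id: str | None, message: str):
        self.stage = stage
        self.image_id = image_id
        where = f" [image {image_id}]" if image_id else ""
        super().__init__(f"stage '{stage}'{where}: {message}")


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, JSON-round-trippable."""

    version: int = CONFIG_VERSION
    stain_matrix: list = field(default_factory=lambda: DEFAULT_STAIN_MATRIX.tolist())
    contrast_low: float = 1.0
    contrast_high: float = 99.0
    min_area: int = 30
    se_radius: int = 2
    min_peak_separation: int = 7
    cut_mode: str = "threshold"
    cut_value: float = 10.0
    k_select: int = DEFAULT_K_SELECT
    min_votes: int = DEFAULT_MIN_VOTES
    seed: int = 0
    test_size: float = 0.2
    n_splits: int = 5
    reference_image: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    def segmentation_config(self) -> SegmentationConfig:
        m = np.asarray(self.stain_matrix, dtype=float)
        return SegmentationConfig(
            contrast_low=self.contrast_low,
            contrast_high=self.contrast_high,
            min_area=self.min_area,
            se_radius=self.se_radius,
            min_peak_separation=self.min_peak_separation,
            stain_matrix=StainMatrix(m[0], m[1]),
        )


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Label masks go out as 16-bit single-channel PNG/TIFF."""
    Image.fromarray(np.asarray(mask, dtype=np.uint16)).save(path)


def run_pipeline(
    image_dir: str | Path,
    labels: dict[str, int] | None,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run every stage over a directory of PNG/TIFF patches.

    ``labels`` maps image stem -> integer grade (None for the unsupervised
    path alone; selection and classification need labels). Returns a dict
    with the feature table, vote matrix (or None) and metric tables, all of
    which are also written under ``out_dir``.
    """
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise PipelineError("input", None, f"no PNG/TIFF images found in {image_dir}")

    seg_config = config.segmentation_config()
    reference_stats = None
    if config.reference_image:
        reference_stats = compute_lab_stats(read_image(config.reference_image))

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "images": {},
    }
    rows = []
    for path in paths:
        image_id = path.stem
        try:
            nuclei = segment_nuclei(read_image(path), seg_config, reference_stats)
            write_mask(nuclei.label_mask, out_dir / f"{image_id}_mask.png")
            pd.DataFrame(
                {
                    "label": np.arange(1, len(nuclei) + 1),
                    "row": nuclei.centroids[:, 0] if len(nuclei) else [],
                    "col": nuclei.centroids[:, 1] if len(nuclei) else [],
                    "area": nuclei.areas,
                }
            ).to_csv(out_dir / f"{image_id}_centroids.csv", index=False)
            if len(nuclei) == 0:
                raise PipelineError("segment", image_id, "no nuclei found")
            mst = build_mst(nuclei.centroids)
            clusters = cut_edges(mst, config.cut_mode, config.cut_value)
            pd.DataFrame(mst.edges, columns=["i", "j", "weight"]).to_csv(
                out_dir / f"{image_id}_mst_edges.csv", index=False
            )
            assignment = np.zeros(len(nuclei), dtype=int)
            for ci, members in enumerate(clusters.clusters):
                assignment[members] = ci
            pd.DataFrame({"label": np.arange(1, len(nuclei) + 1), "cluster": assignment}).to_csv(
                out_dir / f"{image_id}_clusters.csv", index=False
            )
            vector = extract_features(clusters)
            row = dict(zip(feature_names(), vector.values))
            row["image_id"] = image_id
            if labels is not None:
                row["grade"] = labels.get(image_id)
            rows.append(row)
            manifest["images"][image_id] = {
                "n_nuclei": int(len(nuclei)),
                "n_clusters": int(clusters.n_clusters),
            }
        except PipelineError:
            raise
        except Exception as exc:  # abort with stage context
            raise PipelineError("pipeline", image_id, str(exc)) from exc

    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "features.csv", index=False)

    votes = None
    metrics: dict[str, pd.DataFrame] = {}
    if labels is not None and table["grade"].notna().all() and table["grade"].nunique() >= 2:
        x = table[feature_names()]
        y = table["grade"].to_numpy()
        votes = build_vote_matrix(
            x, y, k_select=min(config.k_select, x.shape[1]), min_votes=config.min_votes,
            seed=config.seed,
        )
        votes.to_csv(out_dir / "votes.csv")
        selected, _ = tally_votes(votes, config.min_votes)
        x_selected = x[selected] if selected else x
        counts = table["grade"].value_counts()
        if counts.min() >= config.n_splits * 2:
            supervised = _classify.five_fold_evaluate(
                lambda seed: _StackedFactory(seed),
                x_selected, y, n_splits=config.n_splits, seed=config.seed,
                test_size=config.test_size,
            )
            supervised.to_csv(out_dir / "supervised_metrics.csv")
            metrics["supervised"] = supervised
        if counts.min() >= config.n_splits:
            unsupervised = _classify.kmedoids_evaluate(
                x_selected, y, n_splits=config.n_splits, seed=config.seed
            )
            unsupervised.to_csv(out_dir / "unsupervised_metrics.csv")
            metrics["unsupervised"] = unsupervised

    manifest["n_images"] = len(paths)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"features": table, "votes": votes, "metrics": metrics, "manifest": manifest}


class _StackedFactory:
    """fit/predict adapter giving five_fold_evaluate a stacking ensemble."""

    def __init__(self, seed: int):
        self.seed = seed
        self.model = None

    def fit(self, x, y):
        self.model = _classify.fit_stacked_ensemble(x, y, seed=self.seed)
        return self

    def predict(self, x):
        return self.model.predict(x)
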