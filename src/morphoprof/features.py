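"""Single-cell feature extraction and per-site feature archives.

Two extraction routes:

* a trained 5-channel model — one inference pass per cell; the feature is
  the spatially pooled activation of the model's declared layer (672 dims
  for the EfficientNet-B0 ``block6a_expand_activation`` layer);
* an ImageNet-style 3-channel model via the pseudo-RGB protocol — each of
  the five fluorescence channels is min-max rescaled to [-1, 1], resized to
  224 x 224, replicated to three channels and passed through the network
  separately; the five 672-dim vectors are concatenated into 3,360 dims.

Features are persisted one compressed array file per field of view with a
sidecar index CSV, and row order always equals the site's locations order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn
from .training import TrainedModel, _b0_pooled_features

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "fixed_descriptor_features",
    "pseudo_rgb",
    "extract_pretrained_rgb_features",
    "save_feature_archives",
    "load_feature_archives",
]

PRETRAINED_INPUT_SIZE = 224


@dataclass
class FeatureMatrix:
    """Per-cell feature vectors for one site (or one stacked set of crops)."""

    values: np.ndarray  # (n_cells, d), no missing values
    model_id: str
    layer: str

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def extract_features(
    model: TrainedModel,
    crops: np.ndarray,
    pooling: str = "mean",
    batch_size: int = 64,
) -> FeatureMatrix:
    """One forward pass per cell through the model's declared feature layer.

    ``pooling`` ('mean' or 'max') controls the spatial pooling of the layer
    activation; the toy backbone's feature layer is already pooled. Crops are
    standardized with the statistics fitted at training time.
    """
    crops = model.standardize(crops)
    if model.backbone_name == "toy_cnn":
        net = model.network
        feats = []
        for i in range(0, len(crops), batch_size):
            feats.append(net.features(crops[i : i + batch_size], layer=model.feature_layer))
        values = np.concatenate(feats) if feats else np.zeros((0, net.feature_dim))
    else:
        b0 = model.network[0] if isinstance(model.network, tuple) else model.network
        if pooling == "mean":
            values = _b0_pooled_features(b0, crops, model.feature_layer)
        else:
            feats = []
            for i in range(0, len(crops), 16):
                act = b0.forward_features(crops[i : i + 16], layer=model.feature_layer)
                feats.append(act.max(axis=(1, 2)))
            values = np.concatenate(feats) if feats else np.zeros((0, b0.feature_dim(model.feature_layer)))
    return FeatureMatrix(values=values, model_id=model.backbone_name, layer=model.feature_layer)


def fixed_descriptor_features(
    crops: np.ndarray,
    n_models: int = 3,
    widths: tuple[int, ...] = (8, 16, 32),
    seed: int = 0,
) -> FeatureMatrix:
    """Non-trainable morphology descriptor: pooled random-projection features.

    Concatenates the pooled activations of ``n_models`` untrained CNNs with
    different fixed seeds. Untrained descriptors play the role classical
    engineered features play in screen-scale studies: they are not fitted to
    treatment labels, so they cannot preferentially encode confounders, which
    makes them the right basis for treatment-effect estimation. Multiple
    seeds give the descriptor a more isotropic sensitivity to the different
    axes of morphological change (intensity per channel, cell and nucleus
    size) than any single random projection.
    """
    crops = np.asarray(crops, dtype=np.float32)
    mean = float(crops.mean())
    std = float(crops.std()) + 1e-6
    x = (crops - mean) / std
    blocks = []
    for m in range(n_models):
        net = nn.ToyCNN(
            n_channels=crops.shape[-1],
            n_classes=2,
            widths=widths,
            seed=seed * 1000 + m,
        )
        feats = [net.features(x[i : i + 64]) for i in range(0, len(x), 64)]
        blocks.append(
            np.concatenate(feats) if feats else np.zeros((0, net.feature_dim))
        )
    return FeatureMatrix(
        values=np.concatenate(blocks, axis=1),
        model_id=f"fixed_descriptor_x{n_models}",
        layer=nn.ToyCNN.FEATURE_LAYER,
    )


def pseudo_rgb(channel_image: np.ndarray) -> np.ndarray:
    """Turn one grayscale channel crop into a 224 x 224 x 3 network input.

    Bilinear resize to 224 x 224 first, then min-max rescale and affine map
    to [-1, 1] (so the output attains exactly -1 and 1), then replicate to
    three identical channels. A constant channel maps to all -1 (degenerate
    min-max convention).
    """
    ch = np.asarray(channel_image, dtype=np.float32)
    if ch.ndim != 2:
        raise ValueError("pseudo_rgb expects a single-channel 2-D crop")
    big = resize(ch, (PRETRAINED_INPUT_SIZE, PRETRAINED_INPUT_SIZE), order=1,
                 mode="edge", anti_aliasing=False).astype(np.float32)
    lo, hi = float(big.min()), float(big.max())
    if hi <= lo:
        big = np.full_like(big, -1.0)
    else:
        big = (big - lo) / (hi - lo) * 2.0 - 1.0
    return np.repeat(big[:, :, None], 3, axis=2)


def extract_pretrained_rgb_features(
    pretrained_b0: "nn.EfficientNetB0",
    crops: np.ndarray,
    layer: str | None = None,
) -> FeatureMatrix:
    """Pseudo-RGB feature extraction: five passes per cell, concatenated.

    Each of the 5 channels yields a 672-dim pooled feature; concatenation in
    channel order gives 5 x 672 = 3,360 dims.
    """
    crops = np.asarray(crops)
    if crops.ndim == 3:
        crops = crops[None]
    if crops.shape[-1] != 5:
        raise ValueError(f"expected 5-channel crops, got {crops.shape[-1]} channels")
    layer = layer or pretrained_b0.FEATURE_LAYER
    d = pretrained_b0.feature_dim(layer)
    out = np.zeros((len(crops), 5 * d), dtype=np.float32)
    for i, crop in enumerate(crops):
        for c in range(5):
            x = pseudo_rgb(crop[:, :, c])
            act = pretrained_b0.forward_features(x[None], layer=layer)
            out[i, c * d : (c + 1) * d] = act.mean(axis=(1, 2))[0]
    return FeatureMatrix(values=out, model_id="imagenet_pseudo_rgb", layer=layer)


def save_feature_archives(
    features: np.ndarray,
    cell_index: pd.DataFrame,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write one ``<plate>/<well>_<site>.npz`` per field of view + index CSV.

    ``features`` rows are aligned with ``cell_index`` rows; within each
    archive the row order equals the site's locations order.
    """
    out_dir = Path(out_dir)
    cell_index = cell_index.reset_index(drop=True)
    rows = []
    for (plate, well, site), group in cell_index.groupby(
        ["Metadata_Plate", "Metadata_Well", "Metadata_Site"], sort=True
    ):
        rel = Path(str(plate)) / f"{well}_{site}.npz"
        (out_dir / rel).parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            out_dir / rel,
            features=features[group.index.to_numpy()],
            cell_ids=group["Cell_Id"].to_numpy(),
        )
        rows.append(
            {
                "Metadata_Plate": plate,
                "Metadata_Well": well,
                "Metadata_Site": site,
                "Path": str(rel),
                "n_cells": len(group),
            }
        )
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "feature_index.csv", index=False)
    return index


def load_feature_archives(out_dir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load all archives back; returns (features, cell_ids) in index order."""
    out_dir = Path(out_dir)
    index = pd.read_csv(out_dir / "feature_index.csv")
    feats, ids = [], []
    for row in index.itertuples(index=False):
        with np.load(out_dir / row.Path) as z:
            feats.append(z["features"])
            ids.append(z["cell_ids"])
    if not feats:
        return np.zeros((0, 0)), np.zeros(0, dtype=int)
    return np.concatenate(feats), np.concatenate(ids)
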