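"""Image preprocessing and compression.

The pipeline mirrors the standard high-throughput-microscopy preparation used
before training deep models on Cell Painting screens:

1. fit one illumination correction function per (plate, channel), stored at
   25% of the image height/width;
2. divide each image by the (upsampled) correction surface;
3. stretch the histogram of each individual image by clipping below its 0.05
   and above its 99.95 percentile;
4. quantize 16-bit to 8-bit (an exact 2x reduction of the raw buffer);
5. save as lossless PNG.

The whole pipeline is deterministic — no random number generation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

__all__ = [
    "IlluminationFunction",
    "fit_illumination",
    "apply_illumination",
    "stretch_and_quantize",
    "compress_dataset",
]

ILLUM_SCALE = 0.25  # correction surface stored at 25% of image height/width


@dataclass
class IlluminationFunction:
    """Smoothed, normalized illumination surface for one plate-channel.

    The surface is strictly positive (division-safe) and normalized so its
    robust minimum is 1.0: correction only brightens relatively dark regions.
    """

    plate: str
    channel: int
    surface: np.ndarray  # shape = (round(0.25 H), round(0.25 W))
    target_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if np.any(self.surface <= 0):
            raise ValueError("illumination surface must be strictly positive")

    def upsampled(self) -> np.ndarray:
        return resize(
            self.surface, self.target_shape, order=1, mode="edge", anti_aliasing=False
        )


def fit_illumination(
    images: Sequence[np.ndarray], plate: str = "", channel: int = 0
) -> IlluminationFunction:
    """Fit the per-plate-channel correction surface.

    The per-pixel mean across all images of the plate-channel is downscaled
    to 25% of the height/width, median-filtered (window = 1/4 of the
    downscaled dimension) and Gaussian-smoothed (sigma = window/4) to be
    robust to cells, then rescaled so its robust (1st percentile) minimum is
    1.0.
    """
    images = list(images)
    if len(images) == 0:
        raise ValueError("need at least one image to fit illumination")
    shape = images[0].shape
    for im in images:
        if im.shape != shape:
            raise ValueError(f"image shape mismatch: {im.shape} vs {shape}")
    mean = np.zeros(shape, dtype=float)
    for im in images:
        mean += np.asarray(im, dtype=float)
    mean /= len(images)

    small_shape = (round(ILLUM_SCALE * shape[0]), round(ILLUM_SCALE * shape[1]))
    small = resize(mean, small_shape, order=1, mode="edge", anti_aliasing=True)

    window = max(3, int(round(min(small_shape) / 4)))
    if window % 2 == 0:
        window += 1
    smooth = ndimage.median_filter(small, size=window, mode="nearest")
    smooth = ndimage.gaussian_filter(smooth, sigma=window / 4.0, mode="nearest")

    floor = np.percentile(smooth, 1)
    if floor <= 0:
        floor = max(smooth.max(), 1e-12)
    surface = np.maximum(smooth / floor, 1e-6)
    return IlluminationFunction(plate=plate, channel=channel, surface=surface, target_shape=shape)


def apply_illumination(image: np.ndarray, fn: IlluminationFunction) -> np.ndarray:
    """Divide an image by the upsampled correction surface (float output)."""
    image = np.asarray(image, dtype=float)
    if image.shape != fn.target_shape:
        raise ValueError(
            f"image shape {image.shape} incompatible with illumination "
            f"function fitted for {fn.target_shape}"
        )
    return image / fn.upsampled()


def stretch_and_quantize(
    image: np.ndarray, p_low: float = 0.05, p_high: float = 99.95
) -> np.ndarray:
    """Percentile-stretch one image and quantize it to 8 bits.

    Percentiles are computed on this image alone (linear-interpolation
    definition). Values are clipped to [q_low, q_high], mapped affinely to
    [0, 255] and rounded half-to-even. A constant image maps to all zeros
    (zero-range convention).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if not p_low < p_high:
        raise ValueError("p_low must be < p_high")
    q_low, q_high = np.percentile(image, [p_low, p_high])
    if q_high <= q_low:
        return np.zeros(image.shape, dtype=np.uint8)
    clipped = np.clip(image, q_low, q_high)
    scaled = (clipped - q_low) / (q_high - q_low) * 255.0
    return np.round(scaled).astype(np.uint8)  # numpy rounds half-to-even


def _channel_columns(index: pd.DataFrame) -> list[str]:
    cols = [c for c in index.columns if c.startswith("Channel_") and c.endswith("_Path")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def compress_dataset(
    index: pd.DataFrame,
    root: str | Path,
    out_dir: str | Path,
    use_illumination: bool = True,
    p_low: float = 0.05,
    p_high: float = 99.95,
) -> pd.DataFrame:
    """Run the full fit -> apply -> stretch -> quantize -> PNG pipeline.

    ``index`` is an image index with ``Metadata_Plate`` and per-channel path
    columns relative to ``root``. Returns a manifest mapping each original
    image to its compressed path, with a ``Status`` column; unreadable images
    are logged and skipped (``Status='error'``) rather than aborting the run.
    """
    root = Path(root)
    out_dir = Path(out_dir)
    chan_cols = _channel_columns(index)
    manifest_rows = []

    for plate, plate_group in index.groupby("Metadata_Plate"):
        for chan_col in chan_cols:
            channel = int(chan_col.split("_")[1])
            paths = list(plate_group[chan_col])
            loaded: dict[str, np.ndarray] = {}
            for p in paths:
                try:
                    loaded[p] = tifffile.imread(root / p)
                except Exception:
                    loaded[p] = None  # recorded as error below
            good = [im for im in loaded.values() if im is not None]
            fn = None
            if use_illumination and good:
                fn = fit_illumination(good, plate=str(plate), channel=channel)
            for p in paths:
                im = loaded[p]
                rel_out = Path(p).with_suffix(".png")
                row = {
                    "Metadata_Plate": plate,
                    "Channel": channel,
                    "Original_Path": p,
                    "Compressed_Path": str(rel_out),
                }
                if im is None:
                    row["Status"] = "error"
                    manifest_rows.append(row)
                    continue
                corrected = apply_illumination(im, fn) if fn is not None else np.asarray(im, float)
                quantized = stretch_and_quantize(corrected, p_low=p_low, p_high=p_high)
                (out_dir / rel_out).parent.mkdir(parents=True, exist_ok=True)
                Image.fromarray(quantized, mode="L").save(out_dir / rel_out, format="PNG")
                row["Status"] = "ok"
                manifest_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)
    n_err = int((manifest["Status"] == "error").sum()) if len(manifest) else 0
    manifest.attrs["n_errors"] = n_err
    return manifest
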