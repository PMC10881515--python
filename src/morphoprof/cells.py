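"""Single-cell training corpus construction.

Builds a cell index from an experiment bundle, extracts fixed-size crops
centered on nucleus locations (zero-padded at borders, no resizing, no
masking — the surrounding context is deliberately preserved), creates the two
train/validation split schemes (leave-cells-out and leave-plates-out),
performs median-balanced epoch sampling, applies training augmentations and
assembles multiple-instance-learning bags.

Coordinate convention: 0-based pixel indices, x = column. The crop window for
a center (cx, cy) with size s is the half-open square
[round(cx) - s//2, round(cx) + s - s//2) x (same in y).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .synthetic import ExperimentBundle, load_field

__all__ = [
    "build_cell_index",
    "filter_min_cells",
    "filter_max_concentration",
    "crop_cells",
    "SplitAssignment",
    "split_leave_cells_out",
    "split_leave_plates_out",
    "balanced_epoch_sample",
    "augment_crop",
    "MILBag",
    "build_mil_bags",
    "load_crops",
]

DEFAULT_CROP_SIZE = 128
MIN_CELLS_PER_TREATMENT = 100  # classes below this are dropped before training


def build_cell_index(bundle: ExperimentBundle) -> pd.DataFrame:
    """Join locations with image metadata into one row per cell."""
    idx = bundle.image_index[
        ["Metadata_Plate", "Metadata_Well", "Metadata_Site", "Treatment", "Control", "Concentration"]
    ]
    cells = bundle.locations.merge(
        idx, on=["Metadata_Plate", "Metadata_Well", "Metadata_Site"], how="inner"
    )
    cells = cells.reset_index(drop=True)
    cells.insert(0, "Cell_Id", np.arange(len(cells)))
    return cells


def filter_max_concentration(cell_index: pd.DataFrame) -> pd.DataFrame:
    """Keep only the maximum concentration of each treatment.

    Controls (and treatments observed at a single concentration) pass
    through unchanged.
    """
    if "Concentration" not in cell_index.columns:
        return cell_index
    max_conc = cell_index.groupby("Treatment")["Concentration"].transform("max")
    keep = cell_index["Control"] | (cell_index["Concentration"] == max_conc)
    return cell_index.loc[keep].reset_index(drop=True)


def filter_min_cells(cell_index: pd.DataFrame, min_cells: int = MIN_CELLS_PER_TREATMENT) -> pd.DataFrame:
    """Drop treatment classes with fewer than ``min_cells`` cells."""
    counts = cell_index.groupby("Treatment")["Cell_Id"].transform("count")
    return cell_index.loc[counts >= min_cells].reset_index(drop=True)


def crop_cells(
    field: np.ndarray,
    centers: pd.DataFrame | np.ndarray,
    crop_size: int = DEFAULT_CROP_SIZE,
) -> np.ndarray:
    """Extract one ``crop_size x crop_size x C`` patch per nucleus center.

    Regions outside the image support are zero-filled; order of crops equals
    order of centers. Raises if a center lies outside the image, identifying
    the offending row.
    """
    field = np.asarray(field)
    if field.ndim == 2:
        field = field[:, :, None]
    h, w, c = field.shape
    if isinstance(centers, pd.DataFrame):
        xs = centers["Nuclei_Location_Center_X"].to_numpy(dtype=float)
        ys = centers["Nuclei_Location_Center_Y"].to_numpy(dtype=float)
    else:
        centers = np.asarray(centers, dtype=float)
        xs, ys = centers[:, 0], centers[:, 1]

    half = crop_size // 2
    out = np.zeros((len(xs), crop_size, crop_size, c), dtype=field.dtype)
    for i, (x, y) in enumerate(zip(xs, ys)):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"center row {i} at (x={x}, y={y}) outside image {w}x{h}")
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = cx - half, cx - half + crop_size
        y0, y1 = cy - half, cy - half + crop_size
        sx0, sx1 = max(x0, 0), min(x1, w)
        sy0, sy1 = max(y0, 0), min(y1, h)
        out[i, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0, :] = field[sy0:sy1, sx0:sx1, :]
    return out


def load_crops(
    bundle: ExperimentBundle,
    cell_index: pd.DataFrame,
    crop_size: int = DEFAULT_CROP_SIZE,
    normalize: bool = True,
) -> np.ndarray:
    """Materialize crops for every row of ``cell_index`` from bundle images.

    With ``normalize`` the 16-bit counts are scaled to [0, 1] by the bit
    depth. Rows are returned in ``cell_index`` order.
    """
    cell_index = cell_index.reset_index(drop=True)
    result: np.ndarray | None = None
    grouped = cell_index.groupby(
        ["Metadata_Plate", "Metadata_Well", "Metadata_Site"], sort=False
    )
    for (plate, well, site), group in grouped:
        fieldimg = load_field(bundle, plate, well, site).astype(np.float32)
        if normalize:
            fieldimg = fieldimg / float(2**16 - 1)
        crops = crop_cells(fieldimg, group, crop_size=crop_size)
        if result is None:
            result = np.zeros(
                (len(cell_index), crop_size, crop_size, crops.shape[-1]), dtype=np.float32
            )
        result[group.index.to_numpy()] = crops
    if result is None:
        result = np.zeros((0, crop_size, crop_size, 0), dtype=np.float32)
    return result


@dataclass
class SplitAssignment:
    """Per-cell train/validation partition."""

    tags: pd.Series  # index = Cell_Id, values in {"train", "val"}
    scheme: str  # "leave_cells_out" | "leave_plates_out"
    seed: int | None = None
    report: pd.DataFrame | None = None

    def ids(self, partition: str) -> np.ndarray:
        return self.tags.index[self.tags == partition].to_numpy()


def split_leave_cells_out(
    cell_index: pd.DataFrame, train_frac: float = 0.6, seed: int = 0
) -> SplitAssignment:
    """Random split stratified per well: ~``train_frac`` of each well trains.

    Each well contributes ``round(train_frac * n_well)`` training cells; the
    remainder validates. Deterministic given ``seed``.
    """
    if len(cell_index) == 0:
        raise ValueError("empty cell index")
    if not 0 <= train_frac <= 1:
        raise ValueError("train_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tags = pd.Series("val", index=pd.Index(cell_index["Cell_Id"], name="Cell_Id"), dtype=object)
    for _, group in cell_index.groupby(["Metadata_Plate", "Metadata_Well"]):
        ids = group["Cell_Id"].to_numpy()
        n_train = int(round(train_frac * len(ids)))
        chosen = rng.choice(ids, size=n_train, replace=False)
        tags.loc[chosen] = "train"
    return SplitAssignment(tags=tags, scheme="leave_cells_out", seed=seed)


def split_leave_plates_out(
    cell_index: pd.DataFrame, n_replicate_wells_out: int = 2
) -> SplitAssignment:
    """Hold out whole plates so every treatment keeps replicate wells out.

    Searches plate subsets (smallest first) for one where every treatment has
    at least ``n_replicate_wells_out`` held-out wells and at least one
    training well; plates are atomic (never split). Raises with the violating
    treatments when the design makes this infeasible.
    """
    plates = sorted(cell_index["Metadata_Plate"].unique())
    wells = cell_index[["Metadata_Plate", "Metadata_Well", "Treatment"]].drop_duplicates()
    treatments = sorted(wells["Treatment"].unique())
    per_plate = {
        t: wells[wells["Treatment"] == t].groupby("Metadata_Plate").size() for t in treatments
    }

    best = None
    for k in range(1, len(plates)):
        for subset in itertools.combinations(plates, k):
            ok = True
            for t in treatments:
                counts = per_plate[t]
                held = sum(int(counts.get(p, 0)) for p in subset)
                kept = int(counts.sum()) - held
                if held < n_replicate_wells_out or kept < 1:
                    ok = False
                    break
            if ok:
                best = subset
                break
        if best is not None:
            break
    if best is None:
        violating = []
        for t in treatments:
            if int(per_plate[t].sum()) < n_replicate_wells_out + 1:
                violating.append(t)
        raise ValueError(
            "no plate subset leaves every treatment "
            f"{n_replicate_wells_out} validation wells and 1 training well; "
            f"violating treatments: {violating or treatments}"
        )

    val_plates = set(best)
    tags = pd.Series(
        np.where(cell_index["Metadata_Plate"].isin(val_plates), "val", "train"),
        index=pd.Index(cell_index["Cell_Id"], name="Cell_Id"),
        dtype=object,
    )
    held_wells = (
        wells[wells["Metadata_Plate"].isin(val_plates)].groupby("Treatment").size().rename("held_out_wells")
    )
    report = held_wells.reset_index()
    report["val_plates"] = [",".join(sorted(val_plates))] * len(report)
    return SplitAssignment(tags=tags, scheme="leave_plates_out", report=report)


def balanced_epoch_sample(cell_index: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """Draw one epoch of cell ids with the same count per treatment class.

    Every class contributes exactly m = median class size cells: larger
    classes are subsampled without replacement, smaller classes oversampled
    with replacement. A fresh seed per epoch gives new draws.
    """
    rng = np.random.default_rng(seed)
    groups = cell_index.groupby("Treatment")["Cell_Id"]
    sizes = groups.size()
    if len(sizes) == 0:
        raise ValueError("empty cell index")
    m = int(round(float(np.median(sizes.to_numpy()))))
    m = max(m, 1)
    drawn = []
    for _, ids in groups:
        ids = ids.to_numpy()
        if len(ids) >= m:
            drawn.append(rng.choice(ids, size=m, replace=False))
        else:
            drawn.append(rng.choice(ids, size=m, replace=True))
    epoch = np.concatenate(drawn)
    rng.shuffle(epoch)
    return epoch


def _minmax_channel(ch: np.ndarray) -> np.ndarray:
    lo, hi = ch.min(), ch.max()
    if hi <= lo:
        return np.zeros_like(ch)
    return (ch - lo) / (hi - lo)


def augment_crop(
    crop: np.ndarray,
    rng: np.random.Generator,
    brightness_delta: float = 0.15,
    contrast_range: tuple[float, float] = (0.8, 1.2),
    renormalize: str = "clip",
) -> np.ndarray:
    """Training-time augmentation of one crop (H x W x C in [0, 1]).

    1. with p = 0.5, a random sub-square of side uniform in [0.8, 1.0] x the
       crop is taken and resized back (bilinear);
    2. horizontal flip with p = 0.5 and rotation by k * 90 degrees, k uniform
       in {0, 1, 2, 3};
    3. per-channel affine brightness/contrast jitter — every pixel of a
       channel changes by the same amounts — followed by per-channel
       renormalization.

    ``renormalize='clip'`` (default) restores the valid [0, 1] range while
    keeping the jitter effective, so the model must learn brightness-robust
    structural features; ``'minmax'`` additionally rescales each channel to
    span [0, 1] (which undoes affine jitter entirely). The output shape
    equals the input shape.
    """
    crop = np.asarray(crop, dtype=np.float32)
    h, w, c = crop.shape
    out = crop

    if rng.random() < 0.5:
        scale = rng.uniform(0.8, 1.0)
        side = max(1, int(round(scale * h)))
        y0 = rng.integers(0, h - side + 1)
        x0 = rng.integers(0, w - side + 1)
        sub = out[y0 : y0 + side, x0 : x0 + side, :]
        out = resize(sub, (h, w), order=1, mode="edge", anti_aliasing=False).astype(np.float32)

    if rng.random() < 0.5:
        out = out[:, ::-1, :]
    k = int(rng.integers(0, 4))
    if k:
        out = np.rot90(out, k=k, axes=(0, 1))

    if renormalize not in ("clip", "minmax"):
        raise ValueError(f"unknown renormalize mode {renormalize!r}")
    out = out.copy()
    for ch in range(c):
        delta = rng.uniform(-brightness_delta, brightness_delta)
        factor = rng.uniform(*contrast_range)
        plane = out[:, :, ch]
        mean = plane.mean()
        plane = (plane - mean) * factor + mean + delta
        plane = np.clip(plane, 0.0, 1.0)
        if renormalize == "minmax":
            plane = _minmax_channel(plane)
        out[:, :, ch] = plane
    return out


@dataclass
class MILBag:
    """One multiple-instance bag of cell ids with a single weak label."""

    member_ids: np.ndarray  # length = bag_size
    label: str
    n_treated: int  # members carrying the bag label (0 for control bags)


def build_mil_bags(
    cell_index: pd.DataFrame,
    bag_size: int = 16,
    bags_per_class: int = 8,
    seed: int = 0,
    treated_range: tuple[int, int] = (4, 12),
) -> list[MILBag]:
    """Assemble balanced multiple-instance bags.

    Control bags contain only control cells. A treated bag contains between
    ``treated_range[0]`` and ``treated_range[1]`` cells (25-75% of a 16-cell
    bag) of its treatment, topped up with control cells. Every class gets the
    same number of bags; call again with a new seed to resample per epoch.
    """
    rng = np.random.default_rng(seed)
    controls = cell_index.loc[cell_index["Control"], "Cell_Id"].to_numpy()
    if len(controls) == 0:
        raise ValueError("no control cells available for bag construction")
    control_label = cell_index.loc[cell_index["Control"], "Treatment"].iloc[0]
    treatments = sorted(cell_index.loc[~cell_index["Control"], "Treatment"].unique())

    def draw(pool: np.ndarray, n: int) -> np.ndarray:
        return rng.choice(pool, size=n, replace=len(pool) < n)

    bags: list[MILBag] = []
    for _ in range(bags_per_class):
        bags.append(MILBag(member_ids=draw(controls, bag_size), label=control_label, n_treated=0))
    for t in treatments:
        pool = cell_index.loc[cell_index["Treatment"] == t, "Cell_Id"].to_numpy()
        for _ in range(bags_per_class):
            n_treated = int(rng.integers(treated_range[0], treated_range[1] + 1))
            members = np.concatenate(
                [draw(pool, n_treated), draw(controls, bag_size - n_treated)]
            )
            rng.shuffle(members)
            bags.append(MILBag(member_ids=members, label=t, n_treated=n_treated))
    return bags
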