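"""Synthetic Cell Painting experiment generator.

Produces a complete desk-scale perturbation experiment — multi-channel
field-of-view images, a metadata index, nucleus-center location tables and
mechanism-of-action (MoA) ground truth — with two controllable sources of
variation:

* a *phenotype*: each treatment shifts per-channel blob intensity and cell /
  nucleus size along a direction shared by treatments of the same MoA class,
  scaled by a per-treatment effect size;
* *technical confounders*: a plate-level multiplicative illumination gradient
  and brightness factor, and a well-position-level intensity/background shift
  with both a position-systematic component (shared across plates, mimicking
  non-randomized plate maps) and a random per-(plate, well) component.

Cells are parametric blobs (nucleus disc in channel 1, cytoplasm annulus in
the remaining channels) — statistically controllable rather than
photorealistic, which is all the downstream stages need.
"""

from __future__ import annotations

import hashlib
import json
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ExperimentConfig",
    "ExperimentBundle",
    "generate_experiment",
    "render_field",
    "write_bundle",
    "read_bundle",
    "load_field",
]

# Intensity model constants (dimensionless "intensity units"; one unit maps to
# INTENSITY_SCALE camera counts before clipping to the bit depth).
INTENSITY_SCALE = 20000.0
BACKGROUND_LEVEL = 0.04
NOISE_SD = 0.01
# Per-channel base blob amplitude; channel 0 is the nucleus (DNA) channel.
BASE_AMPLITUDE = np.array([0.55, 0.35, 0.30, 0.40, 0.30])
NUCLEUS_RADIUS = 5.0
CELL_RADIUS = 11.0


@dataclass
class ExperimentConfig:
    """Design of a synthetic screen.

    ``effect_sizes`` are nonnegative phenotype magnitudes in arbitrary
    intensity units (0 = indistinguishable from control). ``plate_effect`` and
    ``well_effect`` set the confounder magnitudes (0 = no technical
    variation). The plate map is fixed across plates (each treatment recurs at
    the same well position) unless ``randomize_layout`` is set.
    """

    n_plates: int = 3
    wells_per_plate: int = 32
    sites_per_well: int = 2
    n_treatments: int = 20
    n_moa_classes: int = 10
    replicates_per_treatment: int = 3
    control_label: str = "DMSO"
    effect_sizes: Sequence[float] | None = None
    plate_effect: float = 0.3
    well_effect: float = 0.15
    cells_per_site_mean: float = 15.0
    image_shape: tuple[int, int] = (256, 256)
    n_channels: int = 5
    bit_depth: int = 16
    crop_size: int = 128
    randomize_layout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_sizes is None:
            # graded effects by default, spanning no-effect (0, realistic for
            # treatments with no detectable phenotype) to clearly detectable
            if self.n_treatments > 0:
                self.effect_sizes = tuple(
                    np.round(np.linspace(0.0, 3.0, self.n_treatments), 6)
                )
            else:
                self.effect_sizes = ()
        else:
            self.effect_sizes = tuple(float(e) for e in self.effect_sizes)
        self.validate()

    def validate(self) -> None:
        if self.n_moa_classes > self.n_treatments:
            raise ValueError(
                f"n_moa_classes ({self.n_moa_classes}) cannot exceed "
                f"n_treatments ({self.n_treatments})"
            )
        if self.n_treatments > 0 and self.n_moa_classes > 0:
            if self.n_treatments < 2 * self.n_moa_classes:
                raise ValueError(
                    "each MoA class needs >=2 treatments to be queryable; "
                    f"got {self.n_treatments} treatments for "
                    f"{self.n_moa_classes} classes"
                )
        if len(self.effect_sizes) != self.n_treatments:
            raise ValueError("effect_sizes length must equal n_treatments")
        if any(e < 0 for e in self.effect_sizes):
            raise ValueError("effect_sizes must be nonnegative")
        h, w = self.image_shape
        if h < 2 * self.crop_size or w < 2 * self.crop_size:
            raise ValueError(
                f"image_shape {self.image_shape} smaller than 2x crop_size "
                f"({self.crop_size}); enlarge images or reduce crop_size"
            )
        wells_needed = self._treatment_wells_per_plate() + 1
        if wells_needed > self.wells_per_plate:
            raise ValueError(
                f"wells_per_plate={self.wells_per_plate} too small for "
                f"{self.n_treatments} treatments plus controls"
            )
        if self.n_plates >= 2 and self.replicates_per_treatment > 0:
            if self.n_plates * self._wells_per_treatment_per_plate() < self.replicates_per_treatment:
                raise ValueError(
                    "design cannot place replicates_per_treatment wells; "
                    "increase n_plates or wells_per_plate"
                )

    def _wells_per_treatment_per_plate(self) -> int:
        if self.n_treatments == 0:
            return 0
        return max(1, math.ceil(self.replicates_per_treatment / max(self.n_plates, 1)))

    def _treatment_wells_per_plate(self) -> int:
        return self.n_treatments * self._wells_per_treatment_per_plate()


@dataclass
class ExperimentBundle:
    """All tables of one synthetic experiment plus the injected ground truth."""

    image_index: pd.DataFrame
    locations: pd.DataFrame
    annotations: pd.DataFrame
    truth: dict
    root: Path | None = None
    config: ExperimentConfig | None = None

    def site_locations(self, plate: str, well: str, site: int) -> pd.DataFrame:
        loc = self.locations
        mask = (
            (loc["Metadata_Plate"] == plate)
            & (loc["Metadata_Well"] == well)
            & (loc["Metadata_Site"] == site)
        )
        return loc.loc[mask].reset_index(drop=True)


def _site_rng(seed: int, plate: str, well: str, site: int | str) -> np.random.Generator:
    """Independent per-site stream derived by hashing the site identity.

    Hash-derived seeds make rendering order-independent: any subset of sites
    can be rendered in any order (or in parallel) with identical output.
    """
    key = f"{seed}/{plate}/{well}/{site}".encode()
    digest = hashlib.sha256(key).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _stream_rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}/{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _well_names(n_wells: int) -> list[str]:
    n_cols = max(1, math.ceil(math.sqrt(n_wells * 1.5)))
    names = []
    for i in range(n_wells):
        row, col = divmod(i, n_cols)
        names.append(f"{string.ascii_uppercase[row]}{col + 1:02d}")
    return names


def _well_position(well: str) -> tuple[int, int]:
    return string.ascii_uppercase.index(well[0]), int(well[1:]) - 1


def _smoothstep(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def render_field(
    plate_offset: float,
    well_offset: float,
    treatment_effect: float,
    n_cells: int,
    shape: tuple[int, int] = (256, 256),
    n_channels: int = 5,
    rng: np.random.Generator | None = None,
    *,
    signature: np.ndarray | None = None,
    gradient_angle: float = 0.0,
    plate_brightness: float = 0.0,
    noise_scale: float = 1.0,
    morpho_factor: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one field of view.

    Returns ``(image, centers)`` where ``image`` is uint16 of shape
    ``(H, W, n_channels)`` and ``centers`` has 0-based pixel columns
    ``Nuclei_Location_Center_X`` (column) and ``Nuclei_Location_Center_Y``.

    The phenotype enters through a monotone response: channel ``c`` blob
    amplitude is multiplied by ``exp(0.4 * effect * s_c)`` and nucleus / cell
    radii by ``exp(0.2 * effect * s_5)`` / ``exp(0.2 * effect * s_6)``, where
    ``s`` is the 7-component phenotype signature (all-equal by default).
    ``plate_offset`` scales a multiplicative illumination ramp along
    ``gradient_angle``; ``well_offset`` is an additive background shift in
    intensity units. ``noise_scale`` and ``morpho_factor`` carry the
    non-affine part of technical variation (camera-noise level and
    growth-condition cell-size drift), which — unlike purely affine
    brightness shifts — survives per-channel renormalization.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = shape
    if signature is None:
        signature = np.full(n_channels + 2, 1.0 / math.sqrt(n_channels + 2))
    signature = np.asarray(signature, dtype=float)
    if signature.shape[0] != n_channels + 2:
        raise ValueError("signature must have n_channels + 2 components")

    amp = BASE_AMPLITUDE[:n_channels].copy()
    amp *= np.exp(0.4 * treatment_effect * signature[:n_channels])
    r_nuc = NUCLEUS_RADIUS * morpho_factor * math.exp(0.2 * treatment_effect * signature[n_channels])
    r_cell = CELL_RADIUS * morpho_factor * math.exp(0.2 * treatment_effect * signature[n_channels + 1])
    r_cell = max(r_cell, r_nuc + 2.0)

    canvas = np.zeros((h, w, n_channels), dtype=float)
    margin = int(math.ceil(r_cell)) + 2
    xs, ys = [], []
    for _ in range(int(n_cells)):
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        xs.append(cx)
        ys.append(cy)
        rn = r_nuc * rng.normal(1.0, 0.08)
        rc = max(r_cell * rng.normal(1.0, 0.10), rn + 1.5)
        jitter = rng.normal(1.0, 0.08, size=n_channels)
        win = int(math.ceil(rc)) + 3
        y0, y1 = max(0, int(cy) - win), min(h, int(cy) + win + 1)
        x0, x1 = max(0, int(cx) - win), min(w, int(cx) + win + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(yy - cy, xx - cx)
        nucleus = _smoothstep(rn - d)
        cyto = _smoothstep((rc - d) / 1.5) * (0.35 + 0.65 * _smoothstep((d - rn) / 1.0))
        canvas[y0:y1, x0:x1, 0] += amp[0] * jitter[0] * nucleus
        for c in range(1, n_channels):
            canvas[y0:y1, x0:x1, c] += amp[c] * jitter[c] * cyto

    # plate-level multiplicative illumination gradient + brightness factor
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx / max(w - 1, 1) - 0.5) * math.cos(gradient_angle) + (
        yy / max(h - 1, 1) - 0.5
    ) * math.sin(gradient_angle)
    illum = (1.0 + plate_offset * ramp) * (1.0 + plate_brightness)
    illum = np.clip(illum, 0.05, None)

    img = (BACKGROUND_LEVEL + canvas) * illum[:, :, None] + well_offset
    img = img + rng.normal(0.0, NOISE_SD * noise_scale, size=img.shape)
    max_count = 2**16 - 1
    img = np.clip(img * INTENSITY_SCALE, 0, max_count)
    image = img.astype(np.uint16)
    centers = pd.DataFrame(
        {
            "Nuclei_Location_Center_X": np.array(xs, dtype=float),
            "Nuclei_Location_Center_Y": np.array(ys, dtype=float),
        }
    )
    return image, centers


def _build_design(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Lay out plates/wells/treatments and draw all injected ground truth."""
    treatments = [f"T{i + 1:03d}" for i in range(config.n_treatments)]
    moa_labels = [f"MOA{i + 1:02d}" for i in range(config.n_moa_classes)]
    moa_of = {t: moa_labels[i % config.n_moa_classes] for i, t in enumerate(treatments)} if config.n_moa_classes else {}

    rng = _stream_rng(config.seed, "design")
    n_sig = config.n_channels + 2
    class_sigs = {}
    for m in moa_labels:
        v = rng.normal(size=n_sig)
        class_sigs[m] = v / np.linalg.norm(v)
    treat_sigs = {}
    for t in treatments:
        base = class_sigs[moa_of[t]] if moa_of else np.zeros(n_sig)
        v = base + 0.25 * rng.normal(size=n_sig)
        treat_sigs[t] = v / np.linalg.norm(v)

    wells = _well_names(config.wells_per_plate)
    wptpp = config._wells_per_treatment_per_plate()
    layout: dict[str, str] = {}
    assignable = list(wells)
    if config.randomize_layout:
        layouts = {}
        for p in range(config.n_plates):
            prng = _stream_rng(config.seed, f"layout/{p}")
            order = list(assignable)
            prng.shuffle(order)
            lay = {}
            k = 0
            for t in treatments:
                for _ in range(wptpp):
                    lay[order[k]] = t
                    k += 1
            layouts[p] = lay
    else:
        k = 0
        for t in treatments:
            for _ in range(wptpp):
                layout[assignable[k]] = t
                k += 1
        layouts = {p: layout for p in range(config.n_plates)}

    # confounder draws
    plates = [f"P{p + 1:02d}" for p in range(config.n_plates)]
    plate_truth = {}
    for p, plate in enumerate(plates):
        prng = _stream_rng(config.seed, f"plate/{plate}")
        plate_truth[plate] = {
            "gradient_amplitude": float(config.plate_effect),
            "gradient_angle": float(prng.uniform(0, 2 * math.pi)),
            "brightness": float(config.plate_effect * prng.uniform(-0.5, 0.5)),
            # plate-wide growth/acquisition drift (non-affine, like the well
            # components): all cells on a plate slightly larger/smaller and
            # noisier/cleaner than average
            "morpho_factor": float(1.0 + 0.4 * config.plate_effect * prng.uniform(-1.0, 1.0)),
            "noise_scale": float(max(0.3, 1.0 + 1.2 * config.plate_effect * prng.uniform(-1.0, 1.0))),
        }

    n_rows_used = max(_well_position(w)[0] for w in wells) + 1
    n_cols_used = max(_well_position(w)[1] for w in wells) + 1
    well_truth = {}
    for plate in plates:
        for well in wells:
            r, c = _well_position(well)
            pos = (c / max(n_cols_used - 1, 1) - 0.5) + (r / max(n_rows_used - 1, 1) - 0.5)
            wrng = _stream_rng(config.seed, f"well/{plate}/{well}")
            rand = wrng.uniform(-1.0, 1.0)
            offset = config.well_effect * BACKGROUND_LEVEL * 4.0 * (0.5 * pos + 0.5 * rand)
            # non-affine components: per-(plate, well) noise level and cell-size
            # drift, the kind of technical signature that survives per-channel
            # renormalization
            noise_scale = max(0.3, 1.0 + 1.5 * config.well_effect * wrng.uniform(-1.0, 1.0))
            morpho = 1.0 + 0.3 * config.well_effect * wrng.uniform(-1.0, 1.0)
            well_truth[f"{plate}/{well}"] = {
                "offset": float(offset),
                "noise_scale": float(noise_scale),
                "morpho_factor": float(morpho),
            }

    rows = []
    for plate in plates:
        p = plates.index(plate)
        lay = layouts[p]
        for well in wells:
            treatment = lay.get(well, config.control_label)
            control = treatment == config.control_label
            for site in range(1, config.sites_per_well + 1):
                rows.append(
                    {
                        "Metadata_Plate": plate,
                        "Metadata_Well": well,
                        "Metadata_Site": site,
                        "Treatment": treatment,
                        "Control": control,
                        "Concentration": 0.0 if control else 10.0,
                    }
                )
    index = pd.DataFrame(rows)

    annotations = pd.DataFrame(
        {"Treatment": treatments, "MoA": [moa_of[t] for t in treatments]}
        if moa_of
        else {"Treatment": [], "MoA": []}
    )

    truth = {
        "treatments": {
            t: {
                "effect_size": float(config.effect_sizes[i]),
                "moa": moa_of.get(t),
                "signature": [float(x) for x in treat_sigs[t]],
            }
            for i, t in enumerate(treatments)
        },
        "plates": plate_truth,
        "wells": well_truth,
        "control_label": config.control_label,
        "seed": config.seed,
    }
    return index, annotations, truth


def generate_experiment(config: ExperimentConfig, out_dir: str | Path) -> ExperimentBundle:
    """Generate images + tables for a full synthetic experiment.

    Per-channel 16-bit grayscale TIFFs are written under
    ``out_dir/images/<plate>/``; the returned bundle holds the metadata index
    (with relative channel paths), the nucleus-center table, MoA annotations
    and the injected ground truth. Deterministic given ``config.seed``.
    """
    config.validate()
    out_dir = Path(out_dir)
    index, annotations, truth = _build_design(config)

    loc_frames = []
    chan_cols: dict[str, list[str]] = {f"Channel_{c + 1}_Path": [] for c in range(config.n_channels)}
    for row in index.itertuples(index=False):
        plate, well, site = row.Metadata_Plate, row.Metadata_Well, row.Metadata_Site
        rng = _site_rng(config.seed, plate, well, site)
        n_cells = int(rng.poisson(config.cells_per_site_mean))
        if row.Control:
            effect, sig = 0.0, None
        else:
            t = truth["treatments"][row.Treatment]
            effect, sig = t["effect_size"], np.array(t["signature"])
        ptr = truth["plates"][plate]
        wtr = truth["wells"][f"{plate}/{well}"]
        image, centers = render_field(
            plate_offset=ptr["gradient_amplitude"],
            well_offset=wtr["offset"],
            treatment_effect=effect,
            n_cells=n_cells,
            shape=config.image_shape,
            n_channels=config.n_channels,
            rng=rng,
            signature=sig,
            gradient_angle=ptr["gradient_angle"],
            plate_brightness=ptr["brightness"],
            noise_scale=wtr.get("noise_scale", 1.0) * ptr.get("noise_scale", 1.0),
            morpho_factor=wtr.get("morpho_factor", 1.0) * ptr.get("morpho_factor", 1.0),
        )
        plate_dir = out_dir / "images" / plate
        plate_dir.mkdir(parents=True, exist_ok=True)
        for c in range(config.n_channels):
            rel = Path("images") / plate / f"{well}_s{site}_ch{c + 1}.tiff"
            tifffile.imwrite(out_dir / rel, image[:, :, c])
            chan_cols[f"Channel_{c + 1}_Path"].append(str(rel))
        centers.insert(0, "Metadata_Plate", plate)
        centers.insert(1, "Metadata_Well", well)
        centers.insert(2, "Metadata_Site", site)
        loc_frames.append(centers)

    for col, values in chan_cols.items():
        index[col] = values
    locations = (
        pd.concat(loc_frames, ignore_index=True)
        if loc_frames
        else pd.DataFrame(
            columns=[
                "Metadata_Plate",
                "Metadata_Well",
                "Metadata_Site",
                "Nuclei_Location_Center_X",
                "Nuclei_Location_Center_Y",
            ]
        )
    )
    return ExperimentBundle(
        image_index=index,
        locations=locations,
        annotations=annotations,
        truth=truth,
        root=out_dir,
        config=config,
    )


def load_field(bundle: ExperimentBundle, plate: str, well: str, site: int) -> np.ndarray:
    """Load one field of view as a float array of shape (H, W, C)."""
    if bundle.root is None:
        raise ValueError("bundle has no root directory")
    idx = bundle.image_index
    row = idx[
        (idx["Metadata_Plate"] == plate)
        & (idx["Metadata_Well"] == well)
        & (idx["Metadata_Site"] == site)
    ]
    if row.empty:
        raise KeyError(f"no image for ({plate}, {well}, {site})")
    row = row.iloc[0]
    chans = [c for c in idx.columns if c.startswith("Channel_") and c.endswith("_Path")]
    chans.sort(key=lambda c: int(c.split("_")[1]))
    planes = [tifffile.imread(bundle.root / row[c]).astype(float) for c in chans]
    return np.stack(planes, axis=-1)


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path, overwrite: bool = False) -> pd.DataFrame:
    """Persist the bundle tables; returns a manifest with one row per site.

    Writes ``index.csv``, ``annotations.csv``, ``truth.json`` and one
    locations CSV per site under ``locations/<plate>/<well>_<site>.csv``.
    Refuses to overwrite an existing ``index.csv`` unless ``overwrite``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_path = out_dir / "index.csv"
    if index_path.exists() and not overwrite:
        raise FileExistsError(f"{index_path} exists; pass overwrite=True to replace")
    bundle.image_index.to_csv(index_path, index=False)
    bundle.annotations.to_csv(out_dir / "annotations.csv", index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1)

    manifest_rows = []
    for row in bundle.image_index.itertuples(index=False):
        plate, well, site = row.Metadata_Plate, row.Metadata_Well, row.Metadata_Site
        rel = Path("locations") / plate / f"{well}_{site}.csv"
        (out_dir / rel).parent.mkdir(parents=True, exist_ok=True)
        site_loc = bundle.site_locations(plate, well, site)
        site_loc[["Nuclei_Location_Center_X", "Nuclei_Location_Center_Y"]].to_csv(
            out_dir / rel, index=False
        )
        manifest_rows.append(
            {
                "Metadata_Plate": plate,
                "Metadata_Well": well,
                "Metadata_Site": site,
                "Locations_Path": str(rel),
            }
        )
    return pd.DataFrame(manifest_rows)


def read_bundle(root: str | Path) -> ExperimentBundle:
    """Round-trip loader for :func:`write_bundle` output."""
    root = Path(root)
    index = pd.read_csv(root / "index.csv")
    annotations = pd.read_csv(root / "annotations.csv")
    if annotations.empty:
        annotations = pd.DataFrame({"Treatment": [], "MoA": []})
    with open(root / "truth.json") as fh:
        truth = json.load(fh)
    frames = []
    for row in index.itertuples(index=False):
        plate, well, site = row.Metadata_Plate, row.Metadata_Well, row.Metadata_Site
        loc = pd.read_csv(root / "locations" / plate / f"{well}_{site}.csv")
        loc.insert(0, "Metadata_Plate", plate)
        loc.insert(1, "Metadata_Well", well)
        loc.insert(2, "Metadata_Site", site)
        frames.append(loc)
    locations = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "Metadata_Plate",
                "Metadata_Well",
                "Metadata_Site",
                "Nuclei_Location_Center_X",
                "Nuclei_Location_Center_Y",
            ]
        )
    )
    return ExperimentBundle(
        image_index=index,
        locations=locations,
        annotations=annotations,
        truth=truth,
        root=root,
    )
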