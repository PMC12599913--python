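"""Reading and writing crop datasets and analysis configurations.

A *crop* is a straightened, fixed-width strip image of a nerve cord
(typically ~20 px tall and a few hundred px long) holding one or two
fluorescence channels.  Crops live on disk as grayscale TIFFs, one file
per crop, with multi-page TIFFs interpreted as channels (page 1 =
channel 1).  Crops are grouped into per-genotype subdirectories::

    dataset_root/
        control/
            worm01.tif
            worm02.tif
        mutant/
            worm01.tif

The analysis configuration is a flat JSON document that round-trips
losslessly, so a saved session replays to bit-identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

MAX_CHANNELS = 2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DetectionParams:
    """Thresholding parameters for one channel.

    sensitivity
        Permissiveness of the local-means threshold, in [0, 1].  Higher
        values admit more pixels as signal.
    neighborhood_size
        Side of the square averaging window in pixels; odd, >= 3.
    method
        ``"local_means"`` (adaptive, per-pixel window mean) or
        ``"global_otsu"`` (single image-wide threshold baseline).
    """

    sensitivity: float = 0.2
    neighborhood_size: int = 15
    method: str = "local_means"

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if self.neighborhood_size < 3 or self.neighborhood_size % 2 == 0:
            raise ValueError(
                f"neighborhood_size must be odd and >= 3, got {self.neighborhood_size}"
            )
        if self.method not in ("local_means", "global_otsu"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class RestrictionParams:
    """ROI exclusion rules applied after segmentation.

    Edge margins remove any ROI with a pixel inside the band (gut-granule
    guard); feature bounds remove ROIs outside [min, max] for area,
    circularity, length-to-width ratio and within-ROI intensity variance.
    A bound set to ``None`` is disabled.  Variance bounds default to
    disabled because the useful direction is dataset-dependent.
    """

    x_edge_px: int = 0
    y_edge_px: int = 0
    min_area_px2: float | None = None
    max_area_px2: float | None = None
    min_circularity: float | None = None
    max_circularity: float | None = None
    max_length_width_ratio: float | None = None
    min_variance: float | None = None
    max_variance: float | None = None

    def __post_init__(self) -> None:
        if self.x_edge_px < 0 or self.y_edge_px < 0:
            raise ValueError("edge margins must be >= 0")
        for lo, hi, name in (
            (self.min_area_px2, self.max_area_px2, "area"),
            (self.min_circularity, self.max_circularity, "circularity"),
            (self.min_variance, self.max_variance, "variance"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"min_{name} > max_{name}")
        if self.max_length_width_ratio is not None and self.max_length_width_ratio < 1:
            raise ValueError("max_length_width_ratio must be >= 1")


@dataclass
class CropImage:
    """One straightened crop: 1-2 aligned intensity channels plus metadata."""

    channels: list[np.ndarray]
    pixel_size_um: float
    genotype: str = ""
    crop_id: str = ""
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= MAX_CHANNELS:
            raise ValueError(f"crops carry 1-{MAX_CHANNELS} channels, got {len(self.channels)}")
        self.channels = [np.asarray(c, dtype=float) for c in self.channels]
        shapes = {c.shape for c in self.channels}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        shape = self.channels[0].shape
        if len(shape) != 2 or shape[0] < 1 or shape[1] < 1:
            raise ValueError(f"channels must be non-empty 2D arrays, got shape {shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(len(self.channels))]
        if len(self.channel_names) != len(self.channels):
            raise ValueError("channel_names length must match number of channels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def length_px(self) -> int:
        """Crop extent along the nerve cord (second axis)."""
        return self.shape[1]


@dataclass
class CropDataset:
    """Ordered crop collection with an exclusion set for flagged outliers."""

    crops: list[CropImage]
    excluded_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.crop_id for c in self.crops]
        if len(ids) != len(set(ids)):
            raise ValueError("crop_ids must be unique within a dataset")

    def active(self) -> list[CropImage]:
        """Crops that contribute to outputs (exclusions dropped)."""
        return [c for c in self.crops if c.crop_id not in self.excluded_ids]

    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.crops:
            seen.setdefault(c.genotype)
        return list(seen)

    def __len__(self) -> int:
        return len(self.crops)


@dataclass
class AnalysisConfig:
    """Complete, serializable description of one analysis session."""

    detection: list[DetectionParams]
    restriction: list[RestrictionParams]
    overlap_threshold: float = 0.3
    pixel_size_um: float = 0.21
    channel_names: list[str] = field(default_factory=lambda: ["ch1"])
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if len(self.detection) != len(self.channel_names) or len(self.restriction) != len(
            self.channel_names
        ):
            raise ValueError("need one DetectionParams and RestrictionParams per channel")


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_crop_tiff(path: str | Path, pixel_size_um: float, genotype: str = "") -> CropImage:
    """Read one TIFF as a crop; pages become channels, values cast to float."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # pragma: no cover - message carries the path
        raise ValueError(f"unreadable crop image {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        channels = [data]
    elif data.ndim == 3:
        if data.shape[0] > MAX_CHANNELS:
            raise ValueError(
                f"channel limit exceeded in {path}: {data.shape[0]} pages (max {MAX_CHANNELS})"
            )
        channels = [data[i] for i in range(data.shape[0])]
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim} in {path}")
    if any(c.size == 0 for c in channels):
        raise ValueError(f"zero-sized image in {path}")
    return CropImage(
        channels=[c.astype(float) for c in channels],
        pixel_size_um=pixel_size_um,
        genotype=genotype,
        crop_id=path.stem,
    )


def write_crop_tiff(crop: CropImage, path: str | Path) -> None:
    """Write a crop as a multi-page float32 TIFF (page = channel)."""
    stack = np.stack([c.astype(np.float32) for c in crop.channels])
    tifffile.imwrite(Path(path), stack if stack.shape[0] > 1 else stack[0])


def read_mask_tiff(path: str | Path) -> np.ndarray:
    """Read a single-page TIFF as a boolean mask (nonzero = ROI)."""
    data = np.asarray(tifffile.imread(Path(path)))
    if data.ndim != 2:
        raise ValueError(f"mask must be single-page 2D, got ndim={data.ndim} in {path}")
    return data != 0


def write_label_tiff(labels: np.ndarray, path: str | Path) -> None:
    """Write a label map as 16-bit single-page TIFF for external inspection."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit TIFF")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def read_crop_dataset(root_path: str | Path, pixel_size_um: float) -> CropDataset:
    """Read a per-genotype directory tree of crop TIFFs.

    Subdirectory names become genotype labels and filename stems become
    crop ids (prefixed with the genotype to keep ids unique across
    groups).  Ordering is lexicographic by genotype then filename, so
    repeat runs see the dataset in the same order.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    crops: list[CropImage] = []
    for geno_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for tif in sorted(geno_dir.glob("*.tif")) + sorted(geno_dir.glob("*.tiff")):
            crop = read_crop_tiff(tif, pixel_size_um, genotype=geno_dir.name)
            crop.crop_id = f"{geno_dir.name}/{tif.stem}"
            crops.append(crop)
    return CropDataset(crops=crops)


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    "detection",
    "restriction",
    "overlap_threshold",
    "pixel_size_um",
    "channel_names",
    "rng_seed",
}


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    doc = {
        "detection": [asdict(d) for d in config.detection],
        "restriction": [asdict(r) for r in config.restriction],
        "overlap_threshold": config.overlap_threshold,
        "pixel_size_um": config.pixel_size_um,
        "channel_names": list(config.channel_names),
        "rng_seed": config.rng_seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> AnalysisConfig:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise ValueError("config file must hold a JSON object")
    missing = _CONFIG_FIELDS - doc.keys()
    if missing:
        raise ValueError(f"config missing field(s): {', '.join(sorted(missing))}")
    unknown = doc.keys() - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"config has unknown field(s): {', '.join(sorted(unknown))}")
    try:
        detection = [DetectionParams(**d) for d in doc["detection"]]
        restriction = [RestrictionParams(**r) for r in doc["restriction"]]
    except TypeError as exc:
        raise ValueError(f"config schema mismatch: {exc}") from exc
    return AnalysisConfig(
        detection=detection,
        restriction=restriction,
        overlap_threshold=doc["overlap_threshold"],
        pixel_size_um=doc["pixel_size_um"],
        channel_names=list(doc["channel_names"]),
        rng_seed=int(doc["rng_seed"]),
    )


def default_config(
    n_channels: int = 1,
    pixel_size_um: float = 0.21,
    channel_names: Sequence[str] | None = None,
) -> AnalysisConfig:
    """A sensible starting configuration for bright punctate reporters."""
    names = list(channel_names) if channel_names else [f"ch{i + 1}" for i in range(n_channels)]
    return AnalysisConfig(
        detection=[DetectionParams() for _ in names],
        restriction=[RestrictionParams(y_edge_px=3, min_area_px2=5.0) for _ in names],
        channel_names=names,
    )
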