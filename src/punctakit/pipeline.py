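"""End-to-end orchestration: detect -> segment -> restrict -> measure ->
colocalize, plus overlay/montage rendering and the run manifest.

`run_pipeline` is the batch equivalent of working through the GUI tabs
once: every non-excluded crop is thresholded, watershed-segmented,
restricted and measured per channel, and two-channel crops additionally
get the colocalization metrics.  All outputs are plain CSV/JSON and the
whole run is deterministic for a fixed configuration, which is what
makes a saved session replayable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crop_io import (
    AnalysisConfig,
    CropDataset,
    CropImage,
    DetectionParams,
    RestrictionParams,
    save_config,
)
from .detection import bradley_threshold, detect, otsu_threshold, segment_rois
from .roi_filtering import count_per_100um, measure_rois, restrict_rois, snr
from .colocalization import colocalize


@dataclass
class ChannelAnalysis:
    """Everything the pipeline derives from one channel of one crop."""

    mask: np.ndarray
    labels: np.ndarray
    table: pd.DataFrame


def analyze_channel(
    channel: np.ndarray,
    detection: DetectionParams,
    restriction: RestrictionParams,
    pixel_size_um: float,
) -> ChannelAnalysis:
    """Threshold, segment, measure and restrict a single channel."""
    if detection.method == "global_otsu":
        mask = otsu_threshold(channel)
    else:
        mask = bradley_threshold(channel, detection)
    labels = segment_rois(mask, channel)
    table = measure_rois(labels, channel, pixel_size_um)
    labels, table = restrict_rois(labels, table, restriction)
    return ChannelAnalysis(mask=mask, labels=labels, table=table)


def _array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(
    dataset: CropDataset,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis over a dataset.

    Returns a dict with keys ``rois`` (per-ROI table), ``crops``
    (per-crop summary), ``coloc`` (per-crop metrics, two-channel crops
    only, else empty), ``labels`` (crop_id -> list of label maps) and
    ``manifest``.  When ``out_dir`` is given the tables are written as
    ``rois.csv``, ``crops.csv``, ``coloc.csv``, the manifest as
    ``manifest.json`` and the config snapshot as ``config.json``.
    """
    roi_rows: list[pd.DataFrame] = []
    crop_rows = []
    coloc_rows = []
    label_maps: dict[str, list[np.ndarray]] = {}
    statuses = []

    for crop in dataset.crops:
        entry = {
            "crop_id": crop.crop_id,
            "genotype": crop.genotype,
            "checksums": [_array_checksum(c) for c in crop.channels],
        }
        if crop.crop_id in dataset.excluded_ids:
            statuses.append({**entry, "status": "excluded"})
            continue
        if crop.n_channels != len(config.channel_names):
            statuses.append(
                {**entry, "status": "error", "message": "channel count mismatch with config"}
            )
            continue
        try:
            analyses = [
                analyze_channel(
                    crop.channels[i],
                    config.detection[i],
                    config.restriction[i],
                    config.pixel_size_um,
                )
                for i in range(crop.n_channels)
            ]
        except ValueError as exc:
            statuses.append({**entry, "status": "error", "message": str(exc)})
            continue

        label_maps[crop.crop_id] = [a.labels for a in analyses]
        crow = {"crop_id": crop.crop_id, "genotype": crop.genotype}
        for i, a in enumerate(analyses):
            name = config.channel_names[i]
            t = a.table.copy()
            t.insert(0, "channel", name)
            t.insert(0, "genotype", crop.genotype)
            t.insert(0, "crop_id", crop.crop_id)
            roi_rows.append(t)
            n = len(a.table)
            crow[f"{name}_n_rois"] = n
            crow[f"{name}_count_per_100um"] = count_per_100um(
                n, crop.length_px, config.pixel_size_um
            )
            try:
                crow[f"{name}_snr"] = snr(crop.channels[i], a.labels > 0)
            except ValueError:
                crow[f"{name}_snr"] = float("nan")
            crow[f"{name}_mean_roi_intensity"] = (
                float(a.table["mean_intensity"].mean()) if n else float("nan")
            )
        crop_rows.append(crow)

        if crop.n_channels == 2:
            try:
                res = colocalize(
                    crop.channels[0],
                    crop.channels[1],
                    analyses[0].labels,
                    analyses[1].labels,
                    config.overlap_threshold,
                )
                coloc_rows.append(
                    {"crop_id": crop.crop_id, "genotype": crop.genotype, **asdict(res)}
                )
            except ValueError as exc:
                coloc_rows.append(
                    {
                        "crop_id": crop.crop_id,
                        "genotype": crop.genotype,
                        "pcc": float("nan"),
                        "pcc_normalized": float("nan"),
                        "m1": float("nan"),
                        "m2": float("nan"),
                        "r1": float("nan"),
                        "r2": float("nan"),
                        "overlap_threshold": config.overlap_threshold,
                    }
                )
                entry = {**entry, "coloc_warning": str(exc)}
        statuses.append({**entry, "status": "ok"})

    rois = (
        pd.concat(roi_rows, ignore_index=True)
        if roi_rows
        else pd.DataFrame()
    )
    crops = pd.DataFrame(crop_rows)
    coloc = pd.DataFrame(coloc_rows)
    manifest = {
        "tool": "punctakit",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": json.loads(json.dumps(_config_doc(config))),
        "crops": statuses,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rois.to_csv(out / "rois.csv", index=False)
        crops.to_csv(out / "crops.csv", index=False)
        coloc.to_csv(out / "coloc.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        save_config(config, out / "config.json")

    return {"rois": rois, "crops": crops, "coloc": coloc, "labels": label_maps, "manifest": manifest}


def _config_doc(config: AnalysisConfig) -> dict:
    return {
        "detection": [asdict(d) for d in config.detection],
        "restriction": [asdict(r) for r in config.restriction],
        "overlap_threshold": config.overlap_threshold,
        "pixel_size_um": config.pixel_size_um,
        "channel_names": list(config.channel_names),
        "rng_seed": config.rng_seed,
    }


# ---------------------------------------------------------------------------
# overlays and montages
# ---------------------------------------------------------------------------

_GREEN = np.array([0.0, 1.0, 0.0])
_MAGENTA = np.array([1.0, 0.0, 1.0])


def overlay_image(
    channel: np.ndarray,
    labels_green: np.ndarray | None = None,
    labels_magenta: np.ndarray | None = None,
) -> np.ndarray:
    """Grayscale intensity base with ROI outlines as an RGB float array.

    Channel-1 ROIs are drawn green and channel-2 ROIs magenta, and both
    can be combined on one base image.
    """
    from skimage.segmentation import find_boundaries

    from .detection import normalize_image

    base = normalize_image(np.asarray(channel, dtype=float))
    rgb = np.stack([base, base, base], axis=-1)
    for labels, color in ((labels_green, _GREEN), (labels_magenta, _MAGENTA)):
        if labels is None:
            continue
        labels = np.asarray(labels)
        if labels.shape != base.shape:
            raise ValueError("label map shape does not match channel shape")
        edges = find_boundaries(labels, mode="outer") | find_boundaries(labels, mode="inner")
        rgb[edges] = color
    return rgb


def render_overlays(
    crops: list[CropImage],
    labels: dict[str, list[np.ndarray]],
    out_dir: str | Path,
    base_channel: int = 0,
    green_channel: int | None = 0,
    magenta_channel: int | None = None,
) -> list[Path]:
    """Write one overlay PNG per crop; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for crop in crops:
        if crop.crop_id not in labels:
            continue
        maps = labels[crop.crop_id]
        lg = maps[green_channel] if green_channel is not None and green_channel < len(maps) else None
        lm = (
            maps[magenta_channel]
            if magenta_channel is not None and magenta_channel < len(maps)
            else None
        )
        rgb = overlay_image(crop.channels[base_channel], lg, lm)
        path = out / f"{crop.crop_id.replace('/', '_')}_overlay.png"
        plt.imsave(path, np.clip(rgb, 0, 1))
        written.append(path)
    return written


def render_montage(
    crops: list[CropImage],
    labels: dict[str, list[np.ndarray]],
    out_path: str | Path,
    pixel_size_um: float,
    base_channel: int = 0,
    scale_bar_um: float = 5.0,
    gap_px: int = 4,
) -> Path:
    """Tile crop overlays vertically in dataset order with a scale bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tiles = []
    width = max(c.shape[1] for c in crops)
    for crop in crops:
        maps = labels.get(crop.crop_id, [None])
        rgb = overlay_image(crop.channels[base_channel], maps[base_channel])
        pad = width - rgb.shape[1]
        if pad:
            rgb = np.pad(rgb, ((0, 0), (0, pad), (0, 0)))
        tiles.append(rgb)
        tiles.append(np.zeros((gap_px, width, 3)))
    canvas = np.concatenate(tiles[:-1], axis=0)
    bar_px = max(1, int(round(scale_bar_um / pixel_size_um)))
    canvas[-3:-1, 2 : 2 + min(bar_px, width - 4)] = 1.0
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    plt.imsave(out_path, np.clip(canvas, 0, 1))
    return out_path
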