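"""Synthetic straightened-crop scenes with known ground truth, plus the
four confocal noise models used for the metric robustness study.

A scene emulates a straightened nerve-cord crop: a thin strip (default
20 x 500 px) with a flat background, Gaussian puncta of randomized
amplitude and width scattered along the cord with a minimum separation,
optional bright off-axis blobs hugging the y-edges (mimicking
autofluorescent gut granules), and additive read noise.  Ground truth
for each punctum is its half-maximum contour in the noiseless image;
confounders appear in the image but never in the truth.

Noise injection mirrors the common imaging-toolbox convention: the image
is min-max rescaled to [0, 1], noise is applied there, the result is
clipped to [0, 1] and mapped back to the original scale.

* poisson      — shot noise; each pixel becomes a Poisson draw with mean
                 equal to the pixel value on a counts scale (default
                 x1000, since Poisson on [0, 1] intensities is
                 ill-posed).
* gaussian     — thermal noise; additive N(mean, variance).
* speckle      — multiplicative I * (1 + U) with zero-mean uniform U of
                 the given variance.
* salt_pepper  — a `density` fraction of pixels replaced by the extremes
                 (half 0, half 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .crop_io import CropDataset, CropImage, DetectionParams, RestrictionParams
from .colocalization import manders, pcc_normalized, roi_overlap_ratio


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Parameters of one synthetic crop.

    Defaults emulate a bright overexpressed punctate reporter in a
    20 x 500 px straightened crop: ~12 well-separated puncta of peak
    amplitude 80-120 over a background offset of 10 with read-noise
    SD 2 (signal-to-read-noise >= 40x).
    """

    height: int = 20
    width: int = 500
    n_puncta: int = 12
    amplitude_range: tuple[float, float] = (80.0, 120.0)
    sigma_range: tuple[float, float] = (1.5, 2.5)
    min_separation: float = 12.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    edge_confounders: int = 0
    pixel_size_um: float = 0.21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("scene must be at least 1x1")
        if self.n_puncta < 0 or self.edge_confounders < 0:
            raise ValueError("counts must be >= 0")
        for name, pair in (("amplitude", self.amplitude_range), ("sigma", self.sigma_range)):
            lo, hi = pair
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name} range {pair}")
        if self.min_separation < 0 or self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("separation, background and read noise must be >= 0")


def overexpressed_like(n_puncta: int = 12, seed: int = 0) -> SceneSpec:
    """Bright-reporter condition: peak amplitude ~50x the read noise."""
    return SceneSpec(n_puncta=n_puncta, seed=seed)


def endogenous_like(n_puncta: int = 12, amplitude_scale: float = 1.0, seed: int = 0) -> SceneSpec:
    """Dim-reporter condition: peak amplitude only ~5-8x the read noise.

    Emulates endogenously tagged reporters, whose low signal-to-noise is
    what makes detection sensitive to the threshold setting; use
    ``amplitude_scale`` < 1 for mutants that also dim the signal.
    """
    return SceneSpec(
        n_puncta=n_puncta,
        amplitude_range=(15.0 * amplitude_scale, 25.0 * amplitude_scale),
        read_noise_sd=3.0,
        seed=seed,
    )


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample punctum centers respecting the minimum separation."""
    margin = int(np.ceil(2.5 * spec.sigma_range[1])) + 1
    ylo, yhi = margin, spec.height - 1 - margin
    xlo, xhi = margin, spec.width - 1 - margin
    if ylo > yhi or xlo > xhi:
        raise ValueError("infeasible packing: scene too small for punctum margins")
    centers: list[tuple[float, float]] = []
    attempts = 0
    limit = 2000 * max(1, spec.n_puncta)
    while len(centers) < spec.n_puncta:
        if attempts >= limit:
            raise ValueError(
                f"infeasible packing: placed {len(centers)}/{spec.n_puncta} puncta "
                f"with min_separation {spec.min_separation}"
            )
        attempts += 1
        y = rng.uniform(ylo, yhi)
        x = rng.uniform(xlo, xhi)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= spec.min_separation**2 for cy, cx in centers):
            centers.append((y, x))
    return np.asarray(centers).reshape(spec.n_puncta, 2)


def generate_scene(spec: SceneSpec) -> tuple[CropImage, np.ndarray]:
    """Render a scene and its ground-truth label map.

    Returns a single-channel :class:`CropImage` and an integer truth map
    where label k marks the pixels whose noiseless contribution from
    punctum k is at least half that punctum's amplitude (ties go to the
    strongest contributor).  Same spec (same seed) -> bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    image = np.full((spec.height, spec.width), float(spec.background))
    truth = np.zeros((spec.height, spec.width), dtype=np.int32)
    best = np.zeros_like(image)  # strongest half-max-clearing contribution seen

    centers = _place_centers(spec, rng)
    amps = rng.uniform(*spec.amplitude_range, size=spec.n_puncta)
    sigmas = rng.uniform(*spec.sigma_range, size=spec.n_puncta)
    for k in range(spec.n_puncta):
        cy, cx = centers[k]
        contrib = amps[k] * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigmas[k] ** 2)
        )
        image += contrib
        inside = (contrib >= amps[k] / 2.0) & (contrib > best)
        truth[inside] = k + 1
        best = np.maximum(best, np.where(contrib >= amps[k] / 2.0, contrib, 0.0))

    for _ in range(spec.edge_confounders):
        # gut-granule mimic: bright blob centered within 3 px of a y-edge
        row = rng.integers(0, 3)
        if rng.random() < 0.5:
            row = spec.height - 1 - row
        col = rng.uniform(5, spec.width - 6)
        amp = 1.5 * spec.amplitude_range[1]
        sig = rng.uniform(*spec.sigma_range)
        image += amp * np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2.0 * sig**2))

    if spec.read_noise_sd > 0:
        image = image + rng.normal(0.0, spec.read_noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    crop = CropImage(
        channels=[image],
        pixel_size_um=spec.pixel_size_um,
        crop_id=f"scene{spec.seed}",
    )
    return crop, truth


def generate_dataset(
    genotype_specs: dict[str, SceneSpec],
    n_crops: int,
    base_seed: int = 0,
) -> tuple[CropDataset, dict[str, np.ndarray]]:
    """A multi-genotype dataset of scenes plus per-crop truth maps."""
    crops = []
    truths: dict[str, np.ndarray] = {}
    for gi, (genotype, spec) in enumerate(genotype_specs.items()):
        for i in range(n_crops):
            s = replace(spec, seed=(base_seed + 7919 * gi + i) % 2**31)
            crop, truth = generate_scene(s)
            crop.genotype = genotype
            crop.crop_id = f"{genotype}/crop{i:03d}"
            crops.append(crop)
            truths[crop.crop_id] = truth
    return CropDataset(crops=crops), truths


# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """One noise condition.  Parameter ranges follow the study grids:
    gaussian mean and variance in [0, 0.2], speckle variance in [0, 0.2],
    salt-and-pepper density in [0, 0.05]."""

    kind: str
    mean: float = 0.0
    variance: float = 0.01
    density: float = 0.05
    poisson_counts_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "gaussian", "speckle", "salt_pepper"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "gaussian":
            if not 0.0 <= self.mean <= 0.2:
                raise ValueError("gaussian mean must be in [0, 0.2]")
            if not 0.0 <= self.variance <= 0.2:
                raise ValueError("gaussian variance must be in [0, 0.2]")
        if self.kind == "speckle" and not 0.0 <= self.variance <= 0.2:
            raise ValueError("speckle variance must be in [0, 0.2]")
        if self.kind == "salt_pepper" and not 0.0 <= self.density <= 0.05:
            raise ValueError("salt-and-pepper density must be in [0, 0.05]")
        if self.kind == "poisson" and self.poisson_counts_scale <= 0:
            raise ValueError("poisson counts scale must be > 0")

    @property
    def is_identity(self) -> bool:
        if self.kind == "gaussian":
            return self.mean == 0.0 and self.variance == 0.0
        if self.kind == "speckle":
            return self.variance == 0.0
        if self.kind == "salt_pepper":
            return self.density == 0.0
        return False


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply one noise model; deterministic for a fixed spec seed."""
    image = np.asarray(image, dtype=float)
    if spec.is_identity:
        return image.copy()
    rng = np.random.default_rng(spec.seed)
    lo = image.min()
    hi = image.max()
    span = hi - lo if hi > lo else 1.0

    if spec.kind == "salt_pepper":
        # impulse noise touches only the hit pixels; write extremes on the
        # original scale so untouched pixels stay bit-identical
        hit = rng.random(image.shape) < spec.density
        salt = rng.random(image.shape) < 0.5
        out = image.copy()
        out[hit & salt] = lo + span
        out[hit & ~salt] = lo
        return out

    x = (image - lo) / span
    if spec.kind == "gaussian":
        x = x + rng.normal(spec.mean, np.sqrt(spec.variance), size=x.shape)
    elif spec.kind == "poisson":
        c = spec.poisson_counts_scale
        x = rng.poisson(x * c).astype(float) / c
    else:  # speckle
        half_width = np.sqrt(3.0 * spec.variance)  # uniform(-a, a) has variance a^2/3
        x = x * (1.0 + rng.uniform(-half_width, half_width, size=x.shape))

    x = np.clip(x, 0.0, 1.0)
    return lo + x * span


# ---------------------------------------------------------------------------
# noise robustness study
# ---------------------------------------------------------------------------

def noise_study(
    channels: Sequence[np.ndarray],
    detection: DetectionParams,
    restriction: RestrictionParams,
    pixel_size_um: float,
    overlap_threshold: float,
    specs: Sequence[NoiseSpec],
) -> pd.DataFrame:
    """Metric robustness of PCC (normalized), M1 and R1 under noise.

    For each noise condition, channel 2 of every input image is that
    image plus noise; both channels run through the fixed detection and
    restriction settings, and the three metrics are computed between
    original and noisy channel, then aggregated (mean, SD) across
    images.  Per-image metric failures become missing values with a
    warning.
    """
    from .pipeline import analyze_channel

    rows = []
    for spec in specs:
        vals = {"pcc_normalized": [], "m1": [], "r1": []}
        for i, ch1 in enumerate(channels):
            ch1 = np.asarray(ch1, dtype=float)
            ch2 = add_noise(ch1, replace(spec, seed=(spec.seed + 7717 * i) % 2**31))
            try:
                a1 = analyze_channel(ch1, detection, restriction, pixel_size_um)
                a2 = analyze_channel(ch2, detection, restriction, pixel_size_um)
                sig1 = a1.labels > 0
                sig2 = a2.labels > 0
                vals["pcc_normalized"].append(pcc_normalized(ch1, ch2))
                vals["m1"].append(manders(sig1, sig2)[0])
                vals["r1"].append(roi_overlap_ratio(a1.labels, sig2, overlap_threshold))
            except ValueError as exc:
                warnings.warn(f"noise study image {i} ({spec.kind}): {exc}", stacklevel=2)
                for key in vals:
                    vals[key].append(float("nan"))
        row = {
            "kind": spec.kind,
            "mean": spec.mean,
            "variance": spec.variance,
            "density": spec.density,
            "n": len(channels),
        }
        for key, series in vals.items():
            arr = np.asarray(series, dtype=float)
            row[f"{key}_mean"] = float(np.nanmean(arr)) if np.any(np.isfinite(arr)) else float("nan")
            row[f"{key}_sd"] = float(np.nanstd(arr, ddof=1)) if np.sum(np.isfinite(arr)) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
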