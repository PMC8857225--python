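"""Synthetic stress-MBF polar-map generator.

Emulates quantitative stress-perfusion bullseye plots: segmental myocardial
blood flow (MBF, ml/g/min) rendered with a rainbow colormap uniformly
scaled over a fixed display window (default 0-3.5 ml/g/min). A case is
ischemic (label 1) exactly when at least one segment falls strictly below
the ischemia cut-off (default 2.3 ml/g/min).

Ischemic cases carry one contiguous angular defect — anchored in a coronary
territory and allowed to spill into an adjacent one — whose core MBF is
drawn from the defect range; the defect edge blends sigmoidally over a few
degrees, mimicking the smooth perfusion transitions of clinical maps.
Non-ischemic cases are a normal-range level plus a smooth low-frequency
noise field, clipped to stay at or above the threshold. A configurable
fraction of cases is made "borderline": their extreme MBF lies within
+/-0.2 ml/g/min of the cut-off, the visually hard regime.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import uniform_filter1d

from .colormap import DEFAULT_SCALE, mbf_to_rgb
from .geometry import TERRITORIES, TerritoryLayout, polar_coordinates


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration, naming the field."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a ~140-subject stress-perfusion cohort with ~40%
    ischemic prevalence and 1024x1024 exported images.
    """

    n_cases: int = 138
    ischemic_fraction: float = 56 / 138
    normal_mbf_range: tuple = (2.5, 3.5)
    defect_mbf_range: tuple = (0.8, 2.2)
    ischemia_threshold: float = 2.3
    display_scale: tuple = DEFAULT_SCALE
    defect_extent_range: tuple = (0.3, 1.0)
    borderline_fraction: float = 0.1
    noise_sd: float = 0.15
    image_size: int = 1024
    jpeg_quality: int = 95
    seed: int = 0
    layout: TerritoryLayout = field(default_factory=TerritoryLayout)

    def validate(self) -> "SyntheticConfig":
        lo, hi = self.display_scale
        if not lo < self.ischemia_threshold < hi:
            raise ConfigError(
                "ischemia_threshold must lie strictly inside display_scale"
            )
        if not 0.0 <= self.ischemic_fraction <= 1.0:
            raise ConfigError("ischemic_fraction must be in [0, 1]")
        if not 0.0 <= self.borderline_fraction <= 1.0:
            raise ConfigError("borderline_fraction must be in [0, 1]")
        if self.defect_mbf_range[0] > self.defect_mbf_range[1] or (
            self.defect_mbf_range[1] >= self.ischemia_threshold
        ):
            raise ConfigError(
                "defect_mbf_range must lie entirely below ischemia_threshold"
            )
        if self.normal_mbf_range[0] > self.normal_mbf_range[1] or (
            self.normal_mbf_range[0] < self.ischemia_threshold
        ):
            raise ConfigError(
                "normal_mbf_range must lie entirely at or above "
                "ischemia_threshold"
            )
        if not 0.0 < self.defect_extent_range[0] <= self.defect_extent_range[1] <= 1.0:
            raise ConfigError("defect_extent_range must satisfy 0 < min <= max <= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        return self


@dataclass
class SegmentalMBF:
    """Ground-truth stress MBF per bullseye segment (ml/g/min)."""

    values: np.ndarray
    layout: TerritoryLayout

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("segment grid is empty")
        if self.values.size != self.layout.n_segments:
            raise ValueError(
                f"expected {self.layout.n_segments} segments, "
                f"got {self.values.size}"
            )
        if (self.values < 0).any():
            raise ValueError("MBF values must be non-negative")

    @property
    def segment_territory(self) -> list[str]:
        return self.layout.segment_territories()


@dataclass
class RenderedCase:
    """One exported study: image raster, binary label and its MBF truth."""

    image: np.ndarray
    label: int
    truth: SegmentalMBF
    case_id: str


def _smooth_noise(rng, n, sd):
    """Low-frequency angular noise: circular moving average of white noise."""
    if sd == 0:
        return np.zeros(n)
    raw = rng.normal(0.0, 1.0, n)
    smooth = uniform_filter1d(raw, size=max(3, n // 4), mode="wrap")
    s = smooth.std()
    return smooth / s * sd if s > 0 else np.zeros(n)


def sample_case(config: SyntheticConfig, case_seed: int):
    """Draw one ground-truth segmental MBF field and its label.

    Deterministic given (config, case_seed): the generator stream is keyed
    on both the dataset seed and the case seed.
    """
    config.validate()
    layout = config.layout
    rng = np.random.default_rng([config.seed, int(case_seed)])
    thr = config.ischemia_threshold
    n_lo, n_hi = config.normal_mbf_range
    ischemic = rng.random() < config.ischemic_fraction
    borderline = rng.random() < config.borderline_fraction

    centers = layout.segment_centers()
    base_level = rng.uniform(n_lo, n_hi)
    noise = _smooth_noise(rng, layout.n_segments, config.noise_sd)
    values = np.clip(base_level + noise, thr, config.display_scale[1])

    if not ischemic:
        if borderline:
            # drag the global minimum to just above the cut-off
            values = values - values.min() + thr + rng.uniform(0.0, 0.2)
            values = np.clip(values, thr, config.display_scale[1])
        return SegmentalMBF(values, layout), 0

    d_lo, d_hi = config.defect_mbf_range
    if borderline:
        d_lo = max(d_lo, thr - 0.2)
    depth = rng.uniform(d_lo, d_hi)
    territory = TERRITORIES[rng.integers(len(TERRITORIES))]
    t_lo, t_hi = layout.territory_spans[territory]
    extent = rng.uniform(*config.defect_extent_range)
    half_width = extent * (t_hi - t_lo) / 2.0
    center_angle = rng.uniform(t_lo, t_hi)

    # transmural angular defect with a sigmoidal edge over ~5 degrees
    edge_scale = 1.25
    ang = centers[:, 1]
    delta = np.abs((ang - center_angle + 180.0) % 360.0 - 180.0)
    w = 1.0 / (1.0 + np.exp((delta - half_width) / edge_scale))
    w[: layout.n_apex_sectors] = 0.0  # apex spared
    values = (1.0 - w) * values + w * depth
    # the segment at the defect core carries the drawn defect MBF exactly
    outer = np.arange(layout.n_apex_sectors, layout.n_segments)
    core = outer[np.argmin(delta[outer])]
    values[core] = depth
    return SegmentalMBF(values, layout), 1


def render_polar_map(
    mbf: SegmentalMBF,
    layout: TerritoryLayout | None = None,
    scale=DEFAULT_SCALE,
    size: int = 1024,
    overlay: bool = False,
):
    """Rasterize a segmental MBF field as an RGB bullseye.

    Pixels take the rainbow LUT color of their segment's (clipped) MBF;
    everything outside the disc is black. With ``overlay=True`` territory
    boundaries are drawn in white, a color absent from the LUT.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    layout = layout or mbf.layout
    r, theta = polar_coordinates(size)
    seg = layout.segment_of(r, theta)
    inside = seg >= 0
    img = np.zeros((size, size, 3), dtype=np.uint8)
    colors = mbf_to_rgb(mbf.values, scale=scale)
    img[inside] = colors[np.maximum(seg[inside], 0)]
    if overlay:
        bounds = np.zeros((size, size), dtype=bool)
        for lo, _hi in layout.territory_spans.values():
            d = np.abs((theta - lo + 180.0) % 360.0 - 180.0)
            bounds |= (d < 0.8) & (r > layout.apex_radius) & (r <= 1.0)
        bounds |= np.abs(r - layout.apex_radius) < 0.004
        img[bounds] = (255, 255, 255)
    return img


def bullseye_bbox(size: int, margin: int = 2):
    """Crop rectangle (top, left, height, width) enclosing the bullseye."""
    radius = 0.45 * size
    c = (size - 1) / 2.0
    lo = max(0, int(np.floor(c - radius)) - margin)
    hi = min(size, int(np.ceil(c + radius)) + 1 + margin)
    return (lo, lo, hi - lo, hi - lo)


def generate_cases(config: SyntheticConfig):
    """Yield ``RenderedCase`` objects for the whole configured dataset."""
    config.validate()
    for i in range(config.n_cases):
        mbf, label = sample_case(config, i)
        img = render_polar_map(
            mbf, scale=config.display_scale, size=config.image_size
        )
        assert label == int(mbf.values.min() < config.ischemia_threshold)
        yield RenderedCase(img, label, mbf, f"case_{i:04d}")


def export_dataset(cases, directory, jpeg_quality: int = 95):
    """Write JPEGs + one-line label sidecars + truth and manifest CSVs.

    Returns the manifest: a list of dicts with case_id, image path, label
    path and label.
    """
    os.makedirs(directory, exist_ok=True)
    manifest = []
    truth_path = os.path.join(directory, "truth.csv")
    manifest_path = os.path.join(directory, "manifest.csv")
    try:
        with open(truth_path, "w", newline="") as th:
            tw = csv.writer(th)
            tw.writerow(["case_id", "segment_id", "territory", "mbf"])
            for case in cases:
                img_path = os.path.join(directory, f"{case.case_id}.jpg")
                lbl_path = os.path.join(directory, f"{case.case_id}.txt")
                Image.fromarray(case.image).save(
                    img_path, quality=jpeg_quality
                )
                with open(lbl_path, "w") as lh:
                    lh.write(f"{case.label}\n")
                for sid, (terr, v) in enumerate(
                    zip(case.truth.segment_territory, case.truth.values)
                ):
                    tw.writerow([case.case_id, sid, terr, f"{v:.6f}"])
                manifest.append(
                    {
                        "case_id": case.case_id,
                        "image": img_path,
                        "label_file": lbl_path,
                        "label": case.label,
                    }
                )
        with open(manifest_path, "w", newline="") as mh:
            mw = csv.DictWriter(
                mh, fieldnames=["case_id", "image", "label_file", "label"]
            )
            mw.writeheader()
            mw.writerows(manifest)
    except OSError as exc:
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return manifest


def with_separation(config: SyntheticConfig, defect_max=2.0, normal_min=2.8):
    """Variant config with well-separated defect and normal MBF ranges."""
    return replace(
        config,
        defect_mbf_range=(config.defect_mbf_range[0], defect_max),
        normal_mbf_range=(normal_min, config.normal_mbf_range[1]),
        borderline_fraction=0.0,
    )
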