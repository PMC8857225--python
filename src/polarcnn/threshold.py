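"""Clinical threshold comparator: ischemia from the stress-MBF cut-off.

The quantitative reading calls a study ischemic when a clinically
significant region of the bullseye has stress MBF strictly below the
cut-off (default 2.3 ml/g/min). "Clinically significant" is
operationalized as at least ``min_defect_segments`` contiguous
sub-threshold segments (default 1, the plain cut-off rule). The rule can
run either on ground-truth segmental MBF or on a rendered image by
inverting the rainbow colormap and taking the per-segment median of the
recovered pixel values (robust to JPEG edge artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colormap import DEFAULT_SCALE, rgb_to_mbf
from .geometry import TerritoryLayout, polar_coordinates
from .synth import SegmentalMBF


@dataclass(frozen=True)
class ClinicalRuleConfig:
    threshold: float = 2.3
    min_defect_segments: int = 1
    source: str = "truth_mbf"  # or "inverted_image"
    display_scale: tuple = DEFAULT_SCALE

    def __post_init__(self):
        lo, hi = self.display_scale
        if not lo < self.threshold < hi:
            raise ValueError("threshold must lie inside the display scale")


def _largest_component(mask: np.ndarray, layout: TerritoryLayout) -> int:
    """Size of the largest connected sub-threshold segment component."""
    nbrs = layout.adjacency()
    seen = set()
    best = 0
    for start in np.flatnonzero(mask):
        if start in seen:
            continue
        stack = [int(start)]
        seen.add(int(start))
        size = 0
        while stack:
            node = stack.pop()
            size += 1
            for nb in nbrs[node]:
                if mask[nb] and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        best = max(best, size)
    return best


def classify_by_threshold(
    mbf: SegmentalMBF, config: ClinicalRuleConfig = ClinicalRuleConfig()
) -> int:
    """1 iff >= min_defect_segments contiguous segments are below cut-off."""
    sub = mbf.values < config.threshold
    if not sub.any():
        return 0
    if config.min_defect_segments <= 1:
        return 1
    return int(
        _largest_component(sub, mbf.layout) >= config.min_defect_segments
    )


def segment_medians_from_image(
    image,
    layout: TerritoryLayout | None = None,
    scale=DEFAULT_SCALE,
    min_valid_fraction: float = 0.25,
) -> SegmentalMBF:
    """Recover segmental MBF from a rendered bullseye image.

    Accepts a preprocessed [0,1] image or an 8-bit raster (bullseye
    centered and filling the frame, as produced by the crop pipeline).
    Raises if too few pixels carry recognizable colormap colors.
    """
    layout = layout or TerritoryLayout()
    px = np.asarray(getattr(image, "pixels", image))
    if px.dtype != np.uint8:
        px = np.round(np.clip(px, 0.0, 1.0) * 255.0).astype(np.uint8)
    size = px.shape[0]
    mbf_px = rgb_to_mbf(px, scale=scale)
    r, theta = polar_coordinates(size, radius_px=size / 2.0 - 1.0)
    seg = layout.segment_of(r, theta)
    valid = (seg >= 0) & np.isfinite(mbf_px)
    inside = seg >= 0
    if valid.sum() < min_valid_fraction * max(inside.sum(), 1):
        raise ValueError(
            "unrecognized palette: too few pixels match the rainbow LUT"
        )
    values = np.empty(layout.n_segments)
    for sid in range(layout.n_segments):
        sel = valid & (seg == sid)
        values[sid] = (
            np.median(mbf_px[sel]) if sel.any() else scale[1]
        )  # unseen segment: assume normal
    return SegmentalMBF(values, layout)


def classify_image_by_threshold(
    image,
    layout: TerritoryLayout | None = None,
    config: ClinicalRuleConfig = ClinicalRuleConfig(),
) -> int:
    """Apply the cut-off rule to a rendered image via colormap inversion."""
    mbf = segment_medians_from_image(
        image, layout=layout, scale=config.display_scale
    )
    return classify_by_threshold(mbf, config)
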