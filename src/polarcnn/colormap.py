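"""Rainbow pseudo-color lookup table and its inversion.

Quantitative polar maps encode stress myocardial blood flow (MBF, ml/g/min)
as color. The LUT used here is a piecewise-linear HSV sweep: hue runs from
240 deg (blue, at the display minimum) to 0 deg (red, at the display
maximum) at full saturation and value. The sweep is documented so that the
renderer, the inverter and the image-based threshold classifier are
mutually consistent:

    t   = clip((mbf - vmin) / (vmax - vmin), 0, 1)
    hue = (1 - t) * 240 deg,  S = V = 1

Every LUT color has max(R,G,B) = 255 and min(R,G,B) = 0, so pure black
(background) and pure white/gray (optional overlays) never collide with
tissue colors; both map to the ``NO_TISSUE`` sentinel (NaN) on inversion.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy.spatial import cKDTree

#: Sentinel returned by :func:`rgb_to_mbf` for background/overlay pixels.
NO_TISSUE = np.nan

#: Default display window for stress MBF (ml/g/min).
DEFAULT_SCALE = (0.0, 3.5)

_HUE_MAX = 240.0 / 360.0  # blue end of the sweep


def mbf_to_rgb(values, scale=DEFAULT_SCALE):
    """Map MBF values (ml/g/min) to 8-bit RGB via the rainbow LUT.

    Values outside ``scale`` are clipped to the window edges, mirroring a
    display uniformly scaled over a fixed range.
    """
    vmin, vmax = float(scale[0]), float(scale[1])
    if not vmin < vmax:
        raise ValueError(f"scale must satisfy min < max, got {scale}")
    values = np.asarray(values, dtype=float)
    t = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    hsv = np.stack(
        [(1.0 - t) * _HUE_MAX, np.ones_like(t), np.ones_like(t)], axis=-1
    )
    return np.round(hsv_to_rgb(hsv) * 255.0).astype(np.uint8)


def build_lut(scale=DEFAULT_SCALE, n=2048):
    """Tabulate the LUT: returns (mbf_grid, float RGB colors in 0..255)."""
    vmin, vmax = float(scale[0]), float(scale[1])
    grid = np.linspace(vmin, vmax, n)
    colors = mbf_to_rgb(grid, scale=scale).astype(float)
    return grid, colors


def tissue_mask(pixels, *, min_value=0.15, min_saturation=0.30):
    """Boolean mask of pixels carrying tissue color.

    Rejects near-black background (low HSV value) and near-achromatic
    overlay colors (low saturation), neither of which occurs on the
    full-saturation rainbow sweep.
    """
    px = np.asarray(pixels, dtype=float)
    hi = px.max(axis=-1)
    lo = px.min(axis=-1)
    value = hi / 255.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(hi > 0, (hi - lo) / np.maximum(hi, 1e-12), 0.0)
    return (value >= min_value) & (sat >= min_saturation)


def rgb_to_mbf(pixels, scale=DEFAULT_SCALE, *, lut_size=2048):
    """Invert rainbow colors back to MBF estimates (ml/g/min).

    Each tissue pixel is assigned the MBF whose LUT color is nearest in
    RGB space (nearest-neighbor over a dense tabulation of the sweep).
    Background and overlay pixels receive the ``NO_TISSUE`` sentinel.

    Accepts a single pixel, a flat pixel list or an image array; the
    returned array drops the trailing channel axis.
    """
    px = np.asarray(pixels, dtype=float)
    scalar = px.ndim == 1
    flat = px.reshape(-1, 3)
    grid, colors = build_lut(scale=scale, n=lut_size)
    out = np.full(flat.shape[0], NO_TISSUE)
    ok = tissue_mask(flat)
    if ok.any():
        _, idx = cKDTree(colors).query(flat[ok])
        out[ok] = grid[idx]
    out = out.reshape(px.shape[:-1])
    return float(out) if scalar else out
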