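"""Dataset I/O: crop, resize, normalize polar maps; labels; splits.

The processing contract follows the export pipeline of quantitative
perfusion software: high-resolution RGB rasters are cropped to a
predefined rectangle around the bullseye, resized to 256x256 with a
bilinear (antialiased) kernel, and scaled to [0, 1] with all three color
channels retained. Labels live in one-line text sidecars (1 = ischemic,
0 = non-ischemic).

Splitting draws the hold-out test set first, then carves the remaining
pool into training and validation with ``val_fraction`` (default 1/3)
assigned to validation; the train count is the floor of the complementary
fraction, so 138 cases with both fractions at 1/3 yield 61/31/46.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import chi2_contingency

TARGET_SIZE = 256


@dataclass
class PolarMapImage:
    """Preprocessed network input: 256x256x3 reals in [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.shape != (TARGET_SIZE, TARGET_SIZE, 3):
            raise ValueError(
                f"expected {(TARGET_SIZE, TARGET_SIZE, 3)}, got {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")


@dataclass
class LabeledCase:
    image: PolarMapImage
    label: int
    case_id: str

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test id sets covering all cases."""

    train_ids: tuple
    val_ids: tuple
    test_ids: tuple
    seed: int
    val_fraction: float = 1 / 3
    test_fraction: float = 1 / 3

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split id sets must be pairwise disjoint")

    @property
    def all_ids(self):
        return self.train_ids + self.val_ids + self.test_ids

    def summary(self, labels: dict) -> pd.DataFrame:
        rows = []
        for name, ids in (
            ("train", self.train_ids),
            ("val", self.val_ids),
            ("test", self.test_ids),
        ):
            pos = sum(labels[i] for i in ids)
            rows.append({"split": name, "n": len(ids), "positives": pos})
        return pd.DataFrame(rows)


def crop_polar_map(raw: np.ndarray, rect) -> np.ndarray:
    """Extract the (top, left, height, width) window; 0-based, half-open."""
    top, left, height, width = (int(v) for v in rect)
    h, w = raw.shape[:2]
    if top < 0:
        raise ValueError("crop rectangle exceeds image bounds at the top")
    if left < 0:
        raise ValueError("crop rectangle exceeds image bounds on the left")
    if top + height > h:
        raise ValueError("crop rectangle exceeds image bounds at the bottom")
    if left + width > w:
        raise ValueError("crop rectangle exceeds image bounds on the right")
    return raw[top : top + height, left : left + width]


def preprocess(raster: np.ndarray, source_path: str = "") -> PolarMapImage:
    """Bilinear-resize an 8-bit RGB raster to 256x256 and scale to [0, 1]."""
    raster = np.asarray(raster)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise ValueError(
            f"expected an RGB raster with 3 channels, got shape {raster.shape}"
        )
    if raster.dtype != np.uint8:
        raise ValueError(f"expected 8-bit input, got dtype {raster.dtype}")
    im = Image.fromarray(raster).resize(
        (TARGET_SIZE, TARGET_SIZE), Image.Resampling.BILINEAR
    )
    return PolarMapImage(np.asarray(im, dtype=np.float32) / 255.0, source_path)


def read_label(path) -> int:
    """Parse a one-line 0/1 label sidecar (surrounding whitespace allowed)."""
    with open(path) as fh:
        content = fh.read()
    token = content.strip()
    if token not in ("0", "1"):
        raise ValueError(f"invalid label {content!r} in {path}")
    return int(token)


def load_case(image_path, label_path=None, crop_rect=None) -> LabeledCase:
    """Read one JPEG/PNG polar map (+ optional sidecar) through the pipeline."""
    raw = np.asarray(Image.open(image_path).convert("RGB"))
    if crop_rect is not None:
        raw = crop_polar_map(raw, crop_rect)
    label = 0 if label_path is None else read_label(label_path)
    case_id = os.path.splitext(os.path.basename(image_path))[0]
    return LabeledCase(preprocess(raw, str(image_path)), label, case_id)


def load_directory(directory, crop_rect=None) -> list[LabeledCase]:
    """Load every image with a matching .txt sidecar from a directory."""
    cases = []
    for name in sorted(os.listdir(directory)):
        stem, ext = os.path.splitext(name)
        if ext.lower() not in (".jpg", ".jpeg", ".png"):
            continue
        lbl = os.path.join(directory, stem + ".txt")
        cases.append(
            load_case(
                os.path.join(directory, name),
                lbl if os.path.exists(lbl) else None,
                crop_rect,
            )
        )
    return cases


def crop_qc(raw: np.ndarray, rect, min_retained: float = 0.99) -> bool:
    """Automated stand-in for visual crop inspection.

    Checks that at least ``min_retained`` of the non-black pixels of the
    source survive the crop.
    """
    nonblack = np.asarray(raw).max(axis=-1) > 0
    total = nonblack.sum()
    if total == 0:
        return True
    top, left, height, width = rect
    kept = nonblack[top : top + height, left : left + width].sum()
    return kept / total >= min_retained


def split_dataset(
    case_ids,
    test_fraction: float = 1 / 3,
    val_fraction: float = 1 / 3,
    seed: int = 0,
) -> SplitSpec:
    """Randomly partition case ids into train/validation/test.

    The test set of ``round(n * test_fraction)`` ids is drawn first; of the
    remaining pool, ``floor(pool * (1 - val_fraction))`` go to training and
    the rest to validation. Deterministic given (ids, fractions, seed).
    """
    ids = [c.case_id if isinstance(c, LabeledCase) else c for c in case_ids]
    n = len(ids)
    n_test = int(round(n * test_fraction))
    n_pool = n - n_test
    n_train = int(np.floor(n_pool * (1.0 - val_fraction)))
    n_val = n_pool - n_train
    if min(n_train, n_val, n_test) < 3:
        raise ValueError(
            f"too few cases for a {n_train}/{n_val}/{n_test} split; "
            "need at least 3 per split"
        )
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return SplitSpec(
        train_ids=tuple(shuffled[n_test : n_test + n_train]),
        val_ids=tuple(shuffled[n_test + n_train :]),
        test_ids=tuple(shuffled[:n_test]),
        seed=seed,
        val_fraction=val_fraction,
        test_fraction=test_fraction,
    )


def check_split_independence(spec: SplitSpec, labels: dict) -> pd.DataFrame:
    """Pairwise Pearson chi-squared tests of label-split independence.

    For each pair of splits, tests the 2x2 split-membership x label table
    (no continuity correction). Pairs with p <= 0.05 are flagged as
    dependent; single-class splits are noted, not raised.
    """
    groups = {
        "train": [labels[i] for i in spec.train_ids],
        "val": [labels[i] for i in spec.val_ids],
        "test": [labels[i] for i in spec.test_ids],
    }
    for name, ls in groups.items():
        if len(ls) == 0:
            raise ValueError(f"split {name!r} is empty")
    rows = []
    pairs = [("train", "val"), ("train", "test"), ("val", "test")]
    for a, b in pairs:
        la, lb = groups[a], groups[b]
        table = np.array(
            [
                [sum(la), len(la) - sum(la)],
                [sum(lb), len(lb) - sum(lb)],
            ]
        )
        note = ""
        if (np.array([sum(la), len(la) - sum(la)]) == 0).any() or (
            np.array([sum(lb), len(lb) - sum(lb)]) == 0
        ).any():
            note = "single-class split"
        if (table.sum(axis=0) == 0).any():
            stat, p = np.nan, np.nan
            note = note or "degenerate table"
        else:
            stat, p, _, _ = chi2_contingency(table, correction=False)
        rows.append(
            {
                "pair": f"{a}-{b}",
                "chi2": stat,
                "p_value": p,
                "dependent": bool(p <= 0.05) if np.isfinite(p) else False,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def pearson_chi2(table) -> tuple:
    """Pearson chi-squared statistic and p-value, no continuity correction."""
    stat, p, _, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)
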