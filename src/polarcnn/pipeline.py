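"""End-to-end glue: synthetic generation through network-ready tensors."""

from __future__ import annotations

from .data import LabeledCase, crop_polar_map, preprocess
from .synth import SyntheticConfig, bullseye_bbox, generate_cases


def synthesize_cases(config: SyntheticConfig):
    """Generate a synthetic cohort and push it through the image pipeline.

    Each case is rendered, cropped to the bullseye bounding box, resized to
    256x256 and scaled to [0, 1]; the raw raster is dropped immediately to
    keep memory flat. Returns (list of LabeledCase, list of SegmentalMBF
    ground truths) in case order.
    """
    rect = bullseye_bbox(config.image_size)
    cases, truths = [], []
    for rc in generate_cases(config):
        img = crop_polar_map(rc.image, rect)
        cases.append(LabeledCase(preprocess(img), rc.label, rc.case_id))
        truths.append(rc.truth)
    return cases, truths
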