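"""Method configuration and training glue.

A :class:`MethodConfig` names one of the five pixel classifiers together
with its color space and tuning parameters; :func:`train_segmenter` turns a
config, a reference image and a set of circular template selections into a
:class:`TrainedSegmenter` that maps any RGB frame to a binary grape mask
(handling the HSV conversion internally).  Trained segmenters are pure:
the same image always yields the same mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import segmentation as seg
from .colorspace import RGB, ColorImage, rgb_to_hsv_shifted
from .morphology import parse_sequence, apply_sequence
from .segmentation import (
    BACKGROUND_PRIOR,
    GRAPE_PRIOR,
    TemplateSelection,
    sample_template,
)

__all__ = ["TemplateSet", "MethodConfig", "TrainedSegmenter", "train_segmenter"]

METHODS = ("threshold", "mahalanobis", "bayes", "lcm", "histogram")


@dataclass
class TemplateSet:
    """Manual circular selections for the grape and background classes.

    The two-class Gaussian and histogram methods follow the two-template
    field protocol: they train on ``grape[0]`` and ``background[0]`` only,
    so ``background[0]`` should be a larger circle over a *mixed* background
    region (leaves, branches and dark areas together).  The
    linear-color-model method instead trains one line per selection, using
    every grape and background circle.
    """

    grape: list[TemplateSelection]
    background: list[TemplateSelection]

    def __post_init__(self) -> None:
        if not self.grape:
            raise ValueError("need at least one grape template")


@dataclass
class MethodConfig:
    """One segmentation method plus its tunable parameters.

    ``color_space`` is ``"RGB"`` or ``"HSV"`` (the shifted-hue HSV space).
    ``layer`` applies to the threshold method only; ``priors`` to the Bayes
    classifier; ``bins``/``radius`` to the histogram method.  ``morph`` is a
    cleanup sequence in "HF + 4E + 4D" notation applied after segmentation
    when requested.
    """

    method: str
    color_space: str = "RGB"
    layer: str = "H"
    priors: tuple[float, float] = (GRAPE_PRIOR, BACKGROUND_PRIOR)
    bins: int = 128
    radius: int = 6
    morph: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.color_space not in ("RGB", "HSV"):
            raise ValueError("color_space must be 'RGB' or 'HSV'")
        if self.method == "threshold":
            # the layer pins the space: H/S/V live in HSV, R/G/B/I in RGB
            self.color_space = "HSV" if self.layer in ("H", "S", "V") else "RGB"

    @property
    def name(self) -> str:
        if self.method == "threshold":
            return f"threshold[{self.layer}]"
        return f"{self.method}[{self.color_space}]"


def _to_space(img: ColorImage, color_space: str) -> ColorImage:
    if color_space == "HSV":
        return rgb_to_hsv_shifted(img) if img.space == RGB else img
    if img.space != RGB:
        raise ValueError("RGB methods need an RGB input image")
    return img


@dataclass
class TrainedSegmenter:
    """A trained method: ``segment(img)`` yields the raw mask,
    ``segment_filtered(img)`` additionally applies the configured
    morphological sequence."""

    config: MethodConfig
    models: dict

    def segment(self, img: ColorImage) -> np.ndarray:
        cfg = self.config
        work = _to_space(img, cfg.color_space)
        if cfg.method == "threshold":
            from .colorspace import extract_layer

            layer = extract_layer(work, cfg.layer)
            return seg.threshold_segment(layer, self.models["rule"])
        if cfg.method == "mahalanobis":
            return seg.mahalanobis_segment(
                work, self.models["grape"], self.models["background"]
            )
        if cfg.method == "bayes":
            return seg.bayes_segment(
                work, self.models["grape"], self.models["background"]
            )
        if cfg.method == "lcm":
            return seg.lcm_segment(
                work, self.models["grape_lines"], self.models["background_lines"]
            )
        return seg.histogram_segment(work, self.models["histogram"])

    def segment_filtered(self, img: ColorImage) -> np.ndarray:
        mask = self.segment(img)
        if self.config.morph:
            mask = apply_sequence(mask, parse_sequence(self.config.morph))
        return mask


def train_segmenter(
    config: MethodConfig,
    reference: ColorImage,
    templates: TemplateSet | None = None,
) -> TrainedSegmenter:
    """Train one method on the reference image.

    Thresholding needs no templates (Otsu fixes the level on the reference
    frame); every other method samples the template circles on the
    reference image in the configured color space.
    """
    from .colorspace import extract_layer

    work = _to_space(reference, config.color_space)

    if config.method == "threshold":
        rule = seg.train_threshold_rule(extract_layer(work, config.layer))
        return TrainedSegmenter(config, {"rule": rule})

    if templates is None:
        raise ValueError(f"method {config.method!r} requires template selections")

    if config.method in ("mahalanobis", "bayes"):
        # two-template protocol: one grape circle and one mixed background
        # circle define the two classes
        if not templates.background:
            raise ValueError("Gaussian methods need a background template")
        p_grape, p_bg = config.priors
        grape = seg.fit_gaussian_model(
            sample_template(work, templates.grape[0]), prior=p_grape
        )
        bg = seg.fit_gaussian_model(
            sample_template(work, templates.background[0]), prior=p_bg
        )
        return TrainedSegmenter(config, {"grape": grape, "background": bg})

    if config.method == "lcm":
        # one line per selection: several grape selections capture shading,
        # several background selections capture leaves/branches/soil.  A
        # mixed background circle (meant for the two-template methods) has
        # no single linear color relationship, so it is skipped here.
        bg_sels = [s for s in templates.background if "mixed" not in s.label]
        if not bg_sels:
            bg_sels = templates.background
        if not bg_sels:
            raise ValueError("LCM needs background templates")
        grape_lines = [
            seg.fit_line_model(sample_template(work, s), label="grape")
            for s in templates.grape
        ]
        bg_lines = [
            seg.fit_line_model(sample_template(work, s), label="background")
            for s in bg_sels
        ]
        return TrainedSegmenter(
            config, {"grape_lines": grape_lines, "background_lines": bg_lines}
        )

    # histogram: trained on the single grape template only
    hist = seg.build_dilated_histogram(
        sample_template(work, templates.grape[0]),
        bins=config.bins,
        radius=config.radius,
    )
    return TrainedSegmenter(config, {"histogram": hist})
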