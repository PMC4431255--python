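"""Validation metrics and the method-comparison harness.

Segmentation quality is scored against manual labels with the XOR error:
the number of pixels on which the automatic and manual masks disagree,
normalized by the manual cluster's pixel count (so the metric can exceed 1
when false positives are plentiful).  Scoring is per cluster inside a
padded window around each manual cluster, then averaged unweighted; cluster
detection uses an any-overlap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspace import ColorImage
from .pipeline import MethodConfig, TemplateSet, train_segmenter
from .regions import ClusterRegion, label_clusters

__all__ = [
    "xor_error",
    "detection_fraction",
    "per_cluster_xor_errors",
    "SegmentationScore",
    "compare_methods",
    "scores_to_frame",
]

#: Fractional padding of each manual cluster's bounding box used as the
#: per-cluster evaluation window.
WINDOW_PADDING = 0.25


def xor_error(auto: np.ndarray, manual: np.ndarray) -> float:
    """XOR pixel disagreement normalized by the manual mask's area.

    ``|auto ⊕ manual| / |manual|``; 0 iff the masks are identical, and 2.0
    for disjoint masks of equal area.
    """
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError(f"mask shapes differ: {auto.shape} vs {manual.shape}")
    n_manual = int(manual.sum())
    if n_manual == 0:
        raise ValueError("manual mask has no foreground pixels")
    return float(np.sum(auto ^ manual)) / n_manual


def detection_fraction(
    auto_regions: list[ClusterRegion], truth_masks: list[np.ndarray]
) -> float:
    """Fraction of true clusters overlapped by at least one predicted region
    (any-overlap rule)."""
    if not truth_masks:
        raise ValueError("need at least one truth mask")
    detected = 0
    for truth in truth_masks:
        truth = np.asarray(truth, dtype=bool)
        for region in auto_regions:
            r0, c0, r1, c1 = region.bounding_box
            if truth[r0:r1, c0:c1][region.mask].any():
                detected += 1
                break
    return detected / len(truth_masks)


def _padded_window(
    truth: np.ndarray, padding: float = WINDOW_PADDING
) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(truth.any(axis=1))
    cols = np.flatnonzero(truth.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    pr = int(round((r1 - r0) * padding))
    pc = int(round((c1 - c0) * padding))
    h, w = truth.shape
    return (max(0, r0 - pr), max(0, c0 - pc), min(h, r1 + pr), min(w, c1 + pc))


def per_cluster_xor_errors(
    auto: np.ndarray,
    truth_masks: list[np.ndarray],
    padding: float = WINDOW_PADDING,
) -> list[float]:
    """XOR error of each manual cluster inside its padded bounding window.

    Cropping keeps one cluster's score from being polluted by false
    positives elsewhere in the frame; the padding (25% of the box by
    default) still charges false positives on the cluster's rim.
    """
    errors = []
    for truth in truth_masks:
        truth = np.asarray(truth, dtype=bool)
        r0, c0, r1, c1 = _padded_window(truth, padding)
        errors.append(xor_error(auto[r0:r1, c0:c1], truth[r0:r1, c0:c1]))
    return errors


@dataclass
class SegmentationScore:
    """One comparison-table row for one method."""

    method: str
    color_space: str
    clusters_detected: float
    xor_error: float
    xor_error_filtered: float
    morph_sequence: str


def compare_methods(
    images: list[ColorImage],
    labels: list[list[np.ndarray]],
    configs: list[MethodConfig],
    templates: TemplateSet | None = None,
    reference_index: int = 0,
    min_cluster_size: int | None = None,
) -> list[SegmentationScore]:
    """Score every configured method over a labeled image set.

    Each method is trained once on the reference image (threshold levels by
    Otsu, the template-based methods from ``templates``), then applied to
    all frames.  Per-cluster XOR errors are averaged unweighted, before and
    after the method's configured morphological sequence; detection uses the
    raw mask's regions under the any-overlap rule.  Detection asks only
    whether a method produced *any* evidence of a cluster, so its region
    filter defaults to 0.01% of the frame — much looser than the 0.1%
    yield-pipeline default — while the XOR columns carry the precision.
    """
    if not images:
        raise ValueError("need at least one labeled image")
    if len(images) != len(labels):
        raise ValueError("one label list per image required")
    if any(not lab for lab in labels):
        raise ValueError("every image needs at least one manual cluster mask")

    scores = []
    for config in configs:
        segmenter = train_segmenter(config, images[reference_index], templates)
        raw_errors: list[float] = []
        filt_errors: list[float] = []
        detected = 0
        n_truth = 0
        for img, truth_masks in zip(images, labels):
            raw = segmenter.segment(img)
            filt = segmenter.segment_filtered(img)
            raw_errors.extend(per_cluster_xor_errors(raw, truth_masks))
            filt_errors.extend(per_cluster_xor_errors(filt, truth_masks))
            detect_min = (
                min_cluster_size
                if min_cluster_size is not None
                else max(1, int(round(1e-4 * raw.size)))
            )
            regions = label_clusters(raw, min_cluster_size=detect_min)
            detected += round(detection_fraction(regions, truth_masks) * len(truth_masks))
            n_truth += len(truth_masks)
        scores.append(
            SegmentationScore(
                method=config.name,
                color_space=config.color_space,
                clusters_detected=detected / n_truth,
                xor_error=float(np.mean(raw_errors)),
                xor_error_filtered=float(np.mean(filt_errors)),
                morph_sequence=config.morph,
            )
        )
    return scores


def scores_to_frame(scores: list[SegmentationScore]) -> pd.DataFrame:
    """Comparison-table rows as a DataFrame (one row per method)."""
    return pd.DataFrame(
        {
            "method": [s.method for s in scores],
            "color_space": [s.color_space for s in scores],
            "clusters_detected": [s.clusters_detected for s in scores],
            "xor_error": [s.xor_error for s in scores],
            "xor_error_filtered": [s.xor_error_filtered for s in scores],
            "morph_sequence": [s.morph_sequence for s in scores],
        }
    )
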