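"""Weight calibration and yield estimation.

Calibration relates image-measured cluster size (area in pixels, or the
solid-of-revolution volume) to cluster weight in grams via an ordinary
least-squares line fitted on reference clusters photographed one at a time
against a white background.  The fitted line then converts the sizes of
clusters segmented in vineyard frames into a per-cluster and total yield
estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .colorspace import ColorImage, extract_layer
from .morphology import MorphSequence, apply_sequence
from .regions import ClusterRegion
from .segmentation import DegenerateInputError, otsu_threshold

__all__ = [
    "CalibrationPair",
    "CalibrationModel",
    "YieldEstimate",
    "calibration_reference_mask",
    "fit_calibration",
    "predict_weight",
    "estimate_yield",
]


@dataclass
class CalibrationPair:
    """One reference cluster: measured size, hand-weighed grams, id."""

    measurement: float
    weight: float
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if self.measurement <= 0 or self.weight <= 0:
            raise ValueError("measurement and weight must be positive")


@dataclass
class CalibrationModel:
    """Linear map weight = slope·measurement + intercept.

    ``predictor`` records whether the measurement is the cluster area (px)
    or the solid-of-revolution volume; ``correlation`` is the Pearson r of
    the calibration fit and ``n`` the number of reference clusters.
    """

    predictor: str
    slope: float
    intercept: float
    correlation: float
    n: int

    def __post_init__(self) -> None:
        if self.predictor not in ("area", "volume"):
            raise ValueError("predictor must be 'area' or 'volume'")
        if self.n < 3:
            raise ValueError("a calibration needs at least 3 pairs")
        for v in (self.slope, self.intercept, self.correlation):
            if not np.isfinite(v):
                raise ValueError("calibration coefficients must be finite")

    def predict(self, measurement: float) -> float:
        return predict_weight(self, measurement)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "slope": self.slope,
            "intercept": self.intercept,
            "correlation": self.correlation,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibration_reference_mask(img: ColorImage, n_morph: int = 10) -> np.ndarray:
    """Segment a single dark cluster hung in front of a white background.

    Otsu's threshold on the gray layer with keep-below polarity (the cluster
    is the dark class), followed by ``n_morph`` erosions and ``n_morph``
    dilations to remove noisy pixels.
    """
    gray = extract_layer(img, "I")
    try:
        thr = otsu_threshold(gray)
    except DegenerateInputError as exc:
        raise DegenerateInputError(
            "calibration image is constant; no cluster to segment"
        ) from exc
    mask = gray.values < thr
    seq = MorphSequence([("E", n_morph), ("D", n_morph)])
    return apply_sequence(mask, seq)


def fit_calibration(pairs: list[CalibrationPair], predictor: str) -> CalibrationModel:
    """Ordinary least squares of weight on measurement, with intercept."""
    if predictor not in ("area", "volume"):
        raise ValueError("predictor must be 'area' or 'volume'")
    if len(pairs) < 3:
        raise ValueError("a calibration needs at least 3 pairs")
    x = np.array([p.measurement for p in pairs], dtype=float)
    y = np.array([p.weight for p in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateInputError("all measurements equal; line undefined")
    res = stats.linregress(x, y)
    return CalibrationModel(
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        n=len(pairs),
    )


def predict_weight(model: CalibrationModel, measurement: float) -> float:
    """Predicted grams for one measurement, clamped below at 0."""
    if measurement < 0:
        raise ValueError("measurement must be >= 0")
    return max(0.0, model.slope * measurement + model.intercept)


@dataclass
class YieldEstimate:
    """Per-cluster and total predicted weight, plus error versus truth."""

    per_cluster: list[tuple[int, float]]
    total: float
    relative_error: float | None = None


def estimate_yield(
    regions: list[ClusterRegion],
    model: CalibrationModel,
    true_weights: list[float] | None = None,
) -> YieldEstimate:
    """Convert segmented regions into a yield estimate.

    ``true_weights`` (per ground-truth cluster, when known) yields
    ``relative_error = (estimated − true) / true`` on the totals; the lists
    need not align cluster-by-cluster.
    """
    if not regions:
        raise ValueError("no regions to estimate yield from")
    measurements = [
        r.area if model.predictor == "area" else r.volume for r in regions
    ]
    per_cluster = [
        (r.label, predict_weight(model, m)) for r, m in zip(regions, measurements)
    ]
    total = float(sum(w for _, w in per_cluster))
    relative_error = None
    if true_weights is not None:
        true_total = float(np.sum(true_weights))
        if true_total <= 0:
            raise ValueError("true weights must sum to a positive total")
        relative_error = (total - true_total) / true_total
    return YieldEstimate(per_cluster=per_cluster, total=total, relative_error=relative_error)
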