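"""Seeded generator of night-vineyard scenes with ground truth.

Emulates the statistics of high-resolution night images taken with a ring
flash: a dark, slightly cold-tinted background, granular green foliage
patches, bright gray branch strokes, and reddish grape clusters built from
packed, spherically shaded berries.  Every scene carries exact per-cluster
truth masks and weights drawn from a known linear weight law, so the whole
segmentation → regions → calibration → yield chain can be tested offline.

The default scale is one quarter of the source imagery regime (berry
diameter ≈ 27 px, cluster area ≈ 15,000 px on a 712×1072 frame, versus
109 px berries and 250,000 px clusters on 4288×2848 frames), so the full
test suite runs in seconds; :func:`paper_scale` restores the full-scale
geometry.

Hues are chosen so that the shifted-hue distributions of grape and
background pixels are separable by construction (grapes ≈ 0.60, dark base
and branches ≈ 0.25, foliage ≈ 0.83), while brightness is deliberately
confusable: berry shading spans nearly the full value range and branches
are as bright as lit berries, which is what defeats plain R/G/B/gray
thresholding on this kind of scene.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

from .colorspace import RGB, ColorImage
from .pipeline import TemplateSet
from .segmentation import TemplateSelection

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "CalibrationSample",
    "generate_scene",
    "generate_calibration_set",
    "sample_calibration_pairs",
    "default_templates",
    "paper_scale",
]


@dataclass
class SceneSpec:
    """Parameters of one synthetic vineyard scene.

    ``grape_hue_mean``/``sd`` are on the shifted-hue scale (red at 0.5).
    ``weight_slope``/``intercept``/``noise_sd`` define the ground-truth
    weight law ``w = slope·area + intercept + N(0, noise_sd)`` in grams;
    the defaults give a ≈15,000 px cluster a weight of ≈600 g, with the
    noise level set so the weight-vs-area correlation of a 29-cluster
    calibration lands in the mid-0.9s, the regime reported for real
    laboratory calibrations of this kind.  Densities are counts per
    100,000 pixels.
    """

    image_size: tuple[int, int] = (712, 1072)
    n_clusters: int = 3
    grape_radius_mean: float = 13.5
    grape_radius_sd: float = 1.5
    grapes_per_cluster: tuple[int, int] = (25, 40)
    grape_hue_mean: float = 0.60
    grape_hue_sd: float = 0.02
    grape_saturation: float = 0.75
    foliage_density: float = 1.0
    branch_density: float = 0.5
    darkness: float = 0.05
    sensor_noise_sd: float = 0.003
    weight_slope: float = 0.04
    weight_intercept: float = 0.0
    weight_noise_sd: float = 18.0
    hue_separable: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.grapes_per_cluster[0] < 1:
            raise ValueError("need at least one grape per cluster")
        if self.grape_radius_mean < 3:
            raise ValueError("grape radius must be >= 3 px")


@dataclass
class SceneTruth:
    """A rendered scene plus its exact ground truth.

    ``cluster_masks`` are the exact rendered supports (pairwise disjoint);
    ``material_masks`` mark background materials outside the clusters and
    exist to place background templates deterministically.
    """

    image: ColorImage
    cluster_masks: list[np.ndarray]
    cluster_weights: np.ndarray
    material_masks: dict[str, np.ndarray]
    spec: SceneSpec


@dataclass
class CalibrationSample:
    """One laboratory-style reference shot: cluster on a white background."""

    image: ColorImage
    mask: np.ndarray
    weight: float
    cluster_id: str


def paper_scale(spec: SceneSpec) -> SceneSpec:
    """Rescale a spec to the full-resolution imaging geometry (×4 linear)."""
    return replace(
        spec,
        image_size=(spec.image_size[0] * 4, spec.image_size[1] * 4),
        grape_radius_mean=spec.grape_radius_mean * 4,
        grape_radius_sd=spec.grape_radius_sd * 4,
        weight_slope=spec.weight_slope / 16.0,
        weight_noise_sd=spec.weight_noise_sd,
    )


# ---------------------------------------------------------------------------
# rendering primitives (all operate on H×W hue/sat/val planes in place)
# ---------------------------------------------------------------------------

_LIGHT = np.array([-0.35, -0.35, 0.87])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)


def _paint_disk(planes, center, radius, hue, sat, val, canvas=None) -> None:
    h_img, s_img, v_img = planes
    H, W = h_img.shape
    cy, cx = center
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(H, int(np.ceil(cy + radius)) + 1)
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(W, int(np.ceil(cx + radius)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    h_img[r0:r1, c0:c1][inside] = hue
    s_img[r0:r1, c0:c1][inside] = sat
    v_img[r0:r1, c0:c1][inside] = val
    if canvas is not None:
        canvas[r0:r1, c0:c1][inside] = True


def _paint_grape(planes, mask, center, radius, hue, sat, rng, brightness=1.0) -> None:
    """One spherically shaded berry; updates planes and the cluster mask."""
    h_img, s_img, v_img = planes
    H, W = h_img.shape
    cy, cx = center
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(H, int(np.ceil(cy + radius)) + 1)
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(W, int(np.ceil(cx + radius)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = (yy - cy) / radius
    dx = (xx - cx) / radius
    rho2 = dy * dy + dx * dx
    inside = rho2 <= 1.0
    nz = np.sqrt(np.clip(1.0 - rho2, 0.0, 1.0))
    shade = np.clip(dx * _LIGHT[0] + dy * _LIGHT[1] + nz * _LIGHT[2], 0.02, 1.0)
    # deep Lambert term plus a strong specular cap from the ring flash;
    # the specular reflection carries the flash color, so it desaturates
    # the skin toward white instead of scaling the skin color linearly
    spec_term = shade**10
    val = np.clip(brightness * (0.08 + 0.68 * shade + 0.26 * spec_term), 0.0, 1.0)
    sat_px = sat * (1.0 - 0.85 * spec_term)
    hue_px = (hue + rng.normal(0.0, 0.004, size=val.shape)) % 1.0
    h_img[r0:r1, c0:c1][inside] = hue_px[inside]
    s_img[r0:r1, c0:c1][inside] = sat_px[inside]
    v_img[r0:r1, c0:c1][inside] = val[inside]
    mask[r0:r1, c0:c1][inside] = True


def _pack_cluster(rng, n_grapes, r_mean, r_sd):
    """Offsets and radii of a compact packed-berry cluster around (0, 0)."""
    radii = np.clip(rng.normal(r_mean, r_sd, size=n_grapes), 3.0, None)
    # hard cap on the cluster footprint so chains cannot sprawl and make
    # multi-cluster placement infeasible
    extent_cap = r_mean * (1.0 + 0.9 * np.sqrt(n_grapes))
    offsets = np.zeros((n_grapes, 2))
    for i in range(1, n_grapes):
        # attach near a random placed berry, keeping a minimum spacing to
        # every other berry so the union keeps growing; among admissible
        # candidates prefer the one closest to the centroid (roundish
        # clusters rather than strings)
        centroid = offsets[:i].mean(axis=0)
        best_valid = None
        best_fallback = None
        for _ in range(8):
            j = int(rng.integers(i))
            theta = rng.uniform(0, 2 * np.pi)
            d = 0.85 * (radii[i] + radii[j])
            cand = offsets[j] + d * np.array([np.sin(theta), np.cos(theta)])
            if np.linalg.norm(cand) + radii[i] > extent_cap:
                continue
            ratios = np.linalg.norm(offsets[:i] - cand, axis=1) / (radii[:i] + radii[i])
            min_ratio = float(ratios.min())
            dist = float(np.linalg.norm(cand - centroid))
            if min_ratio >= 0.72 and (best_valid is None or dist < best_valid[0]):
                best_valid = (dist, cand)
            if best_fallback is None or min_ratio > best_fallback[0]:
                best_fallback = (min_ratio, cand)
        if best_valid is not None:
            offsets[i] = best_valid[1]
        elif best_fallback is not None:
            offsets[i] = best_fallback[1]
        else:
            # every candidate hit the footprint cap: tuck the berry inward
            offsets[i] = centroid + rng.normal(0.0, radii[i], size=2)
        i_norm = np.linalg.norm(offsets[i])
        if i_norm + radii[i] > extent_cap and i_norm > 0:
            offsets[i] *= (extent_cap - radii[i]) / i_norm
    return offsets, radii


def _render_cluster(planes, rng, spec, position, offsets, radii, exposure=1.0):
    H, W = planes[0].shape
    mask = np.zeros((H, W), dtype=bool)
    raw_hue_mean = (spec.grape_hue_mean - 0.5) % 1.0
    # draw berries back-to-front in random order; later berries occlude.
    # Per-berry saturation and brightness vary widely (flash distance,
    # ripeness, skin bloom), so one template circle never captures the whole
    # cluster's color distribution — hue alone stays in a tight band.
    for i in rng.permutation(len(radii)):
        hue = (raw_hue_mean + rng.normal(0.0, spec.grape_hue_sd)) % 1.0
        sat = float(np.clip(rng.normal(spec.grape_saturation, 0.15), 0.35, 0.98))
        brightness = exposure * rng.uniform(0.45, 1.0)
        center = (position[0] + offsets[i, 0], position[1] + offsets[i, 1])
        _paint_grape(planes, mask, center, radii[i], hue, sat, rng, brightness)
    return mask


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Render one scene; deterministic for a fixed seed.

    Raises ``RuntimeError`` if the requested clusters cannot be placed
    without overlap within 1000 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size

    # cool night tint, raw hue 0.75 (shifted-hue 0.25): well away from both
    # the grape band (~0.6 shifted) and the hue wrap at raw 0.5, so sensor
    # noise on dark pixels cannot flip them across the wrap
    hue = np.clip(0.75 + rng.normal(0.0, 0.015, (H, W)), 0.0, 1.0)
    sat = np.clip(0.22 + np.abs(rng.normal(0.0, 0.03, (H, W))), 0.0, 1.0)
    val = np.clip(spec.darkness + np.abs(rng.normal(0.0, 0.02, (H, W))), 0.0, 1.0)
    planes = (hue, sat, val)

    branch_mask = np.zeros((H, W), dtype=bool)
    n_branches = int(round(spec.branch_density * H * W / 1e5))
    for _ in range(n_branches):
        y, x = rng.uniform(0, H), rng.uniform(0, W)
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.2, 0.5) * min(H, W)
        thickness = rng.uniform(2.0, 4.0)
        v0 = rng.uniform(0.35, 0.65)
        steps = max(2, int(length))
        for t in np.linspace(0.0, 1.0, steps):
            cy = y + t * length * np.sin(theta)
            cx = x + t * length * np.cos(theta)
            _paint_disk(
                planes, (cy, cx), thickness, 0.75, 0.08,
                float(np.clip(v0 + rng.normal(0, 0.02), 0.05, 1.0)),
                canvas=branch_mask,
            )

    foliage_mask = np.zeros((H, W), dtype=bool)
    n_patches = int(round(spec.foliage_density * H * W / 1e5))
    for _ in range(n_patches):
        py, px = rng.uniform(0, H), rng.uniform(0, W)
        patch_r = rng.uniform(25, 45)
        n_leaflets = rng.poisson(35)
        for _ in range(n_leaflets):
            ly = py + rng.normal(0, patch_r / 2)
            lx = px + rng.normal(0, patch_r / 2)
            lr = rng.uniform(2.0, 4.0)
            _paint_disk(
                planes, (ly, lx), lr,
                float((0.33 + rng.normal(0, 0.015)) % 1.0),
                float(np.clip(rng.normal(0.55, 0.05), 0.2, 1.0)),
                rng.uniform(0.15, 0.35),
                canvas=foliage_mask,
            )

    # clusters last, so their masks are the exact rendered supports
    cluster_masks: list[np.ndarray] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, extent)
    areas = []
    for _ in range(spec.n_clusters):
        n_g = int(rng.integers(spec.grapes_per_cluster[0], spec.grapes_per_cluster[1] + 1))
        offsets, radii = _pack_cluster(rng, n_g, spec.grape_radius_mean, spec.grape_radius_sd)
        extent = float(np.max(np.linalg.norm(offsets, axis=1) + radii))
        margin = extent + 2
        if 2 * margin >= min(H, W):
            raise RuntimeError("clusters do not fit in the frame; enlarge the image")
        for attempt in range(1000):
            py = rng.uniform(margin, H - margin)
            px = rng.uniform(margin, W - margin)
            if all(
                np.hypot(py - qy, px - qx) > extent + qe + 10
                for qy, qx, qe in placed
            ):
                break
        else:
            raise RuntimeError("could not place clusters without overlap")
        placed.append((py, px, extent))
        mask = _render_cluster(planes, rng, spec, (py, px), offsets, radii)
        cluster_masks.append(mask)
        areas.append(int(mask.sum()))

    rgb = _skcolor.hsv2rgb(np.stack(planes, axis=-1))
    if spec.sensor_noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.sensor_noise_sd, rgb.shape)
    rgb = np.clip(rgb, 0.0, 1.0)
    image = ColorImage(rgb, space=RGB)

    grape_any = np.zeros((H, W), dtype=bool)
    for m in cluster_masks:
        grape_any |= m
    material_masks = {
        "foliage": foliage_mask & ~grape_any,
        "branch": branch_mask & ~grape_any & ~foliage_mask,
        "base": ~(grape_any | foliage_mask | branch_mask),
    }

    weights = np.maximum(
        spec.weight_slope * np.asarray(areas, dtype=float)
        + spec.weight_intercept
        + rng.normal(0.0, spec.weight_noise_sd, size=len(areas)),
        1.0,
    )

    truth = SceneTruth(image, cluster_masks, weights, material_masks, spec)
    if spec.hue_separable and spec.n_clusters > 0:
        overlap = _hue_overlap(truth)
        if overlap >= 0.01:
            raise ValueError(
                f"hue separability violated: distribution overlap {overlap:.3f}"
            )
    return truth


def _hue_overlap(truth: SceneTruth, bins: int = 100) -> float:
    """Histogram intersection of grape vs background shifted-hue pixels."""
    hsv = _skcolor.rgb2hsv(truth.image.pixels)
    shifted = (hsv[..., 0] + 0.5) % 1.0
    grape_any = np.zeros(shifted.shape, dtype=bool)
    for m in truth.cluster_masks:
        grape_any |= m
    pg, _ = np.histogram(shifted[grape_any], bins=bins, range=(0, 1), density=False)
    pb, _ = np.histogram(shifted[~grape_any], bins=bins, range=(0, 1), density=False)
    pg = pg / max(pg.sum(), 1)
    pb = pb / max(pb.sum(), 1)
    return float(np.minimum(pg, pb).sum())


def generate_calibration_set(spec: SceneSpec, n: int = 29) -> list[CalibrationSample]:
    """Laboratory-style reference shots: one cluster on a white background.

    Each sample is a small frame whose background gray value is >= 0.9, with
    a sprinkle of isolated dark speckle pixels (sensor dust) that the
    reference-mask cleanup must remove.  The exposure is metered for the
    white background, so berry highlights stay clearly darker than the
    background and the silhouette is solid.  Weights follow the spec's
    weight law on the true rendered area.
    """
    if n < 3:
        raise ValueError("a calibration set needs at least 3 samples")
    rng = np.random.default_rng(spec.seed)
    samples: list[CalibrationSample] = []
    for i in range(n):
        n_g = int(rng.integers(spec.grapes_per_cluster[0], spec.grapes_per_cluster[1] + 1))
        offsets, radii = _pack_cluster(rng, n_g, spec.grape_radius_mean, spec.grape_radius_sd)
        extent = float(np.max(np.linalg.norm(offsets, axis=1) + radii))
        side = int(2 * extent + 50)
        hue = np.full((side, side), 0.55)
        sat = np.clip(rng.normal(0.02, 0.005, (side, side)), 0.0, 0.05)
        val = np.clip(rng.normal(0.97, 0.01, (side, side)), 0.92, 1.0)
        planes = (hue, sat, val)
        mask = _render_cluster(
            planes, rng, spec, (side / 2, side / 2), offsets, radii, exposure=0.65
        )
        # isolated dark speckle: removed by the 10-erosion cleanup
        n_speckle = 40
        sy = rng.integers(0, side, n_speckle)
        sx = rng.integers(0, side, n_speckle)
        keep = ~mask[sy, sx]
        val[sy[keep], sx[keep]] = rng.uniform(0.0, 0.2, int(keep.sum()))
        rgb = np.clip(
            _skcolor.hsv2rgb(np.stack(planes, axis=-1))
            + rng.normal(0.0, spec.sensor_noise_sd, (side, side, 3)),
            0.0,
            1.0,
        )
        area = float(mask.sum())
        weight = max(
            spec.weight_slope * area
            + spec.weight_intercept
            + rng.normal(0.0, spec.weight_noise_sd),
            1.0,
        )
        samples.append(
            CalibrationSample(
                image=ColorImage(rgb, space=RGB),
                mask=mask,
                weight=weight,
                cluster_id=f"cal-{i:03d}",
            )
        )
    return samples


def sample_calibration_pairs(
    n: int, spec: SceneSpec | None = None, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cheap (area, weight) pairs following the scene weight law, without
    rendering.

    Cluster areas are modeled as 62% of the summed berry disk areas (the
    retention factor of the overlapping packing); weights add the spec's
    Gaussian noise.  Used for fast repeated-simulation studies of the
    calibration fit.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    areas = np.empty(n)
    for i in range(n):
        n_g = int(rng.integers(spec.grapes_per_cluster[0], spec.grapes_per_cluster[1] + 1))
        radii = np.clip(
            rng.normal(spec.grape_radius_mean, spec.grape_radius_sd, n_g), 3.0, None
        )
        areas[i] = 0.62 * np.sum(np.pi * radii**2)
    weights = np.maximum(
        spec.weight_slope * areas
        + spec.weight_intercept
        + rng.normal(0.0, spec.weight_noise_sd, n),
        1.0,
    )
    return areas, weights


# ---------------------------------------------------------------------------
# automatic template placement (emulating the manual circular selections)
# ---------------------------------------------------------------------------

def _inscribed_circles(mask: np.ndarray, k: int, max_radius: float):
    """Up to k well-separated circles inscribed in a boolean mask."""
    circles = []
    work = mask.copy()
    # treat the frame edge as background so circles stay inside the image
    work[0, :] = work[-1, :] = work[:, 0] = work[:, -1] = False
    for _ in range(k):
        dist = ndimage.distance_transform_edt(work)
        r = float(dist.max())
        if r < 3.0:
            break
        cy, cx = np.unravel_index(int(np.argmax(dist)), dist.shape)
        radius = min(r - 1.0, max_radius)
        circles.append(((int(cy), int(cx)), radius))
        # carve out the used spot so the next circle lands elsewhere
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        work[(yy - cy) ** 2 + (xx - cx) ** 2 <= (3 * radius) ** 2] = False
    return circles


def default_templates(truth: SceneTruth) -> TemplateSet:
    """Template selections placed from the scene truth.

    Emulates the operator's circular selections: up to three grape circles
    (one per cluster), a large *mixed* background circle first (leaves,
    branches and dark base together — the single background template of the
    two-template protocol), then six material-specific background circles
    for the linear-color-model method.
    """
    # a grape selection is a patch of skin on a single berry, so its radius
    # stays below half a berry radius
    grape_tpl_radius = max(3.0, 0.45 * truth.spec.grape_radius_mean)
    grape: list[TemplateSelection] = []
    for mask in truth.cluster_masks[:3]:
        for center, radius in _inscribed_circles(mask, 1, max_radius=grape_tpl_radius):
            grape.append(TemplateSelection(center, radius, label="grape"))
    if not grape:
        raise ValueError("no cluster large enough for a grape template")

    background: list[TemplateSelection] = []
    # mixed background circle: centered on a foliage patch so it samples
    # foliage plus the surrounding dark base, kept clear of every cluster
    grape_any = np.zeros(truth.image.shape, dtype=bool)
    for m in truth.cluster_masks:
        grape_any |= m
    allowed = ~grape_any
    allowed[0, :] = allowed[-1, :] = allowed[:, 0] = allowed[:, -1] = False
    foliage_spots = _inscribed_circles(truth.material_masks["foliage"], 1, 12.0)
    if foliage_spots:
        (cy, cx), _ = foliage_spots[0]
    else:
        dist = ndimage.distance_transform_edt(allowed)
        cy, cx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    clearance = ndimage.distance_transform_edt(allowed)[cy, cx]
    mixed_radius = float(min(45.0, clearance - 1.0))
    if mixed_radius >= 3.0:
        background.append(
            TemplateSelection((int(cy), int(cx)), mixed_radius, label="background-mixed")
        )

    for material, k in (("foliage", 2), ("branch", 2), ("base", 2)):
        found = _inscribed_circles(truth.material_masks[material], k, max_radius=12.0)
        for center, radius in found:
            background.append(
                TemplateSelection(center, radius, label=f"background-{material}")
            )
    # the dark base always has room; top up there if a material was too thin
    target = 7  # 1 mixed + 6 material circles
    while len(background) < target:
        extra = _inscribed_circles(
            truth.material_masks["base"], target - len(background) + 2, max_radius=12.0
        )
        more = [
            TemplateSelection(c, r, label="background-base") for c, r in extra
        ]
        if not more:
            break
        background.extend(more[: target - len(background)])
    return TemplateSet(grape=grape, background=background)
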