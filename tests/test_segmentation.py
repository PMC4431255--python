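import numpy as np
import pytest
from scipy.stats import multivariate_normal

from nightgrape.colorspace import ColorImage, IntensityLayer
from nightgrape.segmentation import (
    ColorHistogram3D,
    DegenerateInputError,
    GaussianColorModel,
    LineColorModel,
    PixelSample,
    TemplateSelection,
    ThresholdRule,
    bayes_segment,
    build_dilated_histogram,
    fit_gaussian_model,
    fit_line_model,
    histogram_segment,
    lcm_segment,
    load_models,
    mahalanobis_segment,
    otsu_threshold,
    sample_template,
    save_models,
    threshold_segment,
)


def _rand_image(rng, shape=(16, 16)):
    return ColorImage(rng.uniform(0, 1, shape + (3,)))


class TestSampleTemplate:
    def test_uniform_image_gives_identical_rows(self):
        img = ColorImage(np.full((20, 20, 3), 0.3))
        sample = sample_template(img, TemplateSelection((10, 10), 3))
        assert len(sample) >= 1
        assert np.allclose(sample.colors, 0.3)

    @pytest.mark.parametrize("radius", [3, 5, 8, 12])
    def test_pixel_count_tracks_circle_area(self, radius):
        img = ColorImage(np.zeros((40, 40, 3)))
        sample = sample_template(img, TemplateSelection((20, 20), radius))
        assert abs(len(sample) - np.pi * radius**2) < 4 * radius

    def test_circle_outside_image_rejected(self):
        img = ColorImage(np.zeros((20, 20, 3)))
        with pytest.raises(ValueError):
            sample_template(img, TemplateSelection((2, 10), 5))

    def test_two_labeled_selections_give_disjoint_classes(self, rng):
        px = rng.uniform(0, 1, (40, 40, 3))
        img = ColorImage(px)
        a = sample_template(img, TemplateSelection((10, 10), 4, "grape"))
        b = sample_template(img, TemplateSelection((30, 30), 4, "background"))
        # disjoint circles sample disjoint pixel sets
        assert not any((a.colors[:, None] == b.colors[None]).all(-1).any(0))


def _otsu_oracle(values):
    """Exhaustive search over all 256 quantized split levels."""
    levels = np.clip(np.round(values.ravel() * 255.0), 0, 255).astype(int)
    best_k, best_var = 0, -np.inf
    n = levels.size
    for k in range(256):
        low = levels[levels <= k]
        high = levels[levels > k]
        if low.size == 0 or high.size == 0:
            continue
        w0, w1 = low.size / n, high.size / n
        var = w0 * w1 * (low.mean() - high.mean()) ** 2
        if var > best_var:
            best_var, best_k = var, k
    return best_k / 255.0


class TestOtsu:
    def test_bimodal_layer_split_between_modes(self):
        values = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        thr = otsu_threshold(IntensityLayer(values.reshape(10, 10), "I"))
        assert 0.2 <= thr < 0.8

    def test_matches_exhaustive_search_oracle(self, rng):
        for _ in range(20):
            values = rng.uniform(0, 1, (24, 24))
            if rng.uniform() < 0.5:  # occasionally strongly bimodal
                values = np.where(rng.uniform(size=values.shape) < 0.5,
                                  values * 0.3, 0.6 + values * 0.4)
            layer = IntensityLayer(values, "I")
            assert otsu_threshold(layer) == _otsu_oracle(values)

    def test_constant_layer_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(IntensityLayer(np.full((5, 5), 0.4), "I"))

    def test_separates_grapes_on_synthetic_scene_hue(self, scene):
        from nightgrape.colorspace import extract_layer, rgb_to_hsv_shifted
        from nightgrape.morphology import apply_sequence, parse_sequence

        layer = extract_layer(rgb_to_hsv_shifted(scene.image), "H")
        mask = layer.values > otsu_threshold(layer)
        # speckle cleanup, then compare against the union truth mask
        mask = apply_sequence(mask, parse_sequence("HF + 4E + 4D"))
        truth = np.zeros(mask.shape, bool)
        for m in scene.cluster_masks:
            truth |= m
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou > 0.8


class TestThresholdSegment:
    def test_uniform_layer_above_printed_threshold(self):
        layer = IntensityLayer(np.full((4, 4), 0.6), "H")
        mask = threshold_segment(layer, ThresholdRule("H", 0.54902))
        assert mask.all()

    def test_equality_is_background(self):
        layer = IntensityLayer(np.full((2, 2), 0.54902), "H")
        assert not threshold_segment(layer, ThresholdRule("H", 0.54902)).any()

    def test_true_count_equals_direct_count(self, rng):
        values = rng.uniform(0, 1, (20, 20))
        rule = ThresholdRule("I", 0.37)
        mask = threshold_segment(IntensityLayer(values, "I"), rule)
        assert mask.sum() == (values > 0.37).sum()

    def test_layer_mismatch_rejected(self):
        with pytest.raises(ValueError):
            threshold_segment(IntensityLayer(np.zeros((2, 2)), "I"),
                              ThresholdRule("H", 0.5))


class TestGaussianModels:
    def test_degenerate_sample_regularized(self):
        sample = PixelSample(np.full((10, 3), 0.4))
        model = fit_gaussian_model(sample, prior=0.5)
        assert np.allclose(model.mean, 0.4)
        assert np.allclose(model.covariance, 1e-6 * np.eye(3))

    def test_parameter_recovery_from_known_gaussian(self, rng):
        mean = np.array([0.5, 0.3, 0.2])
        cov = np.array([[0.002, 0.0005, 0.0], [0.0005, 0.001, 0.0002], [0.0, 0.0002, 0.003]])
        colors = np.clip(rng.multivariate_normal(mean, cov, 10_000), 0, 1)
        model = fit_gaussian_model(PixelSample(colors), prior=0.5)
        assert np.allclose(model.mean, mean, atol=0.01)
        assert np.allclose(model.covariance, cov, atol=0.005)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_model(PixelSample(np.zeros((3, 3))), prior=0.5)

    def test_published_priors_are_valid(self):
        model = fit_gaussian_model(
            PixelSample(np.random.default_rng(0).uniform(0, 1, (20, 3))),
            prior=0.4336,
        )
        assert model.prior == 0.4336


class TestMahalanobis:
    def _models(self):
        eye = 0.01 * np.eye(3)
        grape = GaussianColorModel([1, 0, 0], eye, prior=0.5)
        bg = GaussianColorModel([0, 1, 0], eye, prior=0.5)
        return grape, bg

    def test_reduces_to_nearest_mean_with_identity_covariances(self):
        grape, bg = self._models()
        img = ColorImage(np.full((1, 1, 3), [0.9, 0.1, 0.0]))
        assert mahalanobis_segment(img, grape, bg).all()

    def test_tie_goes_to_background(self):
        grape, _ = self._models()
        img = ColorImage(np.full((3, 3, 3), 0.5))
        assert not mahalanobis_segment(img, grape, grape).any()

    def test_matches_per_pixel_formula_oracle(self, rng):
        img = _rand_image(rng)
        grape = fit_gaussian_model(PixelSample(rng.uniform(0.4, 1, (40, 3))), 0.5)
        bg = fit_gaussian_model(PixelSample(rng.uniform(0, 0.6, (40, 3))), 0.5)
        mask = mahalanobis_segment(img, grape, bg)
        for model, other in ((grape, bg),):
            inv_g = np.linalg.inv(grape.covariance)
            inv_b = np.linalg.inv(bg.covariance)
            for i in range(img.shape[0]):
                for j in range(img.shape[1]):
                    x = img.pixels[i, j]
                    dg = (x - grape.mean) @ inv_g @ (x - grape.mean)
                    db = (x - bg.mean) @ inv_b @ (x - bg.mean)
                    assert mask[i, j] == (np.sqrt(dg) < np.sqrt(db))


class TestBayes:
    def test_equal_covariances_and_priors_reduce_to_mahalanobis(self, rng):
        cov = np.array([[0.02, 0.003, 0], [0.003, 0.015, 0], [0, 0, 0.01]])
        grape = GaussianColorModel([0.7, 0.2, 0.2], cov, prior=0.5)
        bg = GaussianColorModel([0.2, 0.4, 0.2], cov, prior=0.5)
        img = _rand_image(rng, (12, 12))
        assert np.array_equal(
            bayes_segment(img, grape, bg), mahalanobis_segment(img, grape, bg)
        )

    def test_identical_models_with_unequal_priors_favor_background(self, rng):
        cov = 0.01 * np.eye(3)
        grape = GaussianColorModel([0.5, 0.5, 0.5], cov, prior=0.4336)
        bg = GaussianColorModel([0.5, 0.5, 0.5], cov, prior=0.5664)
        assert not bayes_segment(_rand_image(rng), grape, bg).any()

    def test_matches_log_posterior_density_oracle(self, rng):
        img = _rand_image(rng)
        grape = fit_gaussian_model(PixelSample(rng.uniform(0.3, 1, (50, 3))), 0.4336)
        bg = fit_gaussian_model(PixelSample(rng.uniform(0, 0.7, (50, 3))), 0.5664)
        mask = bayes_segment(img, grape, bg)
        flat = img.pixels.reshape(-1, 3)
        lg = multivariate_normal.logpdf(flat, grape.mean, grape.covariance) + np.log(0.4336)
        lb = multivariate_normal.logpdf(flat, bg.mean, bg.covariance) + np.log(0.5664)
        assert np.array_equal(mask.ravel(), lg > lb)

    def test_priors_must_sum_to_one(self, rng):
        cov = 0.01 * np.eye(3)
        grape = GaussianColorModel([0.6, 0.2, 0.2], cov, prior=0.3)
        bg = GaussianColorModel([0.2, 0.4, 0.2], cov, prior=0.3)
        with pytest.raises(ValueError):
            bayes_segment(_rand_image(rng), grape, bg)


class TestLineModels:
    def test_collinear_sample_recovers_exact_direction(self):
        t = np.linspace(0.1, 0.5, 5)
        sample = PixelSample(np.outer(t, [1.0, 1.0, 1.0]))
        model = fit_line_model(sample)
        assert np.allclose(model.direction, np.ones(3) / np.sqrt(3))
        assert np.allclose(model.distance_sq(sample.colors), 0, atol=1e-12)

    def test_noisy_line_recovered_within_one_degree(self, rng):
        direction = np.array([0.8, 0.1, 0.2])
        direction /= np.linalg.norm(direction)
        t = rng.uniform(0, 1, 500)
        colors = 0.2 + np.outer(t, direction) * 0.6 + rng.normal(0, 0.002, (500, 3))
        model = fit_line_model(PixelSample(np.clip(colors, 0, 1)))
        angle = np.degrees(np.arccos(abs(model.direction @ direction)))
        assert angle < 1.0

    def test_zero_variance_sample_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_line_model(PixelSample(np.full((8, 3), 0.2)))

    def test_one_line_per_template_selection(self, rng):
        samples = [PixelSample(rng.uniform(0, 1, (20, 3))) for _ in range(9)]
        grape_lines = [fit_line_model(s, "grape") for s in samples[:3]]
        bg_lines = [fit_line_model(s, "background") for s in samples[3:]]
        assert len(grape_lines) == 3 and len(bg_lines) == 6


class TestLcmSegment:
    def _lines(self):
        red = LineColorModel([0, 0, 0], [1, 0.05, 0.05], "grape")
        green = LineColorModel([0, 0, 0], [0.05, 1, 0.05], "background")
        return [red], [green]

    def test_pixel_on_grape_line_is_grape(self):
        grape, bg = self._lines()
        img = ColorImage(np.full((1, 1, 3), 0.0))
        img.pixels[0, 0] = 0.5 * grape[0].direction
        assert lcm_segment(img, grape, bg).all()

    def test_distance_matches_1d_minimization_oracle(self, rng):
        line = fit_line_model(PixelSample(rng.uniform(0, 1, (30, 3))))
        points = rng.uniform(0, 1, (50, 3))
        for x in points:
            ts = np.linspace(-3, 3, 20001)
            brute = np.min(
                np.linalg.norm(x - (line.point + ts[:, None] * line.direction), axis=1)
            )
            assert np.isclose(np.sqrt(line.distance_sq(x[None])[0]), brute, atol=1e-4)

    def test_reddish_pixel_assigned_to_red_line(self):
        grape, bg = self._lines()
        img = ColorImage(np.full((1, 1, 3), [0.9, 0.1, 0.1]))
        assert lcm_segment(img, grape, bg).all()

    def test_empty_class_rejected(self, rng):
        grape, bg = self._lines()
        with pytest.raises(ValueError):
            lcm_segment(_rand_image(rng), grape, [])


def _ball_size(radius):
    r = int(radius)
    count = 0
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            for k in range(-r, r + 1):
                if i * i + j * j + k * k <= radius**2:
                    count += 1
    return count


class TestHistogram:
    def test_radius_zero_keeps_only_sampled_bins(self):
        sample = PixelSample(np.array([[0.1, 0.2, 0.3], [0.8, 0.8, 0.8]]))
        hist = build_dilated_histogram(sample, bins=16, radius=0)
        assert hist.occupancy.sum() == 2

    def test_single_sample_dilation_matches_lattice_ball(self):
        sample = PixelSample(np.array([[0.5, 0.5, 0.5]]))
        hist = build_dilated_histogram(sample, bins=16, radius=2)
        assert hist.occupancy.sum() == _ball_size(2)  # 33 lattice points

    def test_training_pixels_always_classified_grape(self, rng):
        colors = rng.uniform(0, 1, (60, 3))
        hist = build_dilated_histogram(PixelSample(colors), bins=32, radius=1)
        img = ColorImage(colors.reshape(6, 10, 3))
        assert histogram_segment(img, hist).all()

    def test_bins_beyond_radius_are_background(self):
        hist = build_dilated_histogram(
            PixelSample(np.array([[0.0, 0.0, 0.0]])), bins=16, radius=2
        )
        # bin (8,0,0) is 8 bins away from the sampled bin (0,0,0)
        img = ColorImage(np.full((1, 1, 3), [0.53, 0.0, 0.0]))
        assert not histogram_segment(img, hist).any()

    def test_boundary_of_solid_sphere_included(self):
        hist = build_dilated_histogram(
            PixelSample(np.array([[0.0, 0.0, 0.0]])), bins=16, radius=2
        )
        # bin (2,0,0): distance exactly r
        img = ColorImage(np.full((1, 1, 3), [2.4 / 16, 0.0, 0.0]))
        assert histogram_segment(img, hist).all()

    def test_dilation_radius_monotonicity(self, rng):
        colors = rng.uniform(0, 1, (30, 3))
        img = _rand_image(rng, (20, 20))
        prev = None
        for r in (0, 1, 2, 4):
            hist = build_dilated_histogram(PixelSample(colors), bins=16, radius=r)
            mask = histogram_segment(img, hist)
            if prev is not None:
                assert (mask | prev).sum() == mask.sum()  # never shrinks
            prev = mask

    def test_space_mismatch_rejected(self, rng):
        hist = build_dilated_histogram(
            PixelSample(rng.uniform(0, 1, (10, 3)), source_space="HSV-shifted"),
            bins=8,
            radius=0,
        )
        with pytest.raises(ValueError):
            histogram_segment(_rand_image(rng), hist)


def test_model_serialization_round_trip(tmp_path, rng):
    models = {
        "rule": ThresholdRule("H", 0.54902),
        "grape": fit_gaussian_model(PixelSample(rng.uniform(0, 1, (30, 3))), 0.4336),
        "line": fit_line_model(PixelSample(rng.uniform(0, 1, (30, 3)))),
        "hist": build_dilated_histogram(PixelSample(rng.uniform(0, 1, (30, 3))), 16, 2),
    }
    path = tmp_path / "models.json"
    save_models(path, models)
    back = load_models(path)
    assert back["rule"].threshold == models["rule"].threshold
    assert np.allclose(back["grape"].mean, models["grape"].mean)
    assert np.allclose(back["grape"].covariance, models["grape"].covariance)
    assert np.allclose(back["line"].direction, models["line"].direction)
    assert np.array_equal(back["hist"].occupancy, models["hist"].occupancy)


def test_segmenters_are_pure_functions(rng):
    img = _rand_image(rng)
    grape = fit_gaussian_model(PixelSample(rng.uniform(0.4, 1, (40, 3))), 0.5)
    bg = fit_gaussian_model(PixelSample(rng.uniform(0, 0.6, (40, 3))), 0.5)
    assert np.array_equal(
        mahalanobis_segment(img, grape, bg), mahalanobis_segment(img, grape, bg)
    )
    assert np.array_equal(
        bayes_segment(img, grape, bg), bayes_segment(img, grape, bg)
    )
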