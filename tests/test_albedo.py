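import numpy as np
import pytest

import bovitherm as bt
from bovitherm.albedo import (
    estimates_to_frame,
    read_image,
    read_mask_set,
    write_image,
    write_mask_set,
)
from conftest import seeds_from


def brute_force_summary(image, mask):
    """Independent per-pixel oracle for region summaries."""
    values = []
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                values.append(int(image[i, j]))
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1) if len(values) > 1 else 0.0
    hist = [0] * 256
    for v in values:
        hist[v] += 1
    return mean, var**0.5, min(values), max(values), hist


class TestToGray:
    @pytest.mark.parametrize(
        "pixel, expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((10, 20, 30), 20), ((1, 2, 2), 2)],
    )
    def test_unweighted_mean_rounded_half_up(self, pixel, expected):
        image = np.array([[pixel]], dtype=np.uint8)
        assert bt.to_gray(image)[0, 0] == expected

    def test_luminance_weights_option(self):
        image = np.array([[(100, 200, 50)]], dtype=np.uint8)
        gray = bt.to_gray(image, weights=(0.299, 0.587, 0.114))
        assert gray[0, 0] == round(0.299 * 100 + 0.587 * 200 + 0.114 * 50)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            bt.to_gray(np.zeros((4, 4), dtype=np.uint8))


class TestPixelSummary:
    def test_constant_region(self):
        image = np.full((5, 5), 100, dtype=np.uint8)
        s = bt.pixel_summary(image, np.ones((5, 5), bool))
        assert (s.mean, s.sd, s.n_pixels) == (100.0, 0.0, 25)
        assert s.histogram[100] == 25 and s.histogram.sum() == 25

    def test_hand_arithmetic(self):
        image = np.array([[0, 10], [20, 30]], dtype=np.uint8)
        s = bt.pixel_summary(image, np.ones((2, 2), bool))
        assert (s.mean, s.minimum, s.maximum) == (15.0, 0, 30)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            h, w = rng.integers(2, 12, size=2)
            image = rng.integers(0, 256, size=(h, w)).astype(np.uint8)
            mask = rng.random((h, w)) < 0.6
            if not mask.any():
                mask[0, 0] = True
            s = bt.pixel_summary(image, mask)
            mean, sd, lo, hi, hist = brute_force_summary(image, mask)
            assert s.mean == pytest.approx(mean)
            assert s.sd == pytest.approx(sd)
            assert (s.minimum, s.maximum) == (lo, hi)
            assert s.histogram.tolist() == hist

    def test_rejects_empty_mask(self):
        with pytest.raises(ValueError):
            bt.pixel_summary(np.zeros((3, 3), np.uint8), np.zeros((3, 3), bool))


class TestAlbedoRatios:
    def test_reference_against_itself(self):
        assert bt.relative_albedo(193, 193) == 1.0

    def test_single_image_brightness_means(self):
        # mean gray 100 (white hide) and 5 (black hide) against snow at 193
        assert bt.relative_albedo(100, 193) == pytest.approx(100 / 193)
        assert bt.relative_albedo(5, 193) == pytest.approx(0.025906, abs=1e-6)

    def test_over_unity_warns_but_returns(self):
        with pytest.warns(UserWarning):
            assert bt.relative_albedo(200, 100) == pytest.approx(2.0)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            bt.relative_albedo(10, 0)

    @pytest.mark.parametrize(
        "rel, expected", [(1.0, 0.85), (0.0, 0.0), (0.51813, 0.4404105)]
    )
    def test_absolute_albedo(self, rel, expected):
        assert bt.absolute_albedo(rel) == pytest.approx(expected)

    def test_absolute_albedo_rejects_negative(self):
        with pytest.raises(ValueError):
            bt.absolute_albedo(-0.1)


class TestEstimateImageAlbedos:
    def test_noise_free_round_trip_is_exact(self, quantized_scene):
        spec, image, masks, truth = quantized_scene
        estimates = {e.label: e for e in bt.estimate_image_albedos(image, masks)}
        for patch in spec.patches:
            assert estimates[patch.label].albedo_abs == pytest.approx(
                patch.albedo, abs=1e-12
            )
        assert estimates["snow"].albedo_abs == 0.85

    def test_noisy_estimates_unbiased(self, quantized_scene):
        spec = quantized_scene[0]
        values = {p.label: [] for p in spec.patches}
        for seed in seeds_from(100, 10):
            noisy = bt.SceneSpec(
                snow_gray=spec.snow_gray, patches=spec.patches, noise_sd=5.0, seed=seed
            )
            image, masks, _ = bt.generate_winter_image(noisy)
            for e in bt.estimate_image_albedos(image, masks):
                if e.label in values:
                    values[e.label].append(e.albedo_abs)
        for patch in spec.patches:
            assert np.mean(values[patch.label]) == pytest.approx(patch.albedo, abs=0.02)

    def test_darker_region_has_lower_albedo(self, quantized_scene):
        _, image, masks, _ = quantized_scene
        est = {e.label: e.albedo_abs for e in bt.estimate_image_albedos(image, masks)}
        assert est["black"] < est["red"] < est["white"] <= est["snow"]

    def test_requires_snow_region(self):
        labels = np.ones((4, 4), dtype=int)
        labels[:2] = 2
        masks = bt.RegionMaskSet(labels=labels, names={1: "white", 2: "red"})
        with pytest.raises(ValueError, match="snow"):
            bt.estimate_image_albedos(np.full((4, 4), 100, np.uint8), masks)


class TestSummarizeReplicates:
    def test_identical_estimates_have_zero_se(self):
        df = estimates_to_frame(
            [bt.AlbedoEstimate("white", 0.8, 0.68, image_id=str(i)) for i in range(3)]
        )
        row = bt.summarize_replicates(df).iloc[0]
        assert (row["mean"], row["se"]) == (0.68, 0.0)

    def test_hand_arithmetic(self):
        df = estimates_to_frame(
            [
                bt.AlbedoEstimate("white", r / 0.85, r, image_id=str(i))
                for i, r in enumerate((0.6, 0.7, 0.8))
            ]
        )
        row = bt.summarize_replicates(df).iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["se"] == pytest.approx(0.05774, abs=1e-5)

    def test_single_replicate_flags_undefined_se(self):
        df = estimates_to_frame([bt.AlbedoEstimate("red", 0.2, 0.17)])
        row = bt.summarize_replicates(df).iloc[0]
        assert row["mean"] == 0.17 and np.isnan(row["se"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bt.summarize_replicates(estimates_to_frame([]))


class TestEstimatorAndIO:
    def test_estimator_over_replicates(self, quantized_scene):
        spec, image, masks, _ = quantized_scene
        est = bt.SnowReferencedAlbedo().fit([image, image], [masks, masks])
        summary = est.replicate_summary_.set_index("label")
        assert summary.loc["red", "mean"] == pytest.approx(0.425)
        assert summary.loc["red", "se"] == 0.0
        assert ("image0", "snow") in est.summaries_

    def test_png_round_trip(self, quantized_scene, tmp_path):
        _, image, masks, _ = quantized_scene
        write_image(tmp_path / "scene.png", image)
        write_mask_set(tmp_path / "labels.png", tmp_path / "labels.yaml", masks)
        image2 = read_image(tmp_path / "scene.png")
        masks2 = read_mask_set(tmp_path / "labels.png", tmp_path / "labels.yaml")
        assert np.array_equal(image, image2)
        assert np.array_equal(masks.labels, masks2.labels)
        assert masks2.names == dict(masks.names)
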