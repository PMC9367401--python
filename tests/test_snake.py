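"""Contour deformer: circular convolution, snake blocks, losses, training."""

import numpy as np
import pytest

from snakeshot import data as D, geometry as G, snake as S
from snakeshot.config import SnakeConfig, TrainConfig
from snakeshot.geometry import BoundingBox
from snakeshot.nn import Tensor


@pytest.fixture(scope="module")
def cfg():
    return SnakeConfig()


@pytest.fixture(scope="module")
def small_cfg():
    return SnakeConfig(n_diamond=12, n_contour=32, iterations=2, kernel_size=3,
                       feature_channels=8, state_channels=16)


def naive_circular_conv(features, kernel):
    """Loop-based cyclic-sum oracle: out[i] = sum_j K[j] f[(i+j-c) % n]."""
    n, d = features.shape
    k, _, dp = kernel.shape
    c = (k - 1) // 2
    out = np.zeros((n, dp))
    for i in range(n):
        for j in range(k):
            out[i] += features[(i + j - c) % n] @ kernel[j]
    return out


class TestCircularConv:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((10, 4))
        kernel = np.zeros((3, 4, 4))
        kernel[1] = np.eye(4)
        out = S.circular_conv(f, kernel)
        np.testing.assert_allclose(out.data, f)

    def test_constant_rows_scaled_by_tap_sum(self):
        f = np.tile([1.5, -2.0], (7, 1))
        kernel = np.zeros((5, 2, 2))
        for j, s in enumerate([0.1, 0.2, 0.3, 0.2, 0.2]):
            kernel[j] = s * np.eye(2)
        out = S.circular_conv(f, kernel)
        np.testing.assert_allclose(out.data, f * 1.0, atol=1e-12)

    def test_hand_computed_scalar_example(self):
        f = np.array([[1.0], [0.0], [0.0], [0.0]])
        kernel = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        out = S.circular_conv(f, kernel)
        np.testing.assert_allclose(out.data.ravel(), [2.0, 1.0, 0.0, 3.0])

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            k = int(rng.choice([3, 5, 7, 9]))
            if n < k:
                continue
            d, dp = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            f = rng.standard_normal((n, d))
            kernel = rng.standard_normal((k, d, dp))
            out = S.circular_conv(f, kernel)
            np.testing.assert_allclose(out.data, naive_circular_conv(f, kernel), atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            S.circular_conv(np.ones((6, 2)), np.ones((4, 2, 2)))


class TestSnakeBlock:
    def test_zero_head_gives_zero_offsets(self, small_cfg):
        params = S.init_snake_params(small_cfg, seed=0)
        rng = np.random.default_rng(2)
        vf = Tensor(rng.standard_normal((small_cfg.n_contour, small_cfg.feature_channels + 2)))
        out = S.snake_block(params, "df0", vf)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_cyclic_shift_equivariance(self, small_cfg):
        params = S.init_snake_params(small_cfg, seed=3)
        # give the output head nonzero weights so the test is not vacuous
        rng = np.random.default_rng(4)
        params["df0.out.w"].data = rng.standard_normal(params["df0.out.w"].data.shape)
        vf = rng.standard_normal((20, small_cfg.feature_channels + 2))
        out = S.snake_block(params, "df0", Tensor(vf)).data
        for shift in (1, 5, 13):
            shifted = S.snake_block(params, "df0", Tensor(np.roll(vf, shift, axis=0))).data
            np.testing.assert_allclose(shifted, np.roll(out, shift, axis=0), atol=1e-9)


class TestVertexFeatures:
    def test_relative_coordinates_sum_to_zero(self, cfg):
        params = S.init_snake_params(cfg, seed=0)
        img = np.random.default_rng(5).random((64, 64, 3))
        grid = S.extract_features(params, img, cfg)
        contour = G.resample_contour(G.box_to_diamond(BoundingBox(10, 10, 50, 40)), 16)
        vf = S.vertex_features(grid, contour)
        rel = vf.data[:, -2:]
        np.testing.assert_allclose(rel.sum(axis=0), 0.0, atol=1e-6)
        assert vf.data.shape == (16, cfg.feature_channels + 2)


class TestZeroNetworkPipeline:
    def test_identity_on_octagon(self, cfg):
        """Untrained model: extremes = midpoints, deformation = identity."""
        params = S.init_snake_params(cfg, seed=0)
        img = np.random.default_rng(6).random((128, 128, 3))
        grid = S.extract_features(params, img, cfg)
        box = BoundingBox(20, 30, 80, 90)
        ex = S.predict_extreme_points(box, grid, params, cfg)
        d = G.box_to_diamond(box)
        np.testing.assert_allclose(ex.as_array(), d, atol=1e-9)
        octagon = G.build_octagon(ex, box)
        out = S.deform_iteratively(octagon, grid, params, cfg)
        assert out.shape == (cfg.n_contour, 2)
        np.testing.assert_allclose(out, G.resample_contour(octagon, cfg.n_contour), atol=1e-9)

    def test_diamond_resampled_to_40_vertices(self, cfg):
        assert cfg.n_diamond == 40
        d40 = G.resample_contour(G.box_to_diamond(BoundingBox(0, 0, 30, 20)), cfg.n_diamond)
        assert d40.shape == (40, 2)
        # original midpoints survive at the quarter indices
        np.testing.assert_allclose(d40[[0, 10, 20, 30]],
                                   G.box_to_diamond(BoundingBox(0, 0, 30, 20)), atol=1e-9)

    def test_box_outside_grid_rejected(self, cfg):
        params = S.init_snake_params(cfg, seed=0)
        grid = S.extract_features(params, np.zeros((64, 64, 3)), cfg)
        with pytest.raises(G.InvalidGeometryError):
            S.predict_extreme_points(BoundingBox(10, 10, 300, 40), grid, params, cfg)


class TestTrainingLoss:
    def test_zero_for_exact_match(self, cfg):
        poly = D.make_shape(D.default_shape_classes(4)[0], 25, seed=1) + 50
        gt = G.resample_contour(G.ensure_clockwise(poly), cfg.n_contour)
        ext = G.extreme_points_of(G.ensure_clockwise(poly)).as_array()
        loss = S.snake_training_loss(Tensor(ext), [Tensor(gt)], poly, cfg)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_vertex_value(self, cfg):
        """One vertex off by (1, 0) in the final round:
        loss = 2 * smooth-L1(1) / (2 n) (the output round is double-weighted)."""
        poly = D.make_shape(D.default_shape_classes(4)[1], 25, seed=2) + 50
        gtc = G.ensure_clockwise(poly)
        gt = G.resample_contour(gtc, cfg.n_contour)
        ext = G.extreme_points_of(gtc).as_array()
        pred = gt.copy()
        pred[7, 0] += 1.0
        loss = S.snake_training_loss(Tensor(ext), [Tensor(pred)], poly, cfg)
        # smooth-L1 at |d| = 1 with beta 1 is 0.5; mean over n*2 coordinates,
        # doubled because the displaced contour is the final round
        assert float(loss.data) == pytest.approx(2 * 0.5 / (cfg.n_contour * 2), rel=1e-6)

    def test_nonnegative_on_random_inputs(self, cfg, rng):
        poly = D.make_shape(D.default_shape_classes(4)[2], 20, seed=3) + 40
        pred = Tensor(rng.uniform(0, 80, (cfg.n_contour, 2)))
        ext = Tensor(rng.uniform(0, 80, (4, 2)))
        assert float(S.snake_training_loss(ext, [pred], poly, cfg).data) >= 0.0

    def test_wrong_vertex_count_rejected(self, cfg):
        poly = D.make_shape(D.default_shape_classes(4)[0], 25, seed=1) + 50
        with pytest.raises(ValueError):
            S.snake_training_loss(Tensor(np.zeros((4, 2))),
                                  [Tensor(np.zeros((64, 2)))], poly, cfg)


@pytest.fixture(scope="module")
def trained():
    ds = D.generate_dataset(n_classes=3, images_per_class=6, seed=21,
                            image_size=64, regime_prob=0.0)
    cfg = SnakeConfig()
    tc = TrainConfig(epochs_snake=3)
    params, hist = S.train_snake(ds, cfg, tc, seed=0)
    return ds, cfg, tc, params, hist


class TestTrainSnake:
    def test_loss_decreases(self, trained):
        _, _, _, _, hist = trained
        assert hist[-1][1] < hist[0][1]

    def test_same_seed_same_curve(self, trained):
        ds, cfg, tc, _, hist = trained
        _, hist2 = S.train_snake(ds, cfg, tc, seed=0)
        np.testing.assert_allclose([l for _, l in hist], [l for _, l in hist2], atol=1e-4)

    def test_deformed_contour_has_128_vertices(self, trained):
        ds, cfg, _, params, _ = trained
        iid = ds.image_ids("val")[0]
        im = ds.image_by_id(iid)
        ann = ds.annotations_for(iid)[0]
        grid = S.extract_features(params, im["pixels"], cfg)
        x, y, w, h = ann["bbox"]
        out = S.segment_instance(BoundingBox(x, y, x + w, y + h), grid, params, cfg)
        assert out.shape == (128, 2)

    def test_empty_dataset_rejected(self, cfg):
        ds = D.generate_dataset(n_classes=2, images_per_class=2, seed=0, image_size=64)
        ds.annotations = []
        if hasattr(ds, "_ann_index"):
            del ds._ann_index
        with pytest.raises(ValueError):
            S.train_snake(ds, cfg, TrainConfig(epochs_snake=1), seed=0)

    def test_params_round_trip(self, trained, tmp_path):
        _, _, _, params, _ = trained
        S.save_params(params, tmp_path / "snake.pkl")
        back = S.load_params(tmp_path / "snake.pkl")
        assert set(back) == set(params)
        np.testing.assert_array_equal(back["df0.cc1.w"].data, params["df0.cc1.w"].data)
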