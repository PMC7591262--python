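"""Tile-based segmentation: encoding, tiling, normalization, stitching."""

import numpy as np
import pytest
from scipy import ndimage

from aggrescope import segtile, syndata
from aggrescope.io_core import Roi, RoiSet
from aggrescope.nnet import ModelConfig, TrainSchedule, UNet
from aggrescope.segtile import NormalizationParams, SegSample


def _square_roi(x0, y0, side, label="sq"):
    pts = np.array(
        [[x0, y0], [x0 + side - 1, y0], [x0 + side - 1, y0 + side - 1],
         [x0, y0 + side - 1]],
        dtype=float,
    )
    return Roi("polygon", pts, label=label)


def _blank(shape):
    return SegSample(np.zeros(shape), np.zeros(shape, bool), np.zeros(shape, bool))


class TestEncodeRois:
    def test_square_mask_area_and_outline_length(self):
        rs = RoiSet("x", [_square_roi(0, 0, 10)])
        s = segtile.encode_rois(np.zeros((20, 20)), rs)
        assert s.mask.sum() == 100
        assert s.outline.sum() == 36

    def test_empty_roiset_gives_all_false(self):
        s = segtile.encode_rois(np.zeros((16, 16)), RoiSet("x", []))
        assert not s.mask.any() and not s.outline.any()

    def test_overlapping_rois_union_no_double_count(self):
        rs = RoiSet("x", [_square_roi(0, 0, 10), _square_roi(5, 5, 10)])
        s = segtile.encode_rois(np.zeros((24, 24)), rs)
        assert s.mask.sum() == 100 + 100 - 25

    def test_outline_within_dilated_mask(self, blob_training_set):
        frames, rois, _ = blob_training_set
        s = segtile.encode_rois(frames[0], rois[0])
        dilated = ndimage.binary_dilation(s.mask, np.ones((3, 3)))
        assert (s.outline <= dilated).all()


class TestMakeTiles:
    def test_exact_fit_single_tile(self):
        grid, tiles = segtile.make_tiles(_blank((512, 512)))
        assert len(tiles) == 1 and grid.pad == (0, 0)

    def test_1024_with_50pct_overlap_gives_3x3(self):
        grid, tiles = segtile.make_tiles(_blank((1024, 1024)), 512, 256)
        assert len(tiles) == 9
        assert grid.offsets[1] == (0, 256)

    def test_600_padded_to_768_gives_2x2(self):
        grid, tiles = segtile.make_tiles(_blank((600, 600)), 512, 256)
        assert len(tiles) == 4
        assert grid.pad == (168, 168)

    def test_coverage_and_overlap_counts(self):
        """Every padded pixel is covered; interior pixels sit in 4 tiles."""
        grid, tiles = segtile.make_tiles(_blank((128, 128)), 64, 32)
        cover = np.zeros((128, 128), int)
        for oy, ox in grid.offsets:
            cover[oy : oy + 64, ox : ox + 64] += 1
        assert cover.min() >= 1
        assert cover[64, 64] == 4

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            segtile.make_tiles(_blank((64, 64)), window=16)


class TestAugment:
    def _tiles(self):
        img = np.zeros((64, 64))
        img[20:40, 20:40] = 1.0
        mask = img > 0
        return [SegSample(img, mask, np.zeros_like(mask))]

    def test_zero_output_is_empty(self):
        assert segtile.augment(self._tiles(), 0, seed=0) == []

    def test_seeded_and_shape_preserving(self):
        a = segtile.augment(self._tiles(), 3, seed=5)
        b = segtile.augment(self._tiles(), 3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)
            assert x.image.shape == (64, 64)

    def test_mask_area_roughly_preserved(self):
        out = segtile.augment(self._tiles(), 10, seed=1, max_shift=5)
        base = self._tiles()[0].mask.sum()
        for t in out:
            assert t.mask.sum() == pytest.approx(base, rel=0.02)


class TestNormalization:
    def test_nonzero_statistics_and_mapping(self):
        img = np.array([[0.0, 1.0], [2.0, 3.0]])
        params = segtile.estimate_normalization(img)
        assert params.mean == pytest.approx(2.0)
        assert params.stdev == pytest.approx(np.sqrt(2 / 3))  # population sd
        out = segtile.normalize(img, params)
        assert out[0, 1] == pytest.approx((1 - 2) / params.stdev + 0.5)
        assert segtile.normalize(np.array([2.0]), params)[0] == pytest.approx(0.5)

    def test_normalized_nonzero_mean_is_exactly_half(self, rng):
        img = rng.uniform(0, 500, (64, 64))
        img[rng.random((64, 64)) < 0.3] = 0.0
        params = segtile.estimate_normalization(img)
        out = segtile.normalize(img, params)
        assert out[img != 0].mean() == pytest.approx(0.5, abs=1e-12)

    def test_round_trip_identity(self, rng):
        img = rng.uniform(1, 100, (32, 32))
        params = segtile.estimate_normalization(img)
        back = segtile.denormalize(segtile.normalize(img, params), params)
        np.testing.assert_allclose(back, img, atol=1e-12)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            segtile.estimate_normalization(np.zeros((8, 8)))


class TestTrainingContract:
    def test_validation_runs_exactly_every_hundredth_iteration(self):
        """A 2200-iteration budget logs 22 validation entries."""
        rng = np.random.default_rng(0)
        img = rng.uniform(1, 10, (16, 16))
        tile = SegSample(img, img > 5, np.zeros_like(img, dtype=bool))
        schedule = TrainSchedule(
            max_iterations=2200, validate_every=100, batch_size=1
        )
        model = segtile.train(
            [tile], [tile], schedule, ModelConfig(depth=1, base_channels=2), seed=0
        )
        assert len(model.log) == 22
        assert model.log["iteration"].tolist() == list(range(100, 2201, 100))

    def test_fixed_seed_gives_identical_loss_curve(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(1, 10, (16, 16))
        tile = SegSample(img, img > 5, np.zeros_like(img, dtype=bool))
        schedule = TrainSchedule(max_iterations=60, validate_every=20, batch_size=1)
        cfg = ModelConfig(depth=1, base_channels=2)
        a = segtile.train([tile], [tile], schedule, cfg, seed=3)
        b = segtile.train([tile], [tile], schedule, cfg, seed=3)
        assert a.log["train_loss"].tolist() == b.log["train_loss"].tolist()

    def test_loss_decreases_on_learnable_tiles(self, blob_training_set):
        frames, rois, _ = blob_training_set
        samples = [segtile.encode_rois(f, r) for f, r in zip(frames[:4], rois[:4])]
        tiles = [t for s in samples for t in segtile.make_tiles(s, 64, 32)[1]]
        schedule = TrainSchedule(max_iterations=200, validate_every=50, batch_size=4)
        model = segtile.train(
            tiles[:-2], tiles[-2:], schedule, ModelConfig(3, 8), seed=0
        )
        assert model.log["val_loss"].iloc[-1] < model.log["val_loss"].iloc[0]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            segtile.train([], [], TrainSchedule(), ModelConfig())


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        net = UNet(ModelConfig(depth=2, base_channels=2), seed=4)
        model = segtile.TrainedModel(
            net=net, params=NormalizationParams(5.0, 2.0),
            model_cfg=net.cfg, log=None,
        )
        model.save(tmp_path / "m")
        back = segtile.TrainedModel.load(tmp_path / "m")
        x = rng.normal(size=(1, 1, 16, 16))
        np.testing.assert_allclose(back.net.forward(x), net.forward(x), atol=1e-12)
        assert back.params.mean == 5.0


class _ConstantNet:
    """Stand-in model producing a constant probability everywhere."""

    def __init__(self, value):
        self.value = value

    def forward(self, x):
        n, _, h, w = x.shape
        return np.full((n, 2, h, w), self.value)


class TestInferAndStitch:
    def _model(self, value=0.7):
        return segtile.TrainedModel(
            net=_ConstantNet(value), params=NormalizationParams(1.0, 1.0),
            model_cfg=ModelConfig(), log=None,
        )

    def test_constant_model_gives_uniform_map(self):
        mask, outline = segtile.infer_and_stitch(
            np.ones((100, 100)), self._model(0.7), window=64, stride=32
        )
        np.testing.assert_allclose(mask, 0.7)
        assert mask.shape == (100, 100)

    def test_border_blanking(self):
        mask, _ = segtile.infer_and_stitch(
            np.ones((80, 80)), self._model(0.7), window=64, stride=32, border=5
        )
        assert mask[:5].max() == 0.0 and mask[5:-5, 5:-5].min() == 0.7

    def test_overlap_pixel_taken_from_nearest_tile_center(self):
        """De-windowing picks the tile in which the pixel is most interior."""

        class TileMarker:
            def __init__(self):
                self.count = 0

            def forward(self, x):
                n, _, h, w = x.shape
                out = np.full((n, 2, h, w), float(self.count))
                self.count += 1
                return out

        model = segtile.TrainedModel(
            net=TileMarker(), params=NormalizationParams(1.0, 1.0),
            model_cfg=ModelConfig(), log=None,
        )
        mask, _ = segtile.infer_and_stitch(
            np.ones((128, 128)), model, window=64, stride=64
        )
        # disjoint tiles in raster order: each quadrant keeps its own marker
        assert mask[10, 10] == 0.0 and mask[10, 100] == 1.0
        assert mask[100, 10] == 2.0 and mask[100, 100] == 3.0


class TestPostprocess:
    def test_uniform_mask_is_single_frame_object(self):
        labels, n = segtile.postprocess(np.full((32, 32), 0.6))
        assert n == 1 and (labels == 1).all()

    def test_outline_subtraction_separates_touching_squares(self):
        mask_prob = np.zeros((20, 30))
        mask_prob[5:15, 5:25] = 0.9  # two 10x10 squares sharing the x=15 edge
        outline_prob = np.zeros((20, 30))
        outline_prob[5:15, 14:16] = 1.0  # shared boundary
        _, n_plain = segtile.postprocess(mask_prob, outline_prob,
                                         subtract_outline=False)
        _, n_split = segtile.postprocess(mask_prob, outline_prob,
                                         subtract_outline=True)
        assert n_plain == 1
        assert n_split == 2

    def test_missing_outline_rejected_when_subtracting(self):
        with pytest.raises(ValueError):
            segtile.postprocess(np.zeros((4, 4)), None, subtract_outline=True)


class TestEndToEnd:
    def test_scaled_down_benchmark_f1_and_iou(self, blob_training_set):
        """Train small, infer on held-out frames, demand F1 >= 0.9, IoU >= 0.7."""
        frames, rois, _ = blob_training_set
        samples = [segtile.encode_rois(f, r) for f, r in zip(frames, rois)]
        tiles = [t for s in samples[:8] for t in segtile.make_tiles(s, 64, 32)[1]]
        vtiles = [t for s in samples[8:] for t in segtile.make_tiles(s, 64, 32)[1]]
        schedule = TrainSchedule(max_iterations=600, validate_every=200,
                                 batch_size=4)
        model = segtile.train(tiles, vtiles, schedule, ModelConfig(3, 8), seed=0)
        test_frames, test_rois, _ = syndata.simulate_blob_fields(20, seed=99)
        f1s, ious = [], []
        for f, r in zip(test_frames, test_rois):
            mask_prob, outline_prob = segtile.infer_and_stitch(
                f, model, window=64, stride=32
            )
            labels, _ = segtile.postprocess(mask_prob, outline_prob)
            truth = segtile.encode_rois(f, r)
            tl, _ = ndimage.label(truth.mask, np.ones((3, 3)))
            sc = segtile.segmentation_scores(labels, tl)
            f1s.append(sc["f1"])
            ious.append(sc["pixel_iou"])
        assert np.mean(f1s) >= 0.9
        assert np.mean(ious) >= 0.7

    def test_mitochondrial_volume_closure(self):
        """Label stacks fed to 3-D volumetry recover planted voxel volumes."""
        from aggrescope import morpho

        stack, cells, gt = syndata.simulate_em_sections(
            4, {"mitochondrion": 2.0}, seed=12
        )
        out = morpho.volumes_3d(stack, class_map={3: "mitochondrion"})
        planted = sum(
            r["voxels"] for r in gt.records if r["class"] == "mitochondrion"
        )
        assert out.voxels.sum() == pytest.approx(planted, rel=0.10)
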