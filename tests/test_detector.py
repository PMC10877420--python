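"""Tiny detector: shapes, target assignment, loss decomposition, NMS,
training determinism and the loss-variant harness."""

import numpy as np
import pytest

from micropest import nn
from micropest.boxes import Box, ImageDims, mpdiou_loss
from micropest.datapipe import AnnotatedImage
from micropest.detector import (DetectorConfig, TinyDetector, assign_targets,
                                compare_box_loss_variants, load_checkpoint, nms,
                                predict, save_checkpoint, train, training_loss)
from micropest.metrics import Detection, GroundTruthBox
from micropest.synth import easy_config, generate_scenes


@pytest.fixture(scope="module")
def model():
    return TinyDetector(DetectorConfig(), seed=0)


@pytest.fixture(scope="module")
def tiny_scenes():
    return generate_scenes(easy_config(seed=42), 12)


class TestArchitecture:
    def test_grid_shape(self, model, rng):
        x = nn.Tensor(rng.normal(size=(2, 3, 64, 64)) * 0.1)
        raw = model(x)
        assert raw.shape == (2, 2, 9, 8, 8)  # 2 anchors, 5+4 channels, 8x8 grid

    def test_forward_is_finite(self, model, rng):
        raw = model(nn.Tensor(rng.normal(size=(1, 3, 64, 64)) * 0.1))
        assert np.all(np.isfinite(raw.data))

    def test_loss_variant_does_not_change_shapes(self, rng):
        a = TinyDetector(DetectorConfig(box_loss="mpdiou"), seed=1)
        b = TinyDetector(DetectorConfig(box_loss="ciou"), seed=1)
        x = nn.Tensor(rng.normal(size=(1, 3, 64, 64)) * 0.1)
        assert a(x).shape == b(x).shape

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=60)
        with pytest.raises(ValueError):
            DetectorConfig(anchors=())
        with pytest.raises(ValueError):
            DetectorConfig(box_loss="giou")


class TestAssignment:
    CFG = DetectorConfig()

    def test_center_cell_and_best_anchor(self):
        # center (20,12) -> cell (2,1); 13x9 box is closest to the 14x14 anchor
        gts = [[GroundTruthBox(Box(13.5, 7.5, 26.5, 16.5), "B")]]
        idx, boxes, cls = assign_targets(gts, self.CFG)
        g = self.CFG.grid
        n, rem = divmod(idx[0], len(self.CFG.anchors) * g * g)
        a, rem = divmod(rem, g * g)
        gy, gx = divmod(rem, g)
        assert (n, a, gy, gx) == (0, 0, 1, 2)
        assert cls[0] == 1

    def test_one_anchor_per_target_first_wins(self):
        gt = GroundTruthBox(Box(10, 10, 24, 24), "A")
        idx, boxes, _ = assign_targets([[gt, gt]], self.CFG)
        assert len(idx) == 1


class TestTrainingLoss:
    def test_decomposition_identity(self, model, tiny_scenes):
        from micropest.detector import _to_input
        x = nn.Tensor(np.stack([_to_input(s) for s in tiny_scenes[:4]]))
        total, box, obj, cls = training_loss(model(x), [s.boxes for s in tiny_scenes[:4]],
                                             model.cfg)
        cfg = model.cfg
        assert total.item() == pytest.approx(
            cfg.lambda_box * box.item() + cfg.lambda_obj * obj.item()
            + cfg.lambda_cls * cls.item(), abs=1e-9)
        assert min(box.item(), obj.item(), cls.item()) >= 0

    def test_box_term_matches_boxgeom_on_worked_pair(self):
        """The mpdiou variant reproduces the scalar loss for a decoded pair."""
        cfg = DetectorConfig()
        img = ImageDims(cfg.input_size, cfg.input_size)
        from micropest.boxes import mpdiou_loss_t
        pred = nn.Tensor(np.array([[0.0, 0.0, 2.0, 2.0]]))
        gt = nn.Tensor(np.array([[1.0, 1.0, 3.0, 3.0]]))
        val = mpdiou_loss_t(pred, gt, img).data[0]
        assert val == pytest.approx(
            mpdiou_loss(Box(0, 0, 2, 2), Box(1, 1, 3, 3), img), abs=1e-9)

    def test_doubling_lambda_box_doubles_box_component(self, model, tiny_scenes):
        from dataclasses import replace
        from micropest.detector import _to_input
        x = nn.Tensor(np.stack([_to_input(s) for s in tiny_scenes[:2]]))
        raw = model(x)
        gts = [s.boxes for s in tiny_scenes[:2]]
        t1, b1, o1, c1 = training_loss(raw, gts, model.cfg)
        cfg2 = replace(model.cfg, lambda_box=2 * model.cfg.lambda_box)
        t2, b2, o2, c2 = training_loss(raw, gts, cfg2)
        assert b2.item() == pytest.approx(b1.item())
        assert (t2.item() - t1.item()) == pytest.approx(
            model.cfg.lambda_box * b1.item(), abs=1e-9)

    def test_empty_batch_trains_background_only(self, model):
        from micropest.detector import _to_input
        blank = AnnotatedImage(np.full((64, 64, 3), 90, np.uint8), [])
        x = nn.Tensor(np.stack([_to_input(blank)]))
        total, box, obj, cls = training_loss(model(x), [[]], model.cfg)
        assert box.item() == 0.0 and cls.item() == 0.0
        assert obj.item() > 0


class TestTraining:
    def test_identical_seeds_identical_history(self, tiny_scenes):
        h = []
        for _ in range(2):
            m = TinyDetector(DetectorConfig(), seed=7)
            h.append(train(m, tiny_scenes, epochs=2, batch_size=4, lr=1e-3, seed=7))
        assert h[0].total == h[1].total
        assert h[0].box == h[1].box

    def test_loss_decreases_on_smoke_run(self, tiny_scenes):
        m = TinyDetector(DetectorConfig(), seed=3)
        hist = train(m, tiny_scenes, epochs=5, batch_size=4, lr=5e-3, seed=3)
        assert hist.total[-1] < hist.total[0]

    def test_box_ablation_contract(self, tiny_scenes):
        m = TinyDetector(DetectorConfig(), seed=5)
        hist = train(m, tiny_scenes, epochs=2, batch_size=4, lr=1e-3, seed=5,
                     backprop_box=False)
        assert len(hist.box) == 2          # recorded ...
        assert all(v > 0 for v in hist.box)  # ... but merely observed

    def test_wrong_scene_size_rejected(self):
        m = TinyDetector(DetectorConfig(), seed=0)
        bad = AnnotatedImage(np.zeros((32, 32, 3), np.uint8), [])
        with pytest.raises(ValueError):
            train(m, [bad], epochs=1)


class TestPrediction:
    def test_conf_threshold_one_gives_nothing(self, model, tiny_scenes):
        assert predict(model, tiny_scenes[0], conf_threshold=1.0) == []

    def test_nms_suppresses_same_class_overlap(self):
        d1 = Detection(Box(0, 0, 10, 10), "A", 0.9)
        d2 = Detection(Box(1, 1, 11, 11), "A", 0.8)  # IoU ~0.68
        assert nms([d1, d2], 0.5) == [d1]

    def test_nms_keeps_different_classes(self):
        d1 = Detection(Box(0, 0, 10, 10), "A", 0.9)
        d2 = Detection(Box(1, 1, 11, 11), "B", 0.8)
        assert set(d.class_id for d in nms([d1, d2], 0.5)) == {"A", "B"}

    def test_checkpoint_round_trip(self, model, tiny_scenes, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        a = predict(model, tiny_scenes[0], conf_threshold=0.0)
        b = predict(clone, tiny_scenes[0], conf_threshold=0.0)
        assert len(a) == len(b)
        for da, db in zip(a, b):
            assert da.confidence == pytest.approx(db.confidence, abs=1e-12)


def test_variant_comparison_harness_emits_paired_curves():
    scenes = generate_scenes(easy_config(seed=21), 16)
    out = compare_box_loss_variants(scenes, epochs=2, seed=4)
    assert set(out) == {"mpdiou", "ciou"}
    for variant, d in out.items():
        assert len(d["box_curve"]) == 2
        assert all(np.isfinite(d["box_curve"]))
        assert set(d["epochs_to_threshold"]) == {0.8, 0.6, 0.4, 0.2}
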