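"""Augmentation operators, dataset expansion/filter/split, annotation I/O."""

import numpy as np
import pytest

from micropest.boxes import Box, ImageDims
from micropest.datapipe import (AnnotatedImage, AugmentConfig, apportion,
                                augment_image, expand_dataset, quality_filter,
                                read_voc_xml, read_yolo_txt, split_dataset,
                                write_voc_xml, write_yolo_txt)
from micropest.metrics import GroundTruthBox


def make_image(w=100, h=100, boxes=(), rng=None):
    pixels = (rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
              if rng is not None else np.zeros((h, w, 3), np.uint8))
    return AnnotatedImage(pixels, [GroundTruthBox(Box(*b), c) for *b, c in boxes],
                          "img0")


class TestOperators:
    def test_zero_rotation_is_identity(self, rng):
        img = make_image(boxes=[(10, 10, 20, 30, "A")], rng=rng)
        out = augment_image(img, "rotate", angle_deg=0.0)
        assert np.array_equal(out.pixels, img.pixels)
        assert out.boxes[0].box == img.boxes[0].box

    def test_unit_exposure_and_zero_noise_are_identity(self, rng):
        img = make_image(boxes=[(10, 10, 20, 30, "A")], rng=rng)
        assert np.array_equal(augment_image(img, "exposure", gain=1.0).pixels,
                              img.pixels)
        assert np.array_equal(augment_image(img, "noise", sigma=0.0).pixels,
                              img.pixels)

    def test_90_degree_rotation_maps_box_correctly(self, rng):
        img = make_image(100, 100, boxes=[(10, 10, 20, 30, "A")], rng=rng)
        out = augment_image(img, "rotate", angle_deg=90.0)
        b = out.boxes[0].box
        assert (b.x1, b.y1, b.x2, b.y2) == pytest.approx((10, 80, 30, 90), abs=1e-9)

    def test_180_degree_rotation_pixels_match_numpy_flip(self, rng):
        img = make_image(40, 40, rng=rng)
        out = augment_image(img, "rotate", angle_deg=180.0)
        assert np.array_equal(out.pixels, img.pixels[::-1, ::-1])

    def test_exposure_scales_intensity(self):
        img = AnnotatedImage(np.full((10, 10, 3), 100, np.uint8), [])
        assert np.all(augment_image(img, "exposure", gain=1.5).pixels == 150)
        assert np.all(augment_image(img, "exposure", gain=0.5).pixels == 50)

    def test_unknown_operator_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_image(make_image(rng=rng), "shear")

    def test_crop_may_drop_all_boxes(self, rng):
        img = make_image(100, 100, boxes=[(90, 90, 99, 99, "A")], rng=rng)
        cfg = AugmentConfig(crop_keep=(0.2, 0.2))
        for seed in range(30):
            out = augment_image(img, "crop", cfg, seed=seed)
            assert isinstance(out.boxes, list)  # may legitimately be empty

    def test_boxes_stay_in_bounds_over_1000_random_augmentations(self):
        rng = np.random.default_rng(99)
        cfg = AugmentConfig()
        ops = ("crop", "rotate", "enlarge", "exposure", "noise")
        for i in range(1000):
            w, h = int(rng.integers(24, 48)), int(rng.integers(24, 48))
            boxes = []
            for _ in range(int(rng.integers(1, 4))):
                x, y = rng.uniform(0, w - 8), rng.uniform(0, h - 8)
                boxes.append((x, y, x + rng.uniform(3, 8), y + rng.uniform(3, 8), "A"))
            img = make_image(w, h, boxes=boxes, rng=rng)
            out = augment_image(img, ops[i % 5], cfg, seed=int(rng.integers(2**31)))
            oh, ow = out.pixels.shape[:2]
            for g in out.boxes:
                assert 0 <= g.box.x1 <= g.box.x2 <= ow
                assert 0 <= g.box.y1 <= g.box.y2 <= oh


class TestExpansion:
    def test_expansion_arithmetic_matches_study_bookkeeping(self, rng):
        # 417 originals expanded 11x -> 4587 images
        originals = [make_image(24, 24, boxes=[(4, 4, 16, 16, "ABCD"[i % 4])], rng=rng)
                     for i in range(417)]
        out = expand_dataset(originals, AugmentConfig(seed=1), factor=11)
        assert len(out) == 4587

    def test_small_factors(self, rng):
        one = [make_image(24, 24, boxes=[(4, 4, 16, 16, "A")], rng=rng)]
        assert len(expand_dataset(one, AugmentConfig(seed=0), factor=11)) == 11
        assert expand_dataset(one, AugmentConfig(seed=0), factor=1) == one

    def test_originals_retained_first(self, rng):
        imgs = [make_image(24, 24, rng=rng) for _ in range(3)]
        out = expand_dataset(imgs, AugmentConfig(seed=0), factor=4)
        assert out[0] is imgs[0] and out[4] is imgs[1] and out[8] is imgs[2]


class TestQualityFilter:
    def test_area_fraction_rules(self):
        small = make_image(100, 100, boxes=[(0, 0, 10, 10, "A")])
        big = make_image(100, 100, boxes=[(0, 0, 50, 50, "A")])
        empty = make_image(100, 100)
        kept, flagged = quality_filter([small, big, empty], 0.2)
        assert kept == [big]
        assert flagged == [small, empty]

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            quality_filter([], 0.0)


class TestSplit:
    def test_apportionment_reproduces_study_partition_sizes(self):
        assert apportion(1008, (0.6, 0.2, 0.2)) == (605, 202, 201)
        assert apportion(1033, (0.6, 0.2, 0.2)) == (620, 207, 206)
        assert apportion(10, (0.6, 0.2, 0.2)) == (6, 2, 2)

    def test_split_is_deterministic_and_covers_everything(self, rng):
        imgs = [make_image(16, 16, boxes=[(2, 2, 10, 10, "ABCD"[i % 4])], rng=rng)
                for i in range(53)]
        s1 = split_dataset(imgs, seed=5)
        s2 = split_dataset(imgs, seed=5)
        assert s1.assignment == s2.assignment
        assert sorted(s1.assignment) == list(range(53))
        n = {p: len(s1.indices(p)) for p in s1.PARTITIONS}
        assert sum(n.values()) == 53
        s3 = split_dataset(imgs, seed=6)
        assert {p: len(s3.indices(p)) for p in s3.PARTITIONS} == n  # sizes fixed
        assert s3.assignment != s1.assignment                       # membership moves

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            split_dataset([make_image(rng=rng)], (0.6, 0.2, 0.2))


class TestYoloTxt:
    def test_known_line_format(self, tmp_path):
        p = tmp_path / "a.txt"
        write_yolo_txt(p, [GroundTruthBox(Box(10, 10, 30, 30), "A")], ImageDims(100, 100))
        assert p.read_text() == "0 0.200000 0.200000 0.200000 0.200000\n"

    def test_round_trip(self, tmp_path, rng):
        dims = ImageDims(128, 96)
        boxes = [GroundTruthBox(Box(4, 8, 60, 40), "B"),
                 GroundTruthBox(Box(0, 0, 128, 96), "D")]
        p = tmp_path / "b.txt"
        write_yolo_txt(p, boxes, dims)
        back = read_yolo_txt(p, dims)
        for orig, rt in zip(boxes, back):
            assert rt.class_id == orig.class_id
            assert rt.box.as_array() == pytest.approx(orig.box.as_array(), abs=1e-3)
        # writing what was read is a fixed point
        write_yolo_txt(p, back, dims)
        assert read_yolo_txt(p, dims)[0].box.as_array() == pytest.approx(
            back[0].box.as_array(), abs=1e-9)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        assert read_yolo_txt(p, ImageDims(10, 10)) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.2\n0 0.5 oops 0.2\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_txt(p, ImageDims(10, 10))

    def test_out_of_range_value_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1.500000 0.5 0.2 0.2\n")
        with pytest.raises(ValueError, match="outside"):
            read_yolo_txt(p, ImageDims(10, 10))


class TestVocXml:
    def test_full_image_box_convention(self, tmp_path):
        p = tmp_path / "a.xml"
        write_voc_xml(p, [GroundTruthBox(Box(0, 0, 100, 100), "A")],
                      ImageDims(100, 100))
        dims, boxes, _ = read_voc_xml(p)
        assert (dims.w, dims.h) == (100, 100)
        b = boxes[0].box
        assert (b.x1, b.y1, b.x2, b.y2) == (0, 0, 100, 100)

    def test_integer_round_trip_exact_order_preserved(self, tmp_path):
        p = tmp_path / "b.xml"
        orig = [GroundTruthBox(Box(5, 6, 20, 30), "C"),
                GroundTruthBox(Box(1, 2, 3, 4), "B")]
        write_voc_xml(p, orig, ImageDims(64, 48), filename="x.png")
        _, back, fname = read_voc_xml(p)
        assert fname == "x.png"
        assert [g.class_id for g in back] == ["C", "B"]
        for o, r in zip(orig, back):
            assert r.box == o.box

    def test_unknown_class_listed(self, tmp_path):
        p = tmp_path / "c.xml"
        with pytest.raises(ValueError, match="known"):
            write_voc_xml(p, [GroundTruthBox(Box(0, 0, 1, 1), "Z")], ImageDims(8, 8))

    def test_missing_size_rejected(self, tmp_path):
        p = tmp_path / "d.xml"
        p.write_text("<annotation><filename>x</filename></annotation>")
        with pytest.raises(ValueError, match="size"):
            read_voc_xml(p)
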