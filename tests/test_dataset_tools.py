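"""Dataset tooling tests: format conversion, augmentation geometry,
splitting, and the acquisition scheduler."""

import numpy as np
import pytest

from germkit.boxgeom import Box
from germkit.dataset_tools import (
    AnnotationError,
    AnnotationRecord,
    ExperimentConfig,
    acquisition_schedule,
    add_noise,
    flip_rotate,
    hflip,
    read_voc_xml,
    rotate,
    scale,
    split_dataset,
    voc_to_yolo,
    write_voc_xml,
    yolo_to_voc,
)


def record(objects, image_id="img0", size=640):
    return AnnotationRecord(image_id, size, size, tuple(objects))


class TestVocYolo:
    def test_quarter_image_box(self):
        rec = record([("seed", Box.from_corners(0, 0, 320, 320))])
        assert voc_to_yolo(rec) == ["0 0.250000 0.250000 0.500000 0.500000"]

    def test_full_image_box(self):
        rec = record([("L_root", Box.from_corners(0, 0, 640, 640))])
        assert voc_to_yolo(rec) == ["2 0.500000 0.500000 1.000000 1.000000"]

    def test_yolo_round_trip_exact(self):
        lines = ["1 0.300000 0.400000 0.100000 0.200000"]
        rec = yolo_to_voc(lines, "x", 640, 640)
        assert voc_to_yolo(rec) == lines

    def test_voc_round_trip_within_tolerance(self):
        box = Box.from_corners(12.5, 40.25, 300.75, 512.0)
        rec = record([("S_root", box)])
        back = yolo_to_voc(voc_to_yolo(rec), "x", 640, 640)
        for a, b in zip(back.objects[0][1].corners, box.corners):
            assert a == pytest.approx(b, abs=1e-4 * 640)

    def test_box_outside_image_rejected(self):
        rec = record([("seed", Box.from_corners(600, 600, 700, 700))])
        with pytest.raises(AnnotationError):
            voc_to_yolo(rec)

    def test_xml_file_round_trip(self, tmp_path):
        rec = record(
            [("seed", Box.from_corners(10, 20, 50, 60)),
             ("L_root", Box.from_corners(50, 60, 90, 70))]
        )
        path = tmp_path / "img0.xml"
        write_voc_xml(rec, path)
        back = read_voc_xml(path)
        assert back.image_id == rec.image_id
        assert back.image_width == 640
        assert [label for label, _ in back.objects] == ["seed", "L_root"]
        for (_, b1), (_, b2) in zip(back.objects, rec.objects):
            for a, b in zip(b1.corners, b2.corners):
                assert a == pytest.approx(b, abs=0.01)


@pytest.fixture
def checker_image():
    img = np.zeros((640, 640))
    img[0:320, 0:320] = 1.0
    return img


class TestAugment:
    def test_hflip_mirrors_center(self, checker_image):
        rec = record([("seed", Box(160, 160, 320, 320))])
        img, out = hflip(checker_image, rec)
        _, box = out.objects[0]
        assert box.cx == pytest.approx(640 - 160)
        assert (box.w, box.h) == (320, 320)
        assert img[10, -10] == 1.0  # content mirrored too

    def test_rotate_90_quarter_box(self, checker_image):
        # top-left quarter box lands on the top-right quarter
        rec = record([("seed", Box.from_corners(0, 0, 320, 320))])
        img, out = rotate(checker_image, rec, 90.0)
        _, box = out.objects[0]
        assert box.corners == pytest.approx((320, 0, 640, 320), abs=1e-9)
        assert img[10, 630] > 0.5  # bright content followed the box
        assert img[630, 10] < 0.5

    def test_rotate_arbitrary_angle_content_follows_box(self):
        img = np.zeros((640, 640))
        img[100:140, 200:260] = 1.0  # bright patch
        rec = record([("seed", Box.from_corners(200, 100, 260, 140))])
        rotated, out = rotate(img, rec, 30.0)
        _, box = out.objects[0]
        rows, cols = np.nonzero(rotated > 0.5)
        assert cols.mean() == pytest.approx(box.cx, abs=2.0)
        assert rows.mean() == pytest.approx(box.cy, abs=2.0)

    def test_scale_multiplies_coordinates(self, checker_image):
        rec = record([("seed", Box.from_corners(0, 0, 320, 320))])
        img, out = scale(checker_image, rec, 0.5)
        _, box = out.objects[0]
        assert box.corners == pytest.approx((0, 0, 160, 160))
        assert img.shape == checker_image.shape

    def test_scale_clips_to_canvas(self, checker_image):
        rec = record([("seed", Box.from_corners(300, 300, 600, 600))])
        _, out = scale(checker_image, rec, 1.5)
        _, box = out.objects[0]
        assert box.corners == pytest.approx((450, 450, 640, 640))

    def test_object_fully_outside_canvas_dropped(self, checker_image):
        rec = record([("seed", Box.from_corners(0, 0, 10, 10)),
                      ("seed", Box.from_corners(400, 400, 500, 500))])
        _, out = scale(checker_image, rec, 2.0)
        # first box scales to (0,0,20,20); second lands outside 640
        assert len(out.objects) == 1

    def test_noise_deterministic_and_boxes_unchanged(self, checker_image):
        rec = record([("seed", Box.from_corners(0, 0, 320, 320))])
        img1, out1 = add_noise(checker_image, rec, sigma=0.05, seed=42)
        img2, _ = add_noise(checker_image, rec, sigma=0.05, seed=42)
        img3, _ = add_noise(checker_image, rec, sigma=0.05, seed=43)
        np.testing.assert_array_equal(img1, img2)
        assert not np.array_equal(img1, img3)
        assert out1.objects[0][1] == rec.objects[0][1]

    def test_flip_rotate_combined_op(self, checker_image):
        rec = record([("seed", Box.from_corners(0, 0, 320, 320))])
        _, out = flip_rotate(checker_image, rec, 180.0)
        _, box = out.objects[0]
        # hflip -> top-right quarter; 180 deg -> bottom-left quarter
        assert box.corners == pytest.approx((0, 320, 320, 640), abs=1e-9)

    def test_labels_never_altered(self, checker_image):
        rec = record([("L_root", Box.from_corners(100, 100, 200, 150))])
        for transform in (
            lambda: hflip(checker_image, rec),
            lambda: rotate(checker_image, rec, 37.0),
            lambda: scale(checker_image, rec, 0.8),
        ):
            _, out = transform()
            assert [label for label, _ in out.objects] == ["L_root"]


class TestSplit:
    def test_thousand_ids_split_700_200_100(self):
        ids = [f"img{i}" for i in range(1000)]
        train, val, test = split_dataset(ids, (7, 2, 1), seed=0)
        assert (len(train), len(val), len(test)) == (700, 200, 100)

    def test_ten_ids(self):
        train, val, test = split_dataset(list("abcdefghij"), (7, 2, 1), seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_partition_disjoint_and_exhaustive(self):
        ids = [f"i{i}" for i in range(97)]
        parts = split_dataset(ids, (7, 2, 1), seed=3)
        joined = [x for part in parts for x in part]
        assert sorted(joined) == sorted(ids)
        assert len(set(joined)) == len(ids)

    def test_same_seed_reproducible(self):
        ids = [f"i{i}" for i in range(50)]
        assert split_dataset(ids, seed=9) == split_dataset(ids, seed=9)

    def test_different_seeds_differ(self):
        ids = [f"i{i}" for i in range(200)]
        assert split_dataset(ids, seed=1) != split_dataset(ids, seed=2)

    def test_empty_ids_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], (7, 2, 1), 0)


class TestSchedule:
    def test_reference_trial_image_count(self):
        # 6 concentrations x 3 replicates, 48 h every 30 min: 1728 frames
        schedule = acquisition_schedule(ExperimentConfig())
        assert len(schedule) == 1728

    def test_reference_trial_seed_count(self):
        assert ExperimentConfig().total_seeds == 1458

    def test_one_hour_two_acquisitions(self):
        config = ExperimentConfig(
            concentrations=(0.0,), replicates=1, duration_h=1.0, interval_h=0.5
        )
        schedule = acquisition_schedule(config)
        assert [t for _, t in schedule] == [0.5, 1.0]

    def test_zero_replicates_empty_schedule(self):
        config = ExperimentConfig(replicates=0)
        assert acquisition_schedule(config) == []

    def test_indivisible_interval_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(duration_h=48.0, interval_h=0.7)

    def test_yaml_round_trip(self, tmp_path):
        config = ExperimentConfig(concentrations=(0.0, 45.0), replicates=2)
        path = tmp_path / "exp.yaml"
        config.to_yaml(path)
        assert ExperimentConfig.from_yaml(path) == config
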