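import numpy as np
import pytest

from stimchar import (
    Distractor,
    MotionDetectionConfig,
    SyntheticVideoSpec,
    detect_motion_onset,
    difference_mask,
    make_motion_video,
    motion_boxes,
    trim_to_onset,
)

from .conftest import flood_fill_boxes


class TestDifferenceMask:
    def test_identical_frames_give_empty_mask(self):
        frame = np.random.default_rng(0).integers(0, 256, (10, 10), dtype=np.uint8)
        assert not difference_mask(frame, frame).any()

    @pytest.mark.parametrize(
        "value, changed",
        [(120, True), (26, True), (25, False), (0, False)],
    )
    def test_ten_percent_threshold_boundary(self, value, changed):
        """Cutoff is 10% of 255 = 25.5: integer difference 26 registers, 25 does not."""
        reference = np.zeros((4, 4), dtype=np.uint8)
        frame = reference.copy()
        frame[1, 2] = value
        mask = difference_mask(frame, reference, 0.10)
        assert mask[1, 2] == changed
        assert mask.sum() == int(changed)

    def test_threshold_is_symmetric_in_sign(self):
        reference = np.full((2, 2), 200, dtype=np.uint8)
        frame = np.full((2, 2), 170, dtype=np.uint8)  # darker by 30
        assert difference_mask(frame, reference).all()

    def test_shape_mismatch_and_color_input_rejected(self):
        with pytest.raises(ValueError):
            difference_mask(np.zeros((4, 4), np.uint8), np.zeros((4, 5), np.uint8))
        with pytest.raises(ValueError):
            difference_mask(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4, 3), np.uint8))


class TestMotionBoxes:
    def test_single_block_survives_area_filter(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5:35, 10:40] = True
        boxes = motion_boxes(mask, MotionDetectionConfig())
        assert len(boxes) == 1
        box = boxes[0]
        assert (box.x, box.y, box.w, box.h, box.area) == (11, 6, 30, 30, 900)

    def test_small_block_filtered_out(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[0:10, 0:10] = True  # area 100 < 400
        assert motion_boxes(mask, MotionDetectionConfig()) == []

    def test_roi_band_excludes_box_outside_actor(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[5:35, 10:40] = True  # rows 6..35 (1-based)
        cfg_out = MotionDetectionConfig(roi_y=(50, 100))
        cfg_in = MotionDetectionConfig(roi_y=(30, 100))  # overlaps rows 30..35
        assert motion_boxes(mask, cfg_out) == []
        assert len(motion_boxes(mask, cfg_in)) == 1

    def test_diagonal_touch_is_one_component(self):
        """8-connectivity merges diagonally touching pixels into one region."""
        mask = np.zeros((40, 40), dtype=bool)
        mask[0:20, 0:20] = True
        mask[20:40, 20:40] = True  # touches only at the corner
        boxes = motion_boxes(mask, MotionDetectionConfig(min_box_area=1))
        assert len(boxes) == 1
        assert (boxes[0].w, boxes[0].h) == (40, 40)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_flood_fill_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(4, 65, size=2)
        mask = rng.random((h, w)) < rng.uniform(0.05, 0.5)
        cfg = MotionDetectionConfig(min_box_area=1)
        ours = [(b.x, b.y, b.w, b.h) for b in motion_boxes(mask, cfg)]
        assert ours == flood_fill_boxes(mask)


class TestDetectOnset:
    def test_recovers_true_onset_of_synthetic_clip(self, quiet_clip):
        seq, truth = quiet_clip
        result = detect_motion_onset(seq)
        assert result.onset_frame == truth["onset_frame"] == 10
        # log covers every examined frame, and pre-onset frames have no boxes
        assert set(result.box_log) == set(range(2, seq.n_frames + 1))
        assert all(not result.box_log[t] for t in range(2, 10))

    def test_subthreshold_patch_is_invisible(self):
        seq, _ = make_motion_video(SyntheticVideoSpec(onset_frame=10, patch_intensity_step=20))
        assert detect_motion_onset(seq).onset_frame is None

    def test_static_clip_has_no_onset(self):
        seq, _ = make_motion_video(
            SyntheticVideoSpec(onset_frame=10, patch_intensity_step=0)
        )
        assert detect_motion_onset(seq).onset_frame is None

    def test_small_flicker_rejected_real_motion_found(self):
        """A 9x9 every-frame flicker (area 81 < 400) must not mask onset at 7."""
        spec = SyntheticVideoSpec(
            onset_frame=7,
            distractors=(Distractor(x=5, y=5, w=9, h=9, intensity_step=100, period=1),),
        )
        seq, _ = make_motion_video(spec)
        assert detect_motion_onset(seq).onset_frame == 7

    def test_single_frame_sequence_rejected(self):
        from stimchar import FrameSequence

        seq = FrameSequence(frames=np.zeros((1, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            detect_motion_onset(seq)

    def test_actor_band_config_suppresses_offband_motion(self):
        spec = SyntheticVideoSpec(
            onset_frame=5, patch_position=(10, 10), patch_size=(30, 30)
        )  # patch rows 10..39
        seq, _ = make_motion_video(spec)
        assert detect_motion_onset(seq, MotionDetectionConfig(roi_y=(100, 200))).onset_frame is None
        assert detect_motion_onset(seq, MotionDetectionConfig(roi_y=(30, 200))).onset_frame == 5


class TestDetectorProperties:
    @pytest.mark.parametrize("seed", range(5))
    def test_raising_threshold_never_gives_earlier_onset(self, seed):
        rng = np.random.default_rng(seed)
        spec = SyntheticVideoSpec(
            onset_frame=int(rng.integers(2, 19)),
            patch_intensity_step=int(rng.integers(30, 150)),
            background_noise_sd=3.0,
            seed=seed,
        )
        seq, _ = make_motion_video(spec)
        onsets = []
        for frac in (0.05, 0.10, 0.20, 0.40):
            o = detect_motion_onset(seq, MotionDetectionConfig(threshold_fraction=frac))
            onsets.append(o.onset_frame if o.onset_frame is not None else 10**9)
        assert onsets == sorted(onsets)

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_min_area_never_gives_earlier_onset(self, seed):
        rng = np.random.default_rng(seed)
        spec = SyntheticVideoSpec(
            onset_frame=int(rng.integers(2, 19)),
            patch_size=(int(rng.integers(10, 40)), int(rng.integers(10, 40))),
            seed=seed,
        )
        seq, _ = make_motion_video(spec)
        onsets = []
        for area in (1, 100, 400, 900, 2000):
            o = detect_motion_onset(seq, MotionDetectionConfig(min_box_area=area))
            onsets.append(o.onset_frame if o.onset_frame is not None else 10**9)
        assert onsets == sorted(onsets)

    @pytest.mark.parametrize("onset", [2, 5, 11, 18])
    def test_detect_trim_redetect_lands_on_frame_two(self, onset):
        seq, _ = make_motion_video(SyntheticVideoSpec(onset_frame=onset, seed=onset))
        detected = detect_motion_onset(seq).onset_frame
        trimmed = trim_to_onset(seq, detected)
        assert detect_motion_onset(trimmed).onset_frame == 2
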