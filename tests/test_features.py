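"""Clips, alignment, and the behavioral feature dictionary."""

import math
from dataclasses import replace

import numpy as np
import pytest

from motiftrack.features import (
    FEATURE_NAMES,
    SNOUT,
    TAIL_BASE,
    Clip,
    FeatureConfig,
    align_clip,
    build_feature_table,
    compute_features,
    extract_clips,
    register_custom_feature,
    social_gate,
    unregister_custom_feature,
)
from tests.conftest import make_sequence


def make_clip(W=15, ref_xy=(100.0, 100.0), oth_xy=(200.0, 100.0),
              ref_heading=0.0, oth_heading=math.pi, body=40.0,
              ref_vel=(0.0, 0.0), oth_vel=(0.0, 0.0),
              ref_turn=0.0):
    """Hand-built two-animal clip with scripted rigid motion."""
    def pose(c, heading):
        h = np.array([math.cos(heading), math.sin(heading)])
        n = np.array([-math.sin(heading), math.cos(heading)])
        return np.array([
            c + 0.5 * body * h,
            c + 0.15 * body * h + 0.2 * body * n,
            c + 0.15 * body * h - 0.2 * body * n,
            c - 0.5 * body * h,
        ])

    data = np.zeros((2, W, 4, 3))
    data[..., 2] = 1.0
    for t in range(W):
        rc = np.array(ref_xy) + np.array(ref_vel) * t
        oc = np.array(oth_xy) + np.array(oth_vel) * t
        data[0, t, :, :2] = pose(rc, ref_heading + ref_turn * t)
        data[1, t, :, :2] = pose(oc, oth_heading)
    return Clip(clip_id=0, start_frame=0, data=data, track_ids=(1, 2),
                reference=0, non_reference=1)


def feature_dict(clip):
    return {f.name: f.values for f in compute_features(clip)}


class TestExtractClips:
    def test_window_counting(self):
        seq = make_sequence(150)
        assert len(extract_clips(seq, window=15, stride=15)) == 10
        assert len(extract_clips(make_sequence(14), window=15)) == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_clips(make_sequence(30), window=14)

    def test_clip_count_matches_enumeration_with_dropped_region(self):
        """A frame-numbering gap restricts windows to contiguous runs."""
        seq = make_sequence(100)
        frames = tuple(f for f in seq.frames if not 40 <= f.frame_index < 43)
        seq = replace_frames(seq, frames)
        clips = extract_clips(seq, window=15, stride=15)
        # oracle: enumerate windows over the observed index list
        idx = [f.frame_index for f in frames]
        count = 0
        start = 0
        while start + 15 <= len(idx):
            if idx[start + 14] - idx[start] == 14:
                count += 1
                start += 15
            else:
                start += 1
        assert len(clips) == count

    def test_low_confidence_clip_dropped(self):
        seq = make_sequence(30)
        frames = []
        for f in seq.frames:
            insts = []
            for inst in f.instances:
                if inst.track_id == 1 and f.frame_index < 15:
                    kps = tuple(
                        replace(k, confidence=0.01) for k in inst.keypoints
                    )
                    insts.append(replace(inst, keypoints=kps))
                else:
                    insts.append(inst)
            frames.append(replace(f, instances=tuple(insts)))
        seq2 = replace_frames(seq, tuple(frames))
        clips = extract_clips(seq2, window=15, stride=15)
        assert len(clips) == 1  # first window dropped, second survives


def replace_frames(seq, frames):
    return replace(seq, frames=frames)


class TestAlignClip:
    def test_quarter_turn_example(self):
        """Tail base (5,5), snout (5,9): alignment maps them to (0,0) and
        (4,0) — a -90 degree rotation in image coordinates."""
        clip = make_clip()
        data = clip.data.copy()
        mid = clip.middle
        data[0, mid, TAIL_BASE, :2] = (5.0, 5.0)
        data[0, mid, SNOUT, :2] = (5.0, 9.0)
        clip = replace(clip, data=data)
        al = align_clip(clip, "reference")
        np.testing.assert_allclose(al.data[0, mid, TAIL_BASE, :2], (0, 0), atol=1e-12)
        np.testing.assert_allclose(al.data[0, mid, SNOUT, :2], (4, 0), atol=1e-12)

    def test_already_aligned_clip_unchanged(self):
        clip = make_clip()
        mid = clip.middle
        data = clip.data.copy()
        # move reference so its middle-frame tail sits at origin, snout on +x
        shift = data[0, mid, TAIL_BASE, :2].copy()
        data[..., :2] -= shift
        clip = replace(clip, data=data)
        al = align_clip(clip, "reference")
        np.testing.assert_allclose(al.data, clip.data, atol=1e-9)

    def test_rigid_transform_preserves_distances(self, rng):
        clip = make_clip(ref_heading=0.7, oth_heading=-1.2,
                         ref_vel=(2.0, 1.0), oth_vel=(-1.0, 0.5))
        al = align_clip(clip, "reference")
        pts0 = clip.data[..., :2].reshape(-1, 2)
        pts1 = al.data[..., :2].reshape(-1, 2)
        for _ in range(100):
            i, j = rng.integers(0, len(pts0), 2)
            d0 = np.linalg.norm(pts0[i] - pts0[j])
            d1 = np.linalg.norm(pts1[i] - pts1[j])
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_alignment_postcondition_on_simulated_clips(self):
        import motiftrack as mt

        session = mt.standard_benchmark(seed=7)
        clips = extract_clips(session.ground_truth)
        for clip in clips[:20]:
            for ref in (0, 1):
                c = clip.with_reference(ref)
                al = align_clip(c, "reference")
                mid = c.middle
                tail = al.data[ref, mid, TAIL_BASE, :2]
                snout = al.data[ref, mid, SNOUT, :2]
                assert np.abs(tail).max() < 1e-9
                assert abs(snout[1]) < 1e-9
                assert snout[0] > 0

    def test_degenerate_body_vector_rejected(self):
        clip = make_clip()
        data = clip.data.copy()
        data[0, clip.middle, SNOUT, :2] = data[0, clip.middle, TAIL_BASE, :2]
        with pytest.raises(ValueError, match="degenerate"):
            align_clip(replace(clip, data=data), "reference")


class TestComputeFeatures:
    def test_static_pose_has_zero_displacement(self):
        feats = feature_dict(make_clip())
        np.testing.assert_allclose(feats["displace_rho"], 0.0, atol=1e-12)

    def test_nose_nose_rho_pythagorean(self):
        """Snouts offset by (3, 4) are 5 apart."""
        clip = make_clip()
        data = clip.data.copy()
        data[1, :, :, :2] = data[0, :, :, :2]  # identical poses...
        data[1, :, :, 0] += 3.0                # ...offset by (3, 4)
        data[1, :, :, 1] += 4.0
        feats = feature_dict(replace(clip, data=data))
        np.testing.assert_allclose(feats["nose_nose_rho"], 5.0, atol=1e-9)
        np.testing.assert_allclose(feats["two_body_sin"], 0.0, atol=1e-9)
        np.testing.assert_allclose(feats["two_body_cos"], 1.0, atol=1e-9)

    def test_turning_clip_body_change_sin(self):
        """A body vector rotating 10 deg/frame gives body_change_sin =
        sin(10 deg) at every frame after the first."""
        clip = make_clip(ref_turn=math.radians(10.0))
        feats = feature_dict(clip)
        expected = math.sin(math.radians(10.0))
        np.testing.assert_allclose(feats["body_change_sin"][1:], expected,
                                   atol=1e-9)
        assert feats["body_change_sin"][0] == 0.0

    def test_body_length_and_ear_distances(self):
        clip = make_clip(body=40.0)
        feats = feature_dict(clip)
        np.testing.assert_allclose(feats["body_length"], 40.0, atol=1e-9)
        # snout at 0.5L forward; ears at 0.15L forward, +-0.2L lateral
        d = 40.0 * math.hypot(0.35, 0.2)
        np.testing.assert_allclose(feats["left_ear"], d, atol=1e-9)
        np.testing.assert_allclose(feats["right_ear"], d, atol=1e-9)

    def test_sin_cos_pairs_unit_norm(self):
        clip = make_clip(ref_heading=0.3, oth_heading=2.1,
                         ref_vel=(2.0, -1.0), oth_vel=(1.0, 1.5),
                         ref_turn=0.05)
        feats = feature_dict(clip)
        for base in ("left_ear", "right_ear", "two_body", "two_head",
                     "nose_nose", "TM_nose_RM_tail", "RM_nose_TM_tail"):
            s, c = feats[f"{base}_sin"], feats[f"{base}_cos"]
            np.testing.assert_allclose(s**2 + c**2, 1.0, atol=1e-9)
        # displacement defined from frame 1 on
        s, c = feats["displace_sin"], feats["displace_cos"]
        np.testing.assert_allclose(s[1:]**2 + c[1:]**2, 1.0, atol=1e-9)

    def test_invariance_under_global_rigid_motion(self, rng):
        clip = make_clip(ref_heading=0.4, oth_heading=-0.9,
                         ref_vel=(1.5, 0.5), oth_vel=(-0.5, 1.0))
        base = feature_dict(clip)
        th = rng.uniform(-math.pi, math.pi)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        shift = rng.uniform(-200, 200, 2)
        data = clip.data.copy()
        data[..., :2] = data[..., :2] @ R.T + shift
        moved = feature_dict(replace(clip, data=data))
        for name in base:
            np.testing.assert_allclose(moved[name], base[name], atol=1e-6,
                                       err_msg=name)

    def test_rho_scales_linearly_sin_cos_invariant(self):
        clip = make_clip(ref_vel=(2.0, 1.0), oth_vel=(0.5, -0.5))
        base = feature_dict(clip)
        data = clip.data.copy()
        data[..., :2] *= 3.0
        scaled = feature_dict(replace(clip, data=data))
        for name in base:
            if name.endswith("_rho") or name in (
                "body_length", "left_ear", "right_ear", "displace_rho"
            ):
                np.testing.assert_allclose(scaled[name], 3.0 * base[name],
                                           atol=1e-8, err_msg=name)
            elif name.endswith(("_sin", "_cos")):
                np.testing.assert_allclose(scaled[name], base[name],
                                           atol=1e-9, err_msg=name)


class TestSocialGate:
    def test_infinite_threshold_accepts_everything(self):
        assert social_gate(make_clip(oth_xy=(5000.0, 100.0)), math.inf)

    def test_far_apart_clip_rejected(self):
        clip = make_clip(oth_xy=(1000.0, 100.0))
        assert not social_gate(clip, 100.0)

    def test_approaching_clip_accepted(self):
        clip = make_clip(oth_xy=(300.0, 100.0), oth_vel=(-10.0, 0.0))
        assert social_gate(clip, 80.0)


class TestFeatureTable:
    def _clips(self, rng, n=6):
        clips = []
        for i in range(n):
            c = make_clip(
                ref_xy=tuple(rng.uniform(100, 400, 2)),
                oth_xy=tuple(rng.uniform(100, 400, 2)),
                ref_heading=rng.uniform(-3, 3),
                oth_heading=rng.uniform(-3, 3),
                ref_vel=tuple(rng.uniform(-3, 3, 2)),
            )
            clips.append(replace(c, clip_id=i))
        return clips

    def test_zscore_columns_standardized(self, rng):
        table = build_feature_table(self._clips(rng), FeatureConfig())
        sd = table.values.std(axis=0)
        mean = table.values.mean(axis=0)
        nondeg = sd > 1e-9
        np.testing.assert_allclose(mean[nondeg], 0.0, atol=1e-6)
        np.testing.assert_allclose(sd[nondeg], 1.0, atol=1e-6)
        assert np.all(np.isfinite(table.values))

    def test_weights_scale_columns(self, rng):
        clips = self._clips(rng)
        t1 = build_feature_table(clips, FeatureConfig(weights={"body_length": 1.0}))
        t4 = build_feature_table(clips, FeatureConfig(weights={"body_length": 4.0}))
        np.testing.assert_allclose(
            t4.feature_block("body_length"),
            4.0 * t1.feature_block("body_length"), atol=1e-9,
        )
        np.testing.assert_allclose(
            t4.feature_block("nose_nose_rho"),
            t1.feature_block("nose_nose_rho"), atol=1e-9,
        )

    def test_zero_weights_remove_all_but_one_feature(self, rng):
        clips = self._clips(rng)
        weights = {n: 0.0 for n in FEATURE_NAMES}
        weights["displace_rho"] = 1.0
        table = build_feature_table(clips, FeatureConfig(weights=weights))
        for name in FEATURE_NAMES:
            block = table.feature_block(name)
            if name == "displace_rho":
                assert np.abs(block).max() > 0
            else:
                np.testing.assert_allclose(block, 0.0, atol=1e-12)

    def test_two_rows_per_dyad_clip(self, rng):
        clips = self._clips(rng, n=5)
        table = build_feature_table(clips, FeatureConfig())
        assert table.n_rows == 10
        assert sorted(set(table.clip_ids)) == [0, 1, 2, 3, 4]


class TestCustomFeatures:
    def test_constant_feature_zscores_to_zero(self, rng):
        register_custom_feature("always_one", lambda arrays: np.ones(15))
        try:
            clips = TestFeatureTable()._clips(rng)
            table = build_feature_table(clips, FeatureConfig())
            np.testing.assert_allclose(
                table.feature_block("always_one"), 0.0, atol=1e-12
            )
        finally:
            unregister_custom_feature("always_one")

    def test_rebinding_builtin_name_rejected(self):
        with pytest.raises(ValueError, match="already defined"):
            register_custom_feature("body_length", lambda arrays: np.ones(15))

    def test_wrong_length_rejected(self):
        register_custom_feature("bad_len", lambda arrays: np.ones(7))
        try:
            with pytest.raises(ValueError, match="bad_len"):
                compute_features(make_clip())
        finally:
            unregister_custom_feature("bad_len")

    def test_snout_speed_matches_external_recomputation(self):
        """A custom snout-velocity feature equals the displacement of the
        snout computed directly from the raw clip."""
        def snout_speed(arrays):
            snout = arrays["pose_clips"][:, SNOUT, :2]
            d = np.linalg.norm(np.diff(snout, axis=0), axis=1)
            return np.concatenate([[0.0], d])

        register_custom_feature("snout_speed", snout_speed)
        try:
            clip = make_clip(ref_vel=(2.0, 1.0))
            feats = feature_dict(clip)
            expected = np.full(15, math.hypot(2.0, 1.0))
            expected[0] = 0.0
            np.testing.assert_allclose(feats["snout_speed"], expected, atol=1e-9)
        finally:
            unregister_custom_feature("snout_speed")
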