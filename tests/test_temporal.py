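"""Timed verification protocol: sampling, motion, majority vote, fusion."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gericare.core import FrameRecord, PoseLabel, Skeleton, StaticPose, VitalsSeries
from gericare.synthetic import (
    generate_skeleton_sequence,
    generate_vitals,
    script_from_schedule,
    _standing_points,
    _to_pixels,
)
from gericare.temporal import (
    ActivityLedger,
    AssessmentWindow,
    MonitorConfig,
    VerifiedPose,
    disambiguate_lying,
    monitor,
    motion_score,
    sample_assessments,
    verify_pose,
)
from conftest import make_skeleton


def standing_at(x, t=0.0):
    return make_skeleton(_to_pixels(_standing_points(), (x, 460.0), 160.0), timestamp=t)


def stream_of(duration, fps, person="p"):
    frames = []
    n = int(duration * fps)
    for k in range(n):
        t = k / fps
        sk = make_skeleton(
            _to_pixels(_standing_points(), (200.0, 460.0), 160.0), timestamp=t, person=person
        )
        frames.append(FrameRecord(timestamp=t, skeletons=(sk,)))
    return frames


class TestSampling:
    def test_600_frames_per_minute_yield_12_assessments(self):
        frames = stream_of(60.0, 10.0)
        assert len(frames) == 600
        out = sample_assessments(frames, period=5.0)
        assert len(out["p"]) == 12

    def test_period_equal_to_duration_gives_one_assessment(self):
        frames = stream_of(30.0, 10.0)
        out = sample_assessments(frames, period=30.0)
        assert len(out["p"]) == 1

    def test_empty_stream_gives_empty_output(self):
        assert sample_assessments([], period=5.0) == {}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_jittered_timestamps_match_brute_force_scheduler(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0.0, 120.0, size=200))
        frames = [
            FrameRecord(timestamp=float(t), skeletons=(standing_at(200.0, float(t)),))
            for t in times
        ]
        got = [t for t, _ in sample_assessments(frames, period=5.0)["p"]]
        # brute force: walk period boundaries, keep the first frame at or
        # after each boundary, then jump to the boundary after that frame
        expected = []
        t0 = times[0]
        due = t0
        for t in times:
            if t >= due:
                expected.append(float(t))
                due = t0 + (np.floor((t - t0) / 5.0) + 1) * 5.0
        assert got == expected


class TestMotionScore:
    def test_identical_skeletons_score_zero(self):
        a = standing_at(200.0)
        assert motion_score(a, a) == pytest.approx(0.0)

    def test_one_torso_length_translation_scores_one(self):
        a = standing_at(200.0)
        from gericare.posture import extract_features

        torso = extract_features(a).torso_length
        b = standing_at(200.0 + torso)
        assert motion_score(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric(self, rng):
        a = standing_at(200.0)
        arr = a.as_array()
        arr[:, :2] += rng.normal(0, 5, (17, 2))
        b = Skeleton.from_array(arr, timestamp=1.0)
        assert motion_score(a, b) == pytest.approx(motion_score(b, a))

    def test_matches_naive_per_keypoint_computation(self, rng):
        a = standing_at(200.0)
        arr = a.as_array()
        arr[:, :2] += rng.normal(0, 8, (17, 2))
        b = Skeleton.from_array(arr, timestamp=1.0)
        from gericare.posture import extract_features

        disp = np.linalg.norm(a.as_array()[:, :2] - b.as_array()[:, :2], axis=1).mean()
        torso = 0.5 * (extract_features(a).torso_length + extract_features(b).torso_length)
        assert motion_score(a, b) == pytest.approx(disp / torso, abs=1e-9)

    def test_too_few_common_keypoints_is_undefined(self):
        a = standing_at(200.0)
        arr = a.as_array()
        arr[2:, 2] = 0.0
        b = Skeleton.from_array(arr, timestamp=1.0)
        assert motion_score(a, b) is None


def window_of(poses, skeletons=None):
    if skeletons is None:
        skeletons = [standing_at(200.0, t) for t in (0.0, 5.0, 10.0)]
    triples = tuple((5.0 * i, p, sk) for i, (p, sk) in enumerate(zip(poses, skeletons)))
    return AssessmentWindow(assessments=triples)


class TestVerifyPose:
    def test_translating_upright_window_is_walking(self):
        sks = [standing_at(200.0 + 60.0 * i, 5.0 * i) for i in range(3)]
        w = window_of([StaticPose.UPRIGHT] * 3, sks)
        assert verify_pose(w) is VerifiedPose.WALKING

    def test_static_upright_window_is_standing(self):
        w = window_of([StaticPose.UPRIGHT] * 3)
        assert verify_pose(w) is VerifiedPose.STANDING

    def test_exhaustive_truth_table(self):
        """All 3-combinations of static classes against a hand rule table."""
        classes = [
            StaticPose.UPRIGHT,
            StaticPose.SITTING,
            StaticPose.FALLEN_ON_GROUND,
            StaticPose.LYING_LIKE,
            StaticPose.UNKNOWN,
        ]
        for combo in itertools.product(classes, repeat=3):
            got = verify_pose(window_of(list(combo)))
            counts = {c: combo.count(c) for c in classes}
            if counts[StaticPose.FALLEN_ON_GROUND] >= 2:
                expect = VerifiedPose.FALLEN_ON_GROUND
            else:
                top = max(counts.values())
                winners = [c for c in classes if counts[c] == top]
                if top < 2 or winners[0] is StaticPose.UNKNOWN:
                    expect = VerifiedPose.UNDETERMINED
                else:
                    w = winners[0]
                    if w is StaticPose.UPRIGHT:
                        expect = VerifiedPose.STANDING  # static skeletons
                    else:
                        expect = VerifiedPose(w.value)
            assert got is expect, f"{combo}: {got} != {expect}"

    def test_never_outputs_sleeping(self):
        for combo in itertools.product(
            [StaticPose.UPRIGHT, StaticPose.LYING_LIKE, StaticPose.UNKNOWN], repeat=3
        ):
            assert verify_pose(window_of(list(combo))).value != "sleeping"


def lying_assessments(move_px):
    """One minute of lying skeletons, shifting by move_px between samples."""
    from gericare.synthetic import _lying_points

    out = []
    for i in range(13):
        t = 5.0 * i
        xy = _to_pixels(_lying_points(), (420.0 + move_px * i, 245.0), 160.0)
        out.append((t, make_skeleton(xy, timestamp=t)))
    return out


def vitals_with(hr, sleep_state):
    rows = [
        {"timestamp": 5.0 * i, "heart_rate": hr, "sleep_state": sleep_state}
        for i in range(13)
    ]
    return VitalsSeries(pd.DataFrame(rows))


class TestDisambiguateLying:
    def test_sleep_flag_forces_sleeping(self):
        label, low = disambiguate_lying(
            lying_assessments(5.0), vitals_with(80.0, True), baseline_hr=70.0
        )
        assert label is PoseLabel.SLEEPING and not low

    def test_visible_motion_and_normal_hr_is_lying(self):
        label, _ = disambiguate_lying(
            lying_assessments(5.0), vitals_with(70.0, False), baseline_hr=70.0
        )
        assert label is PoseLabel.LYING_IN_BED

    @pytest.mark.parametrize("sleep", [True, False])
    @pytest.mark.parametrize("hr_offset", [-15.0, -10.0, -5.0, 0.0])
    @pytest.mark.parametrize("move_px", [0.0, 3.0])
    def test_rule_grid(self, sleep, hr_offset, move_px):
        baseline = 70.0
        label, _ = disambiguate_lying(
            lying_assessments(move_px),
            vitals_with(baseline + hr_offset, sleep),
            baseline_hr=baseline,
            still_threshold=0.02,
            hr_margin=10.0,
        )
        still = move_px == 0.0
        expect = sleep or (still and hr_offset <= -10.0)
        assert (label is PoseLabel.SLEEPING) == expect

    def test_missing_vitals_fall_back_to_motion_with_flag(self):
        label, low = disambiguate_lying(lying_assessments(0.0), None, baseline_hr=70.0)
        assert label is PoseLabel.SLEEPING and low
        label, low = disambiguate_lying(lying_assessments(5.0), None, baseline_hr=70.0)
        assert label is PoseLabel.LYING_IN_BED and low


class TestLedger:
    def test_conservation_and_cap(self):
        led = ActivityLedger("p")
        for m in range(24 * 60):
            led.add_minutes(m * 60.0, PoseLabel.SITTING)
        day = led.day_of(0.0)
        assert led.total_hours(day) == pytest.approx(24.0)
        with pytest.raises(ValueError):
            led.add_minutes(10.0, PoseLabel.SITTING)

    def test_csv_round_trip(self, tmp_path):
        led = ActivityLedger("p")
        led.add_minutes(0.0, PoseLabel.WALKING, 90.0)
        led.add_minutes(90000.0, PoseLabel.SLEEPING, 300.0)
        path = tmp_path / "ledger.csv"
        led.to_csv(path)
        back = ActivityLedger.read_csv(path)
        assert back.days == led.days
        for d in led.days:
            for p in (PoseLabel.WALKING, PoseLabel.SLEEPING):
                assert back.hours(d, p) == pytest.approx(led.hours(d, p))


@pytest.fixture(scope="module")
def scripted_run():
    schedule = [
        (PoseLabel.WALKING, 240.0),
        (PoseLabel.SITTING, 240.0),
        (PoseLabel.STANDING, 240.0),
        (PoseLabel.LYING_IN_BED, 240.0),
        (PoseLabel.SLEEPING, 240.0),
        (PoseLabel.FALLEN_ON_GROUND, 60.0),
    ]
    script = script_from_schedule(
        "p1", 0.0, schedule, seed=9, sleep_intervals=((960.0, 1200.0),)
    )
    frames = generate_skeleton_sequence(script, fps=2.0)
    vitals = generate_vitals(script, period=30.0)
    labels, ledgers, alerts = monitor(frames, vitals, config=MonitorConfig())
    return script, labels, ledgers, alerts


class TestMonitor:
    def test_ledger_matches_script_to_the_minute(self, scripted_run):
        script, labels, ledgers, _ = scripted_run
        led = ledgers["p1"]
        day = led.day_of(0.0)
        for pose, minutes in [
            (PoseLabel.WALKING, 4),
            (PoseLabel.SITTING, 4),
            (PoseLabel.STANDING, 4),
            (PoseLabel.LYING_IN_BED, 4),
            (PoseLabel.SLEEPING, 4),
            (PoseLabel.FALLEN_ON_GROUND, 1),
        ]:
            assert led.hours(day, pose) == pytest.approx(minutes / 60.0), pose

    def test_every_minute_label_matches_ground_truth(self, scripted_run):
        script, labels, _, _ = scripted_run
        for l in labels:
            assert l.pose is script.true_label(l.minute)

    def test_single_fall_gives_single_alert_at_scripted_minute(self, scripted_run):
        _, _, _, alerts = scripted_run
        assert len(alerts) == 1
        assert alerts[0].minute == pytest.approx(1200.0)

    def test_conservation_total_equals_labelled_minutes(self, scripted_run):
        _, labels, ledgers, _ = scripted_run
        led = ledgers["p1"]
        total = sum(led.total_hours(d) for d in led.days)
        assert total == pytest.approx(len(labels) / 60.0)

    def test_all_day_standing_fills_ledger(self):
        # coarse frames: one per assessment, to keep a full day cheap
        frames = []
        for m in range(0, 24 * 60):
            for s in (0.0, 5.0, 10.0):
                t = m * 60.0 + s
                frames.append(
                    FrameRecord(timestamp=t, skeletons=(standing_at(200.0, t),))
                )
        labels, ledgers, _ = monitor(frames, None)
        led = ledgers["p"]
        day = led.day_of(0.0)
        assert led.hours(day, PoseLabel.STANDING) == pytest.approx(24.0)
        assert led.total_hours(day) == pytest.approx(24.0)
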