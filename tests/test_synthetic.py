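"""Generators: determinism, frame budgets, ground-truth consistency."""

import numpy as np
import pytest

from gericare.careplan import evaluate_rules
from gericare.core import PATIENT_SCHEMA, PoseLabel
from gericare.posture import extract_features
from gericare.reid import DetectorParams, build_vocabulary, encode, extract_descriptors
from gericare.synthetic import (
    ScenarioScript,
    Segment,
    generate_labelled_skeletons,
    generate_patient_states,
    generate_skeleton_sequence,
    generate_vitals,
    generate_ward_images,
    script_from_schedule,
)


def minute_script(seed=0, **kw):
    return ScenarioScript(
        subject_tag="s",
        segments=(Segment(0.0, 60.0, PoseLabel.STANDING),),
        seed=seed,
        **kw,
    )


class TestSkeletonGeneration:
    def test_60s_at_10fps_gives_600_frames(self):
        frames = generate_skeleton_sequence(minute_script(), fps=10.0)
        assert len(frames) == 600

    def test_zero_noise_standing_has_vertical_torso_everywhere(self):
        frames = generate_skeleton_sequence(
            minute_script(noise_frac=0.0, occlusion_prob=0.0), fps=2.0
        )
        for f in frames:
            feats = extract_features(f.skeletons[0])
            assert feats.torso_angle == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_is_bit_identical(self):
        f1 = generate_skeleton_sequence(minute_script(seed=5), fps=5.0)
        f2 = generate_skeleton_sequence(minute_script(seed=5), fps=5.0)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(
                a.skeletons[0].as_array(), b.skeletons[0].as_array()
            )

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            ScenarioScript(
                subject_tag="s",
                segments=(
                    Segment(0.0, 60.0, PoseLabel.STANDING),
                    Segment(30.0, 90.0, PoseLabel.WALKING),
                ),
            )

    def test_schedule_helper_assigns_ground_truth(self):
        script = script_from_schedule(
            "s", 0.0, [(PoseLabel.WALKING, 60.0), (PoseLabel.SITTING, 60.0)]
        )
        assert script.true_label(30.0) is PoseLabel.WALKING
        assert script.true_label(90.0) is PoseLabel.SITTING
        assert script.true_label(120.0) is None


class TestVitals:
    def test_no_sleep_intervals_means_sleep_state_false(self):
        vit = generate_vitals(minute_script(), period=10.0)
        assert all(s is False for s in vit.frame["sleep_state"])

    def test_full_dropout_gives_all_missing(self):
        vit = generate_vitals(minute_script(vitals_dropout=1.0), period=10.0)
        assert vit.frame["heart_rate"].isna().all()

    def test_awake_heart_rate_mean_near_baseline(self):
        script = ScenarioScript(
            subject_tag="s",
            segments=(Segment(0.0, 10000.0 * 60.0, PoseLabel.STANDING),),
            seed=4,
            baseline_hr=72.0,
        )
        vit = generate_vitals(script, period=60.0)
        assert len(vit) == 10000
        assert vit.frame["heart_rate"].mean() == pytest.approx(72.0, abs=2.0)

    def test_sleep_interval_lowers_heart_rate_and_raises_flag(self):
        script = minute_script(sleep_intervals=((0.0, 30.0),), hr_sleep_drop=15.0)
        vit = generate_vitals(script, period=5.0).frame
        asleep = vit[[bool(s) for s in vit["sleep_state"]]]
        awake = vit[[not bool(s) for s in vit["sleep_state"]]]
        assert asleep["heart_rate"].mean() < awake["heart_rate"].mean() - 10.0

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            minute_script(baseline_hr=-5.0)


class TestPatientStates:
    def test_states_are_schema_valid_by_construction(self, ruleset):
        for state, _ in generate_patient_states(50, ruleset, seed=1):
            for var, vals in PATIENT_SCHEMA.items():
                assert state[var] in vals

    def test_labels_match_direct_rule_sweep(self, ruleset):
        for state, action in generate_patient_states(200, ruleset, seed=2):
            assert evaluate_rules(state, ruleset)[0] is action

    def test_same_seed_identical_datasets(self, ruleset):
        a = generate_patient_states(30, ruleset, seed=3)
        b = generate_patient_states(30, ruleset, seed=3)
        assert [(s.values, act) for s, act in a] == [(s.values, act) for s, act in b]

    def test_uniform_priors_supported(self, ruleset):
        recs = generate_patient_states(200, ruleset, seed=4, priors="uniform")
        seen = {s["Temp"] for s, _ in recs}
        assert len(seen) == len(PATIENT_SCHEMA["Temp"])

    def test_n_below_one_rejected(self, ruleset):
        with pytest.raises(ValueError):
            generate_patient_states(0, ruleset)


class TestLabelledSkeletons:
    def test_ground_truth_covers_four_static_classes(self):
        data = generate_labelled_skeletons(5, seed=0)
        assert len({lbl for _, lbl in data}) == 4

    def test_determinism(self):
        a = generate_labelled_skeletons(5, noise_frac=0.02, occlusion_prob=0.1, seed=8)
        b = generate_labelled_skeletons(5, noise_frac=0.02, occlusion_prob=0.1, seed=8)
        for (sa, la), (sb, lb) in zip(a, b):
            assert la is lb
            np.testing.assert_array_equal(sa.as_array(), sb.as_array())


class TestWardImages:
    def test_same_seed_identical_images(self):
        a = generate_ward_images(per_class=3, seed=6)
        b = generate_ward_images(per_class=3, seed=6)
        for (ia, la), (ib, lb) in zip(a, b):
            assert la == lb
            np.testing.assert_array_equal(ia, ib)

    def test_per_class_below_two_rejected(self):
        with pytest.raises(ValueError):
            generate_ward_images(per_class=1)

    def test_same_identity_histograms_more_similar_than_cross_identity(self):
        images = generate_ward_images(identities=3, per_class=6, seed=10)
        params = DetectorParams()
        descs = np.vstack([extract_descriptors(im, params) for im, _ in images[:8]])
        vocab = build_vocabulary(descs, k=24, seed=0)
        hists: dict[str, list[np.ndarray]] = {}
        for im, lab in images:
            hists.setdefault(lab, []).append(encode(im, vocab, params))

        def cos(u, v):
            return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v) + 1e-12))

        within, across = [], []
        labs = list(hists)
        for lab in labs:
            hs = hists[lab]
            within += [cos(a, b) for i, a in enumerate(hs) for b in hs[i + 1 :]]
        for i, la in enumerate(labs):
            for lb in labs[i + 1 :]:
                across += [cos(a, b) for a in hists[la] for b in hists[lb]]
        assert np.mean(within) > np.mean(across)
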