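"""Synthetic cohort generator: schedules, coupling model, behavior, scores."""

import numpy as np
import pytest

from plvnet.bands import ALPHA
from plvnet.connectivity import build_matrix
from plvnet.preprocess import band_filter, segment
from plvnet.synth import (
    BEHAVIOR_PARAMS,
    CouplingPlan,
    SubjectSpec,
    calibrate_coupling,
    default_coupling_plans,
    make_cohort,
    make_trial_schedule,
    simulate_behavior,
    simulate_recording,
    simulate_trial_events,
)


def _subject(group="HC", seed=0, cesd=None):
    cesd = cesd if cesd is not None else (25 if group == "DE" else 10)
    return SubjectSpec(f"{group}X", group, cesd, 9, seed=seed)


class TestSubjectSpec:
    def test_inclusion_criteria_enforced(self):
        with pytest.raises(ValueError):
            SubjectSpec("s", "DE", cesd=15, bdi=9, seed=0)  # CES-D too low for DE
        with pytest.raises(ValueError):
            SubjectSpec("s", "HC", cesd=20, bdi=9, seed=0)  # too high for HC
        with pytest.raises(ValueError):
            SubjectSpec("s", "HC", cesd=10, bdi=20, seed=0)  # BDI-II cap
        SubjectSpec("s", "DE", cesd=17, bdi=13, seed=0)  # boundary is legal

    def test_cohort_scores_satisfy_criteria(self):
        subjects = make_cohort(10, seed=3)
        assert len(subjects) == 20
        for s in subjects:
            assert s.bdi <= 13
            assert (s.cesd > 16) if s.group == "DE" else (s.cesd < 16)
        assert len({s.subject_id for s in subjects}) == 20
        assert len({s.seed for s in subjects}) == 20


class TestTrialSchedule:
    @pytest.mark.parametrize(
        "n_types,n_persp,expected", [(2, 8, 16), (1, 1, 1), (3, 4, 12)]
    )
    def test_counts(self, n_types, n_persp, expected):
        trials = make_trial_schedule(n_types, n_persp, seed=7)
        assert len(trials) == expected

    def test_full_crossing_is_a_permutation(self):
        trials = make_trial_schedule(3, 4, seed=7)
        combos = {(t.obstacle, t.perspective_deg) for t in trials}
        assert len(combos) == 12  # every (type, angle) pair exactly once

    def test_canonical_angles(self):
        trials = make_trial_schedule(2, 8, seed=0)
        assert {t.perspective_deg for t in trials} == {
            30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0
        }

    def test_seed_shuffles_order(self):
        a = make_trial_schedule(2, 8, seed=1)
        b = make_trial_schedule(2, 8, seed=2)
        assert [t.obstacle for t in a] != [t.obstacle for t in b] or [
            t.perspective_deg for t in a
        ] != [t.perspective_deg for t in b]

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            make_trial_schedule(0, 8, seed=0)


class TestCouplingPlan:
    def test_rejects_self_and_duplicate_edges(self):
        with pytest.raises(ValueError):
            CouplingPlan(ALPHA, "RS", edges=[("F3", "F3", 0.5)])
        with pytest.raises(ValueError):
            CouplingPlan(ALPHA, "RS", edges=[("F3", "P3", 0.5), ("P3", "F3", 0.2)])
        with pytest.raises(ValueError):
            CouplingPlan(ALPHA, "RS", edges=[("F3", "P3", 1.5)])

    def test_unknown_channel_detected(self, montage8):
        plan = CouplingPlan(ALPHA, "RS", edges=[("F3", "Qz9", 0.5)])
        with pytest.raises(ValueError, match="Qz9"):
            plan.validate_against(montage8)


class TestSimulateRecording:
    def test_fully_coupled_pair_has_unit_plv(self, montage8):
        """c = 1 with no noise gives a constant-lag pair: PLV ~ 1.

        The tolerance covers per-epoch Hilbert edge effects on the lagged
        signals; the exact PLV = 1 property of constant-lag *phases* is
        covered by the connectivity oracle tests.
        """
        plan = CouplingPlan(ALPHA, "RS", edges=[("F3", "P3", 1.0)], baseline_c=0.0)
        sub = _subject(seed=11)
        rec = simulate_recording(
            sub, [plan], montage8, durations={"RS": 20.0}, noise_sigma=0.0,
            bands=(ALPHA,),
        )
        epochs = band_filter(segment(rec, "RS"), ALPHA)
        mat = build_matrix(epochs)
        i, j = montage8.index("F3"), montage8.index("P3")
        assert mat.values[i, j] == pytest.approx(1.0, abs=5e-3)

    def test_uncoupled_pair_matches_monte_carlo_null(self, montage8):
        """c = 0 PLV sits within 3 MC sd of the independent-phase expectation."""
        cal = calibrate_coupling([0.0], duration=120.0, n_rep=30, seed=5)
        null_mean, null_sd = cal[0.0]
        plan = CouplingPlan(ALPHA, "RS", edges=[], baseline_c=0.0)
        sub = _subject(seed=21)
        rec = simulate_recording(
            sub, [plan], montage8, durations={"RS": 120.0}, noise_sigma=0.0,
            bands=(ALPHA,),
        )
        epochs = band_filter(segment(rec, "RS"), ALPHA)
        mat = build_matrix(epochs)
        i, j = montage8.index("F3"), montage8.index("P3")
        assert abs(mat.values[i, j] - null_mean) < 3 * null_sd

    def test_seed_determinism_bitwise(self, montage8):
        sub = _subject(seed=33)
        plans = [CouplingPlan(ALPHA, "RS", edges=[("F3", "P3", 0.6)])]
        a = simulate_recording(sub, plans, montage8, durations={"RS": 4.0})
        b = simulate_recording(sub, plans, montage8, durations={"RS": 4.0})
        np.testing.assert_array_equal(a.data, b.data)

    def test_different_seeds_differ(self, montage8):
        plans = [CouplingPlan(ALPHA, "RS", edges=[])]
        a = simulate_recording(_subject(seed=1), plans, montage8, durations={"RS": 4.0})
        b = simulate_recording(_subject(seed=2), plans, montage8, durations={"RS": 4.0})
        assert not np.array_equal(a.data, b.data)

    def test_nyquist_guard(self, montage8):
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_recording(
                _subject(), [], montage8, fs=80.0, durations={"RS": 2.0}
            )

    def test_stage_annotations_cover_durations(self, montage8):
        rec = simulate_recording(
            _subject(), [], montage8, durations={"RS": 4.0, "LM": 6.0},
        )
        assert rec.stages() == ["RS", "LM"]
        spans = {a.stage: (a.start_s, a.end_s) for a in rec.annotations}
        assert spans["RS"] == (0.0, 4.0)
        assert spans["LM"] == (4.0, 10.0)
        assert rec.duration_s == pytest.approx(10.0)


class TestCalibration:
    def test_extremes_ordered(self):
        cal = calibrate_coupling([0.0, 1.0], duration=10.0, n_rep=10, seed=0)
        assert cal[1.0][0] > cal[0.0][0]
        assert cal[1.0][0] == pytest.approx(1.0, abs=1e-6)

    def test_response_curve_monotone_within_noise(self):
        cal = calibrate_coupling(
            [0.2, 0.5, 0.8], duration=30.0, n_rep=20, seed=2
        )
        (m1, s1), (m2, s2), (m3, s3) = cal[0.2], cal[0.5], cal[0.8]
        assert m2 > m1 - 2 * max(s1, s2)
        assert m3 > m2 - 2 * max(s2, s3)

    def test_small_n_rep_rejected(self):
        with pytest.raises(ValueError):
            calibrate_coupling([0.5], n_rep=0)


class TestBehavior:
    def test_zero_sd_reproduces_group_means(self):
        """Degenerate draws return the configured group stage means exactly."""
        zero_sd = {
            g: {s: (m, 0.0) for s, (m, _) in BEHAVIOR_PARAMS[g].items()}
            for g in BEHAVIOR_PARAMS
        }
        hc = simulate_behavior(_subject("HC"), zero_sd)
        assert [hc.stage_times[s] for s in ("O", "LM", "FO", "D")] == [
            10.91, 20.52, 19.31, 24.22
        ]
        assert hc.total == pytest.approx(74.96)
        de = simulate_behavior(_subject("DE"), zero_sd)
        assert de.total == pytest.approx(89.43)

    def test_sample_means_converge_to_parameters(self):
        """Monte-Carlo stage means land within 3 SEM of the configuration."""
        n = 1000
        draws = {s: [] for s in ("O", "LM", "FO", "D")}
        for k in range(n):
            rec = simulate_behavior(_subject("HC", seed=k))
            for s in draws:
                draws[s].append(rec.stage_times[s])
        for s, (mean, sd) in BEHAVIOR_PARAMS["HC"].items():
            sem = sd / np.sqrt(n)
            # truncation at zero is negligible at these means (> 5 sd away)
            assert abs(np.mean(draws[s]) - mean) < 3 * sem

    def test_negative_sd_rejected(self):
        bad = {"HC": {"O": (10.0, -1.0), "LM": (20.0, 1.0),
                      "FO": (19.0, 1.0), "D": (24.0, 1.0)}}
        with pytest.raises(ValueError):
            simulate_behavior(_subject("HC"), bad)

    def test_trial_events_consistent_with_behavior(self):
        sub = _subject("HC", seed=9)
        behavior, events = simulate_trial_events(sub, n_trials=16)
        assert len(events) == 16 * 5
        times = [e["time_s"] for e in events if e["trial"] == 1]
        assert times == sorted(times)
        # mean total across trials tracks the subject's drawn total
        totals = [
            max(e["time_s"] for e in events if e["trial"] == t)
            for t in range(1, 17)
        ]
        assert np.mean(totals) == pytest.approx(behavior.total, rel=0.1)


class TestDefaultPlans:
    def test_structure_covers_planted_families(self, montage62):
        plans = default_coupling_plans("DE", montage62)
        keys = {(p.band.name, p.stage) for p in plans}
        assert ("theta", "RS") in keys and ("alpha", "RS") in keys
        for stage in ("LM", "FO"):
            for band in ("delta", "beta", "gamma"):
                assert (band, stage) in keys
        for p in plans:
            assert len(p.edges) == 10

    def test_group_asymmetry_has_expected_direction(self, montage62):
        de = {(p.band.name, p.stage): p for p in default_coupling_plans("DE", montage62)}
        hc = {(p.band.name, p.stage): p for p in default_coupling_plans("HC", montage62)}
        # rest: HC couples more strongly; task: DE couples more strongly
        assert de[("theta", "RS")].edges[0][2] < hc[("theta", "RS")].edges[0][2]
        assert de[("beta", "LM")].edges[0][2] > hc[("beta", "LM")].edges[0][2]
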