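import json

import numpy as np
import pandas as pd
import pytest

from gridsync.maps import ArenaSpec, SpikeTrain, Trajectory
from gridsync.cohort_pipeline import (
    Cohort,
    SelectionCriteria,
    SessionFormatError,
    classify_hd_clusters,
    clip_during_window,
    cross_session_control_pairs,
    exclude_duplicates,
    rayleigh_uniformity_test,
    read_session,
    select_cohort,
    spike_overlap_fraction,
    summarize,
    write_session,
)
from gridsync.synthgen import SessionRecording, simulate_trajectory

from conftest import poisson_train


def tiny_session(arena, seed=0, durations=(300.0, 300.0, 300.0), n_cells=2, rate=3.0):
    rng = np.random.default_rng(seed)
    trajectories = {}
    spikes = {f"c{i}": {} for i in range(n_cells)}
    offset = 0.0
    for cond, dur in zip(("pre", "during", "post"), durations):
        traj = simulate_trajectory(arena, dur, seed=rng)
        trajectories[cond] = Trajectory(traj.t + offset, traj.x, traj.y, traj.hd)
        for i in range(n_cells):
            n = rng.poisson(rate * dur)
            times = np.sort(rng.uniform(offset, offset + dur, n))
            spikes[f"c{i}"][cond] = SpikeTrain(times, offset, offset + dur, f"c{i}", cond)
        offset += dur
    return SessionRecording(
        session_id=f"tiny{seed}", arena=arena, trajectories=trajectories, spikes=spikes
    )


class TestSessionIO:
    def test_round_trip_identity(self, arena, tmp_path):
        sess = tiny_session(arena, seed=1)
        write_session(sess, tmp_path / "s1")
        loaded = read_session(tmp_path / "s1")
        assert loaded.session_id == sess.session_id
        assert loaded.cell_ids == sess.cell_ids
        assert loaded.conditions == sess.conditions
        for cond in sess.conditions:
            assert np.allclose(
                loaded.trajectories[cond].x, sess.trajectories[cond].x, atol=1e-5
            )
            for cid in sess.cell_ids:
                assert np.allclose(
                    loaded.spikes[cid][cond].times,
                    sess.spikes[cid][cond].times,
                    atol=1e-5,
                )

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(SessionFormatError, match="manifest"):
            read_session(tmp_path / "nothing")

    def test_spike_beyond_span_reports_location(self, arena, tmp_path):
        sess = tiny_session(arena, seed=2)
        p = write_session(sess, tmp_path / "s2")
        bad = p / "spikes_c0_pre.txt"
        bad.write_text(bad.read_text() + "99999.0\n")
        with pytest.raises(SessionFormatError, match="outside condition span"):
            read_session(p)

    def test_unsorted_spikes_detected(self, arena, tmp_path):
        sess = tiny_session(arena, seed=3)
        p = write_session(sess, tmp_path / "s3")
        bad = p / "spikes_c1_during.txt"
        lines = bad.read_text().split()
        lines[2], lines[3] = lines[3], lines[2]
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(SessionFormatError, match="unsorted"):
            read_session(p)

    def test_out_of_arena_position_detected(self, arena, tmp_path):
        sess = tiny_session(arena, seed=4)
        p = write_session(sess, tmp_path / "s4")
        f = p / "position_pre.csv"
        df = pd.read_csv(f)
        df.loc[5, "x"] = 1e4
        df.to_csv(f, index=False)
        with pytest.raises(SessionFormatError, match="outside arena"):
            read_session(p)

    def test_loads_synthetic_fixture(self, coupled_session, tmp_path):
        p = write_session(coupled_session, tmp_path / "synth")
        loaded = read_session(p)
        assert len(loaded.cell_ids) == 4


class TestClipDuringWindow:
    def test_sixty_minute_condition(self, arena):
        sess = tiny_session(arena, seed=5, durations=(60.0, 3600.0, 60.0))
        clipped = clip_during_window(sess, (900.0, 2700.0))
        traj = clipped.trajectories["during"]
        assert traj.t[-1] - traj.t[0] == pytest.approx(1800.0, abs=0.1)
        tr = clipped.spikes["c0"]["during"]
        assert tr.duration == pytest.approx(1800.0, abs=0.1)
        assert np.all(tr.times >= tr.t_start) and np.all(tr.times <= tr.t_stop)

    def test_twenty_minute_condition(self, arena):
        sess = tiny_session(arena, seed=6, durations=(60.0, 1200.0, 60.0))
        clipped = clip_during_window(sess, (900.0, 2700.0))
        traj = clipped.trajectories["during"]
        assert traj.t[-1] - traj.t[0] == pytest.approx(300.0, abs=0.1)

    def test_pre_condition_untouched(self, arena):
        sess = tiny_session(arena, seed=7, durations=(120.0, 3600.0, 120.0))
        clipped = clip_during_window(sess, (900.0, 2700.0))
        assert np.array_equal(clipped.trajectories["pre"].t, sess.trajectories["pre"].t)
        assert np.array_equal(
            clipped.spikes["c1"]["pre"].times, sess.spikes["c1"]["pre"].times
        )

    def test_too_short_raises(self, arena):
        sess = tiny_session(arena, seed=8, durations=(60.0, 600.0, 60.0))
        with pytest.raises(ValueError):
            clip_during_window(sess, (900.0, 2700.0))


class TestExcludeDuplicates:
    def test_identical_train_dropped(self, arena):
        sess = tiny_session(arena, seed=9, n_cells=2)
        # make c1 a copy of c0 with a few spikes removed (lower rate)
        for cond in sess.conditions:
            t0 = sess.spikes["c0"][cond]
            sess.spikes["c1"][cond] = SpikeTrain(
                t0.times[:-5], t0.t_start, t0.t_stop, "c1", cond
            )
        cleaned, dropped = exclude_duplicates(sess)
        assert dropped == ["c1"]
        assert "c1" not in cleaned.spikes

    def test_overlap_fraction_full(self):
        rng = np.random.default_rng(10)
        a = poisson_train(3.0, 100.0, rng, "a")
        assert spike_overlap_fraction(a, a) == 1.0

    def test_independent_pair_overlap_matches_closed_form(self):
        # P(partner within +/- w/2) = 1 - exp(-lambda w)
        rng = np.random.default_rng(11)
        lam, dur, window = 2.0, 3000.0, 0.001
        fracs = [
            spike_overlap_fraction(
                poisson_train(lam, dur, rng), poisson_train(lam, dur, rng), window
            )
            for _ in range(30)
        ]
        expected = 1.0 - np.exp(-lam * window)
        assert np.mean(fracs) == pytest.approx(expected, rel=0.5)
        assert np.mean(fracs) < 0.01  # comfortably retained at 5%

    def test_independent_cells_retained(self, arena):
        sess = tiny_session(arena, seed=12, n_cells=3)
        cleaned, dropped = exclude_duplicates(sess)
        assert dropped == []
        assert len(cleaned.cell_ids) == 3


class TestSelectCohort:
    @staticmethod
    def fake_scores(rows):
        return pd.DataFrame(
            rows, columns=["session", "cell", "condition", "grid_score", "rayleigh"]
        )

    def test_threshold_rules(self, arena):
        sess = tiny_session(arena, seed=13, n_cells=3)
        scores = self.fake_scores(
            [
                (sess.session_id, "c0", "pre", 0.92, 0.1),
                (sess.session_id, "c0", "during", -0.30, 0.1),
                (sess.session_id, "c1", "pre", 0.40, 0.1),
                (sess.session_id, "c1", "during", 0.00, 0.1),
                (sess.session_id, "c2", "pre", 0.80, 0.1),
                (sess.session_id, "c2", "during", 0.35, 0.1),
            ]
        )
        crit = SelectionCriteria(during_window=(0.0, 300.0))
        cohort = select_cohort([sess], crit, scores=scores)
        assert cohort.kept_cells == {sess.session_id: ["c0"]}

    def test_pair_count_combinatorics(self, arena):
        sess = tiny_session(arena, seed=14, n_cells=4)
        rows = []
        for c in sess.cell_ids:
            rows.append((sess.session_id, c, "pre", 1.0, 0.1))
            rows.append((sess.session_id, c, "during", 0.0, 0.1))
        cohort = select_cohort(
            [sess], SelectionCriteria(during_window=(0.0, 300.0)),
            scores=self.fake_scores(rows),
        )
        assert len(cohort.pairs()) == 6  # 4*3/2


class TestClassifyHdClusters:
    def test_rule_application(self):
        scores = pd.DataFrame(
            [
                ("s", "c0", "pre", 0.1),
                ("s", "c0", "during", 0.7),
                ("s", "c1", "pre", 0.1),
                ("s", "c1", "during", 0.2),
                ("s", "c2", "pre", 0.5),
                ("s", "c2", "during", 0.7),
            ],
            columns=["session", "cell", "condition", "rayleigh"],
        )
        labels = classify_hd_clusters(scores, threshold=0.4)
        got = labels.set_index("cell")["hd_label"]
        assert got["c0"] == "grid_turned_hd"
        assert got["c1"] == "non_hd"
        assert got["c2"] == "unclassified"


class TestCrossSessionControls:
    def make_cohort(self, arena, cells_per_session=(3, 3)):
        sessions = {}
        kept = {}
        for k, n in enumerate(cells_per_session):
            s = tiny_session(arena, seed=20 + k, n_cells=n)
            sessions[s.session_id] = s
            kept[s.session_id] = s.cell_ids
        return Cohort(sessions=sessions, kept_cells=kept, scores=pd.DataFrame())

    def test_pair_combinatorics(self, arena):
        cohort = self.make_cohort(arena, (3, 3))
        df, _ = cross_session_control_pairs(cohort)
        assert len(df) == 9

    def test_no_pair_shares_session(self, arena):
        cohort = self.make_cohort(arena, (3, 2))
        df, _ = cross_session_control_pairs(cohort)
        assert (df["session_a"] != df["session_b"]).all()

    def test_independent_sessions_near_zero(self, arena):
        cohort = self.make_cohort(arena, (4, 4, 4))
        df, r = cross_session_control_pairs(cohort)
        # independent Poisson sessions: correlation-of-correlations ~ 0
        n = len(df)
        assert abs(r) < 3.0 / np.sqrt(n - 3)

    def test_single_session_raises(self, arena):
        cohort = self.make_cohort(arena, (4,))
        with pytest.raises(ValueError):
            cross_session_control_pairs(cohort)


class TestSummarize:
    @staticmethod
    def pair_rows(n_pairs=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(n_pairs):
            base = rng.uniform(-0.5, 0.5)
            for cond in ("pre", "during", "post"):
                rows.append(
                    {
                        "session": "s",
                        "cell_a": f"c{k}",
                        "cell_b": f"d{k}",
                        "condition": cond,
                        "temporal_r": base,
                        "spatial_r0": base / 2.0,
                        "nearest_peak_angle": rng.uniform(0, 360),
                        "significant": bool(abs(base) > 0.25),
                        "sign": "positive" if base > 0.25 else (
                            "negative" if base < -0.25 else "none"
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_correlations_give_unity(self):
        out = summarize(self.pair_rows())
        assert out["temporal_pre_vs_during"]["r"] == pytest.approx(1.0, abs=1e-9)

    def test_signed_proportions_sum(self):
        out = summarize(self.pair_rows(10, seed=3))
        for cond, p in out["significance_proportions"].items():
            assert p["positive"] + p["negative"] == pytest.approx(p["significant"])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            summarize(self.pair_rows(2))


class TestRayleighUniformity:
    def test_uniform_angles_high_p(self):
        rng = np.random.default_rng(30)
        _, p = rayleigh_uniformity_test(rng.uniform(0, 360, 200))
        assert p > 0.01

    def test_concentrated_angles_low_p(self):
        rng = np.random.default_rng(31)
        _, p = rayleigh_uniformity_test(rng.normal(100.0, 10.0, 200) % 360.0)
        assert p < 1e-6
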