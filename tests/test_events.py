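import numpy as np
import pandas as pd
import pytest

from flyarena import (
    Epoch,
    ProtocolError,
    ProtocolSchedule,
    ReturnParams,
    detect_return,
    return_probability,
    screen_matrix,
    summarize_on_off,
    zscore_screen,
)
from flyarena.events import delta_distance_from_center
from conftest import make_tracks


def _metrics_frame(t, fly_id="f", **cols):
    t = np.asarray(t, dtype=float)
    df = pd.DataFrame({"fly_id": fly_id, "frame": np.arange(len(t)), "t": t})
    for k, v in cols.items():
        df[k] = v
    for k in ("speed", "dtheta_abs", "cos_upwind", "dist_center", "cum_turn_5"):
        if k not in df.columns:
            df[k] = 0.0
    return df


def _one_pulse_schedule(t_on=2.0, t_off=12.0, tail=20.0):
    return ProtocolSchedule(
        "one_pulse",
        [Epoch("led_on", t_on, t_off, 0, "led"), Epoch("led_off", t_off, t_off + tail, 0, "led")],
    )


class TestSummarizeOnOff:
    def test_forced_speed_values(self):
        sched = _one_pulse_schedule()
        t = np.arange(0, 32, 1 / 30)
        on = (t >= 2.0) & (t < 12.0)
        m = _metrics_frame(t, speed=np.where(on, 5.0, 10.0))
        out = summarize_on_off(m, sched).set_index("parameter")["value"]
        assert out["speed_ON"] == pytest.approx(5.0)
        assert out["speed_OFF"] == pytest.approx(10.0)

    def test_single_trial_matches_hand_mean(self):
        sched = _one_pulse_schedule()
        rng = np.random.default_rng(0)
        t = np.arange(0, 32, 1 / 30)
        speed = rng.uniform(0, 20, t.size)
        m = _metrics_frame(t, speed=speed)
        out = summarize_on_off(m, sched).set_index("parameter")["value"]
        assert out["speed_ON"] == pytest.approx(speed[(t >= 2) & (t < 4)].mean())
        assert out["speed_OFF"] == pytest.approx(speed[(t >= 12) & (t < 14)].mean())

    def test_no_led_epochs_is_configuration_error(self):
        sched = ProtocolSchedule("odor_only", [Epoch("test", 0, 60, 0, "odor")])
        m = _metrics_frame(np.arange(0, 60, 1 / 30))
        with pytest.raises(ProtocolError):
            summarize_on_off(m, sched)

    def test_empty_window_warns_and_is_missing(self):
        sched = _one_pulse_schedule()
        m = _metrics_frame(np.arange(0, 5, 1 / 30))  # recording ends before LED offset
        with pytest.warns(UserWarning, match="missing"):
            out = summarize_on_off(m, sched).set_index("parameter")["value"]
        assert np.isnan(out["speed_OFF"])


class TestDeltaDistance:
    def test_stationary_fly_is_zero(self):
        sched = _one_pulse_schedule()
        t = np.arange(0, 32, 1 / 30)
        m = _metrics_frame(t, dist_center=20.0)
        value, detail, n_excl = delta_distance_from_center(m, sched, fps=30.0)
        assert value == pytest.approx(0.0)
        assert n_excl == 0

    def test_linear_radial_ramp(self):
        # 10 -> 20 mm linearly across the 10 s ON window: mean 15, onset 10
        sched = _one_pulse_schedule()
        t = np.arange(0, 32, 1 / 30)
        dist = np.full(t.size, 10.0)
        on = (t >= 2.0) & (t < 12.0)
        dist[on] = 10.0 + (t[on] - 2.0)
        dist[t >= 12.0] = 20.0
        m = _metrics_frame(t, dist_center=dist)
        value, detail, _ = delta_distance_from_center(m, sched, fps=30.0)
        assert value == pytest.approx(5.0, abs=0.05)  # discrete frames vs continuous ramp

    def test_matches_bruteforce_per_fly(self, geometry, activation, small_cohort):
        from flyarena import frame_metrics

        cohort, _, _ = small_cohort
        m = frame_metrics(cohort, geometry)
        value, detail, _ = delta_distance_from_center(m, activation, cohort.fps)
        # oracle: explicit loop over flies and trials
        expected = []
        for e in activation.led_on:
            onset_frame = int(np.floor(e.t_start * 30.0 + 1e-9))
            for fly_id, grp in m.groupby("fly_id"):
                at = grp[grp.frame == onset_frame]
                win = grp[(grp.t >= e.t_start) & (grp.t < e.t_end)]
                if len(at) and len(win):
                    expected.append(win.dist_center.mean() - float(at.dist_center.iloc[0]))
        assert value == pytest.approx(np.mean(expected), abs=1e-12)

    def test_untracked_at_onset_excluded_and_counted(self):
        sched = _one_pulse_schedule()
        t = np.arange(0, 32, 1 / 30)
        m = _metrics_frame(t, dist_center=20.0)
        m = m[m.frame != 60]  # drop the onset frame (t = 2 s)
        value, detail, n_excl = delta_distance_from_center(m, sched, fps=30.0)
        assert n_excl == 1 and np.isnan(value)


class TestDetectReturn:
    def _track_with_path(self, dists, fps=30.0):
        """Fly at origin-ish position (20, 0) whose distance from the start
        follows `dists` (moved along +x)."""
        x = 20.0 + np.asarray(dists, dtype=float)
        return make_tracks({"f": (range(len(dists)), x, np.zeros(len(dists)))}, fps=fps)

    def test_excursion_then_return_detected(self):
        fps = 30.0
        n = int(16 * fps)
        d = np.zeros(n)
        d[int(3 * fps): int(8 * fps)] = 12.0  # out 12 mm at +3 s
        d[int(8 * fps):] = 1.0                # back to 1 mm at +8 s
        out = detect_return(self._track_with_path(d), t_ref=0.0)
        assert out.returned and not out.excluded

    def test_no_excursion_means_no_return(self):
        d = np.abs(np.sin(np.linspace(0, 10, 480))) * 8.0  # never reaches 10 mm
        out = detect_return(self._track_with_path(d), t_ref=0.0)
        assert not out.returned

    def test_return_before_excursion_does_not_count(self):
        n = 480
        d = np.full(n, 5.0)
        d[0:100] = 1.0    # "returns" first ...
        d[200:] = 12.0    # ... then leaves for good
        out = detect_return(self._track_with_path(d), t_ref=0.0)
        assert not out.returned

    def test_low_coverage_is_excluded(self):
        d = np.zeros(480)
        tr = self._track_with_path(d)
        tr.data = tr.data[tr.data.frame % 2 == 0].reset_index(drop=True)  # 50% coverage
        out = detect_return(tr, t_ref=0.0)
        assert out.excluded

    def test_t_ref_outside_recording_is_error(self):
        tr = self._track_with_path(np.zeros(480))
        with pytest.raises(ValueError):
            detect_return(tr, t_ref=100.0)

    def test_monotone_in_thresholds(self):
        # raising excursion, lowering return radius or horizon never flips False -> True
        rng = np.random.default_rng(17)
        for _ in range(25):
            steps = rng.normal(0, 1.2, (450, 2))
            pos = np.cumsum(steps, axis=0) * 0.5
            tr = make_tracks({"f": (range(450), 20 + pos[:, 0], pos[:, 1])})
            lax = detect_return(tr, 0.0, ReturnParams(8.0, 4.0, 14.0))
            strict = detect_return(tr, 0.0, ReturnParams(10.0, 3.0, 10.0))
            assert not (strict.returned and not lax.returned)


class TestReturnProbability:
    def test_bounds_attained(self):
        sched = ProtocolSchedule("p", [Epoch("led_on", 0.0, 1.0, 0, "led")])
        fps = 30.0
        n = int(17 * fps)
        d = np.zeros(n)
        d[int(5 * fps): int(9 * fps)] = 15.0
        returner = 20.0 + d
        stayer = np.full(n, 20.0)
        both = make_tracks({"r": (range(n), returner, np.zeros(n)),
                            "s": (range(n), stayer, np.zeros(n))})
        stats = return_probability(both, sched)
        assert stats.probability == pytest.approx(0.5)
        assert stats.n_valid == 2 and stats.n_returned == 1

    def test_invariant_to_fly_relabeling(self, activation, small_cohort):
        cohort, _, _ = small_cohort
        p1 = return_probability(cohort, activation)
        relabeled = cohort.data.copy()
        mapping = {f: f"z{i}" for i, f in enumerate(reversed(cohort.fly_ids))}
        relabeled["fly_id"] = relabeled["fly_id"].map(mapping)
        relabeled = relabeled.sort_values(["fly_id", "frame"]).reset_index(drop=True)
        from flyarena import FlyTrackTable
        p2 = return_probability(FlyTrackTable(relabeled, cohort.fps), activation)
        assert p1 == p2


class TestZScores:
    def test_sample_sd_standardization(self):
        v = pd.DataFrame({"p": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        np.testing.assert_allclose(zscore_screen(v)["p"], [-1.0, 0.0, 1.0])

    def test_constant_column_missing_with_warning(self):
        v = pd.DataFrame({"p": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="degenerate"):
            z = zscore_screen(v)
        assert z["p"].isna().all()

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(8)
        v = pd.DataFrame(rng.normal(3, 5, (20, 9)))
        z = zscore_screen(v)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_invariant_under_affine_column_transform(self):
        rng = np.random.default_rng(9)
        v = pd.DataFrame(rng.normal(0, 1, (12, 4)))
        z1 = zscore_screen(v)
        z2 = zscore_screen(v * 7.5 + 3.0)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_screen_matrix_carries_values_and_z(self):
        v = pd.DataFrame({"p": [1.0, 3.0]}, index=["ctrl", "line"])
        sm = screen_matrix(v)
        pd.testing.assert_frame_equal(sm.values, v)
        assert sm.zscores.loc["line", "p"] > 0
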