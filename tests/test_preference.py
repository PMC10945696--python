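import numpy as np
import pandas as pd
import pytest

from flyarena import (
    ArenaGeometry,
    AssayRun,
    Epoch,
    ProtocolSchedule,
    assign_quadrant,
    build_schedule,
    light_preference_index,
    memory_score,
    preference_index,
    screening_filter,
    swap_odor_labels,
)
from conftest import make_tracks

QUADRANT_CENTER_ANGLES = {0: np.pi / 4, 1: 3 * np.pi / 4, 2: -3 * np.pi / 4, 3: -np.pi / 4}


def _static_cohort(quadrant_counts, n_frames, r=25.0, fps=30.0):
    """Flies parked at the centre angle of given quadrants for n_frames."""
    per_fly = {}
    i = 0
    for q, count in quadrant_counts.items():
        ang = QUADRANT_CENTER_ANGLES[q]
        for _ in range(count):
            per_fly[f"fly{i:03d}"] = (
                np.arange(n_frames),
                np.full(n_frames, r * np.cos(ang)),
                np.full(n_frames, r * np.sin(ang)),
            )
            i += 1
    return make_tracks(per_fly, fps=fps)


class TestAssignQuadrant:
    def test_45_degrees_is_quadrant_zero(self, geometry):
        tr = make_tracks({"f": ([0], [10 * np.cos(np.pi / 4)], [10 * np.sin(np.pi / 4)])})
        assert assign_quadrant(tr, geometry)["quadrant"].iloc[0] == 0

    def test_hysteresis_near_center_keeps_previous_quadrant(self, geometry):
        # firmly in quadrant 1, then a point within 0.5 mm of the centre
        tr = make_tracks({"f": ([0, 1], [-10.0, 0.1], [10.0, 0.1])})
        q = assign_quadrant(tr, geometry)["quadrant"]
        assert list(q) == [1, 1]

    def test_hysteresis_near_boundary_keeps_previous_quadrant(self, geometry):
        # x-axis is the quadrant 0/3 boundary; approach it from quadrant 0
        tr = make_tracks({"f": ([0, 1, 2], [10.0, 20.0, 20.0], [10.0, 0.2, -0.2])})
        q = assign_quadrant(tr, geometry)["quadrant"]
        assert list(q) == [0, 0, 0]

    def test_full_angle_sweep_matches_sector_oracle(self):
        phase = 0.3
        geometry = ArenaGeometry(quadrant_phase=phase)
        angles = np.linspace(-np.pi, np.pi, 721, endpoint=False)
        r = 30.0
        tr = make_tracks(
            {f"f{i}": ([0], [r * np.cos(a)], [r * np.sin(a)]) for i, a in enumerate(angles)}
        )
        got = assign_quadrant(tr, geometry, hysteresis_mm=0.0)
        got = got.set_index("fly_id")["quadrant"]
        for i, a in enumerate(angles):
            rel = (a - phase) % (2 * np.pi)
            expected = int(rel // (np.pi / 2)) % 4
            if abs(r * np.sin(rel % (np.pi / 2))) < 1e-9:  # exactly on a boundary
                continue
            assert got[f"f{i}"] == expected, f"angle {a}"


class TestPreferenceIndex:
    def _pi_of_counts(self, paired, unpaired, geometry):
        cohort = _static_cohort({0: paired, 1: unpaired}, n_frames=3)
        quad = assign_quadrant(cohort, geometry)
        return preference_index(quad, geometry.odor_assignment)

    @pytest.mark.parametrize("paired,unpaired,expected", [(15, 5, 0.5), (10, 10, 0.0), (20, 0, 1.0)])
    def test_formula_arithmetic(self, geometry, paired, unpaired, expected):
        pi = self._pi_of_counts(paired, unpaired, geometry)
        np.testing.assert_allclose(pi["pi"], expected)
        assert (pi["n_flies"] == paired + unpaired).all()

    def test_bounds_and_label_swap_negation(self, geometry):
        rng = np.random.default_rng(12)
        quad = pd.DataFrame(
            {
                "fly_id": np.repeat([f"f{i}" for i in range(20)], 50),
                "frame": np.tile(np.arange(50), 20),
                "t": np.tile(np.arange(50) / 30.0, 20),
                "quadrant": rng.integers(0, 4, 1000),
            }
        )
        pi = preference_index(quad, geometry.odor_assignment)
        assert pi["pi"].between(-1.0, 1.0).all()
        swapped = preference_index(quad, swap_odor_labels(geometry.odor_assignment))
        np.testing.assert_allclose(swapped["pi"], -pi["pi"], atol=0)

    def test_rotation_with_relabeling_is_invariant(self, geometry):
        rng = np.random.default_rng(13)
        n = 40
        x = rng.uniform(-30, 30, n)
        y = rng.uniform(-30, 30, n)
        tr = make_tracks({f"f{i}": ([0], [x[i]], [y[i]]) for i in range(n)})
        pi = preference_index(assign_quadrant(tr, geometry), geometry.odor_assignment)
        # rotate arena by 90 degrees and rotate the labels with it
        tr2 = make_tracks({f"f{i}": ([0], [-y[i]], [x[i]]) for i in range(n)})
        rotated_labels = {q: geometry.odor_assignment[(q - 1) % 4] for q in range(4)}
        geom2 = ArenaGeometry(odor_assignment=rotated_labels)
        pi2 = preference_index(assign_quadrant(tr2, geom2), rotated_labels)
        np.testing.assert_allclose(pi2["pi"], pi["pi"], atol=1e-12)


class TestMemoryScore:
    def _run(self, paired_count, unpaired_count, labels, geometry):
        sched = ProtocolSchedule("test_only", [Epoch("test", 0.0, 60.0, 0, "odor")])
        paired_q = next(q for q, v in labels.items() if v == "paired")
        unpaired_q = next(q for q, v in labels.items() if v == "unpaired")
        cohort = _static_cohort({paired_q: paired_count, unpaired_q: unpaired_count},
                                n_frames=int(60 * 30))
        return AssayRun(cohort, sched, labels)

    def test_reciprocal_mean(self, geometry):
        labels_a = geometry.odor_assignment
        labels_b = swap_odor_labels(labels_a)
        run_a = self._run(14, 6, labels_a, geometry)   # PI = +0.4
        run_b = self._run(12, 8, labels_b, geometry)   # PI = +0.2
        ms = memory_score([run_a, run_b], geometry)
        assert ms.score == pytest.approx(0.3)
        assert ms.run_scores == (pytest.approx(0.4), pytest.approx(0.2))
        assert not ms.single_run

    def test_single_run_flagged(self, geometry):
        ms = memory_score([self._run(14, 6, geometry.odor_assignment, geometry)], geometry)
        assert ms.single_run and ms.score == pytest.approx(0.4)

    def test_uses_last_30s_of_final_test(self, geometry):
        # flies sit in unpaired quadrants for the first 30 s, paired for the last 30 s
        sched = ProtocolSchedule("test_only", [Epoch("test", 0.0, 60.0, 0, "odor")])
        n = int(60 * 30)
        half = n // 2
        ang_un, ang_p = QUADRANT_CENTER_ANGLES[1], QUADRANT_CENTER_ANGLES[0]
        x = np.where(np.arange(n) < half, 25 * np.cos(ang_un), 25 * np.cos(ang_p))
        y = np.where(np.arange(n) < half, 25 * np.sin(ang_un), 25 * np.sin(ang_p))
        tr = make_tracks({"f": (np.arange(n), x, y)})
        ms = memory_score([AssayRun(tr, sched, geometry.odor_assignment)], geometry)
        assert ms.score == pytest.approx(1.0)


class TestLightPreference:
    def test_all_flies_in_lit_quadrants_gives_plus_one(self, geometry):
        sched = build_schedule("light_preference_v1")
        n = int(210 * 30)
        frames = np.arange(n)
        t = frames / 30.0
        # sit in quadrant 0 (lit in test 1), move to quadrant 1 (lit in test 2)
        in_second = t >= 150.0
        x = np.where(in_second, 25 * np.cos(QUADRANT_CENTER_ANGLES[1]),
                     25 * np.cos(QUADRANT_CENTER_ANGLES[0]))
        y = np.where(in_second, 25 * np.sin(QUADRANT_CENTER_ANGLES[1]),
                     25 * np.sin(QUADRANT_CENTER_ANGLES[0]))
        tr = make_tracks({"a": (frames, x, y), "b": (frames, x, y)})
        res = light_preference_index(tr, sched, geometry)
        assert res.score == pytest.approx(1.0)
        assert res.test_scores == (pytest.approx(1.0), pytest.approx(1.0))


class TestScreeningFilter:
    @pytest.mark.parametrize("score,flag", [(0.15, True), (-0.05, False), (0.1, False),
                                            (-0.3, True), (0.100001, True)])
    def test_strict_threshold(self, score, flag):
        assert screening_filter([score])[0] == flag
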