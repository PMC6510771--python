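import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, strategies as st

import watermaze as wm
from conftest import make_trajectory
from oracle_utils import oracle_indices

DATA = Path(__file__).parent / "data"

B = wm.Point(0.0, 50.0)
C0 = wm.Point(0.0, -50.0)


def step(c_n, c_next, b=B, c0=C0):
    return wm.StepGeometry(c_n=wm.Point(*c_n), c_next=wm.Point(*c_next), b=b, c0=c0)


class TestStepOperations:
    @pytest.mark.parametrize(
        "c_n,c_next,expected",
        [
            ((0, 0), (10, 0), 10.0),  # perpendicular to the route
            ((0, 0), (0, 10), 0.0),  # along the route
            ((0, 50), (10, 50), 0.0),  # from the platform centre itself
        ],
    )
    def test_lateral_deviation(self, c_n, c_next, expected):
        assert wm.lateral_deviation(step(c_n, c_next)) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "c_n,c_next,expected",
        [
            ((0, 0), (0, 10), 0.0),
            ((0, 0), (0, -10), 180.0),
            ((0, 0), (10, 0), 90.0),
            ((0, 0), (10, 10), 45.0),
        ],
    )
    def test_offset_angle(self, c_n, c_next, expected):
        assert wm.offset_angle(step(c_n, c_next)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "c_n,c_next,expected",
        [
            ((0, 0), (0, 10), 0.0),  # toward the platform: nothing to correct
            ((0, 0), (0, -10), 20.0),  # reversal: full 2L chord
            ((0, 0), (10, 0), 10.0 * math.sqrt(2)),  # right angle: L*sqrt(2)
        ],
    )
    def test_correction_length(self, c_n, c_next, expected):
        assert wm.correction_length(step(c_n, c_next)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "c_n,c_next,expected",
        [
            ((0, 0), (10, 0), 10.0),  # perpendicular to the entry route
            ((30, 0), (30, 10), 0.0),  # parallel to the entry route
            ((5, 5), (5, 5), 0.0),  # zero displacement
        ],
    )
    def test_initial_lateral_deviation(self, c_n, c_next, expected):
        assert wm.initial_lateral_deviation(step(c_n, c_next)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_entry_on_platform_is_invalid(self):
        bad = wm.StepGeometry(c_n=wm.Point(0, 0), c_next=wm.Point(1, 0), b=B, c0=B)
        with pytest.raises(ValueError):
            wm.initial_lateral_deviation(bad)

    def test_degenerate_step_angle_conventions(self):
        still = step((3, 3), (3, 3))
        assert wm.offset_angle(still) == 0.0
        assert wm.offset_angle(still, strict=True) == 90.0
        assert wm.correction_length(still) == 0.0
        assert wm.correction_length(still, strict=True) == 0.0
        on_platform = step((0, 50), (10, 50))
        assert wm.offset_angle(on_platform) == 0.0
        assert wm.offset_angle(on_platform, strict=True) == 90.0
        assert wm.correction_length(on_platform) == 0.0


coords = st.floats(-70, 70, allow_nan=False)
points = st.tuples(coords, coords)


class TestStepProperties:
    @given(points, points, points)
    def test_bounds_and_dominance(self, c_n, c_next, b):
        s = wm.StepGeometry(c_n=wm.Point(*c_n), c_next=wm.Point(*c_next), b=wm.Point(*b), c0=C0)
        length = s.step_length
        lat = wm.lateral_deviation(s)
        ang = wm.offset_angle(s)
        corr = wm.correction_length(s)
        ild = wm.initial_lateral_deviation(s)
        assert 0 <= ang <= 180
        assert lat <= length * (1 + 1e-9) + 1e-12
        assert ild <= length * (1 + 1e-9) + 1e-12
        assert corr <= 2 * length * (1 + 1e-9) + 1e-12
        assert corr >= lat - 1e-9 * max(1.0, length)

    @given(points, points, st.floats(0.1, 5.0))
    def test_scaling_step(self, c_n, c_next, k):
        s = wm.StepGeometry(c_n=wm.Point(*c_n), c_next=wm.Point(*c_next), b=B, c0=C0)
        scaled = wm.StepGeometry(
            c_n=wm.Point(c_n[0] * k, c_n[1] * k),
            c_next=wm.Point(c_next[0] * k, c_next[1] * k),
            b=wm.Point(B.x * k, B.y * k),
            c0=wm.Point(C0.x * k, C0.y * k),
        )
        assert wm.lateral_deviation(scaled) == pytest.approx(k * wm.lateral_deviation(s), abs=1e-9)
        assert wm.offset_angle(scaled) == pytest.approx(wm.offset_angle(s), abs=1e-6)


class TestComputeIndices:
    def test_straight_path_has_zero_deviation(self, arena):
        pts = [(0.0, -50.0 + 4.0 * i) for i in range(30)]  # 20 cm/s straight north
        traj = make_trajectory(pts, dt=0.2)
        res = wm.compute_indices(traj, arena)
        assert res.escaped
        assert res.index1_cm == pytest.approx(0.0, abs=1e-9)
        assert res.index2_deg == pytest.approx(0.0, abs=1e-9)
        assert res.index3_cm == pytest.approx(0.0, abs=1e-9)
        assert res.index4_cm == pytest.approx(0.0, abs=1e-9)
        # contact at distance 45 from entry -> 95 cm of the 116 cm line
        assert res.path_length_cm == pytest.approx(res.escape_latency_s * 20.0, rel=1e-9)

    def test_non_finder_covers_exactly_the_capped_trial(self, arena):
        angles = np.linspace(0, 4 * np.pi, 400)
        pts = np.column_stack([30 * np.cos(angles), -30 + 10 * np.sin(angles)])
        traj = make_trajectory(pts, dt=0.2)  # 79.8 s of wandering, never north
        res = wm.compute_indices(traj, arena, unit_time_s=0.2)
        assert not res.escaped
        assert res.escape_latency_s == 60.0
        assert res.n_steps == 300  # 60 s x 5 Hz

    def test_zigzag_fixture_matches_frozen_oracle_values(self, arena):
        traj = wm.read_trajectory_csv(str(DATA / "zigzag.csv"), arena)
        res = wm.compute_indices(traj, arena)
        # golden values computed with the brute-force per-step oracle
        assert res.index1_cm == pytest.approx(153.98995973496562, rel=1e-9)
        assert res.index2_deg == pytest.approx(2103.881413976749, rel=1e-9)
        assert res.index3_cm == pytest.approx(299.48738854672337, rel=1e-9)
        assert res.index4_cm == pytest.approx(169.2057570985518, rel=1e-9)
        assert not res.escaped and res.escape_latency_s == 60.0

    def test_matches_oracle_with_escape_truncation(self, arena):
        rng = np.random.default_rng(21)
        # biased walk that reaches the platform partway through the recording
        pts = [np.array([0.0, -50.0])]
        for _ in range(200):
            drift = np.array([0.0, 50.0]) - pts[-1]
            drift = drift / np.linalg.norm(drift)
            pts.append(pts[-1] + 3.0 * drift + rng.normal(0, 2.0, 2))
        traj = make_trajectory(np.array(pts), dt=0.2)
        res = wm.compute_indices(traj, arena, resample=False)
        ref = oracle_indices(traj.t, traj.xy, arena.platform_center, 5.0, 60.0)
        assert res.escaped == ref["escaped"]
        assert res.n_steps == ref["n_steps"]
        for key in ("index1_cm", "index2_deg", "index3_cm", "index4_cm"):
            assert getattr(res, key) == pytest.approx(ref[key], rel=1e-9)

    def test_strict_angle_mode_scores_floats_as_90(self, arena):
        pts = [(0, -50), (0, -46), (0, -46), (0, -42)]  # one stationary step
        traj = make_trajectory(pts, dt=0.2)
        default = wm.compute_indices(traj, arena, resample=False)
        strict = wm.compute_indices(traj, arena, resample=False, strict_angles=True)
        assert default.index2_deg == pytest.approx(0.0, abs=1e-9)
        assert strict.index2_deg == pytest.approx(90.0, abs=1e-9)
        assert strict.index1_cm == default.index1_cm
        assert strict.index3_cm == default.index3_cm

    def test_dominance_holds_per_trial(self, arena):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 3, (60, 2)), axis=0)
            traj = make_trajectory(pts, dt=0.2)
            res = wm.compute_indices(traj, arena, resample=False)
            assert res.index3_cm >= res.index1_cm - 1e-9
            assert res.index1_cm <= res.path_length_cm + 1e-9
            assert res.index4_cm <= res.path_length_cm + 1e-9

    def test_indices_table_columns(self, arena):
        traj = make_trajectory([(0, -50 + 4 * i) for i in range(30)], dt=0.2)
        df = wm.indices_table([wm.compute_indices(traj, arena)])
        assert list(df.columns) == list(wm.INDEX_COLUMNS)
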