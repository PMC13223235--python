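"""Zone occupancy, corner distances, freezing scores, habituation series."""

import numpy as np
import pandas as pd
import pytest

import feargen as fg
from feargen import arena
from feargen._exceptions import ValidationError


def traj_from(points, arena_size=(18.0, 18.0)):
    t, x, y = zip(*points)
    return fg.Trajectory(t=np.array(t), x=np.array(x), y=np.array(y),
                         arena=arena_size)


class TestTimeInZones:
    def test_stationary_center(self):
        tr = traj_from([(0, 9, 9), (10, 9, 9), (20, 9, 9)])
        occ = fg.time_in_zones(tr)
        assert occ.fractions[4] == pytest.approx(1.0)
        assert occ.labels[4] == "center"

    def test_two_equal_intervals_split_evenly(self):
        tr = traj_from([(0, 1, 1), (1, 9, 9), (2, 9, 9)])
        occ = fg.time_in_zones(tr)
        assert occ.fractions[arena.zone_index(1, 1)] == pytest.approx(0.5)
        assert occ.fractions[4] == pytest.approx(0.5)

    def test_fractions_sum_to_one_and_rescale_invariant(self, rng):
        n = 500
        t = np.arange(n, dtype=float)
        x, y = rng.uniform(0, 18, n), rng.uniform(0, 18, n)
        occ = fg.time_in_zones(fg.Trajectory(t=t, x=x, y=y))
        assert occ.fractions.sum() == pytest.approx(1.0)
        scaled = fg.Trajectory(t=t, x=x * 3, y=y * 3, arena=(54.0, 54.0))
        np.testing.assert_allclose(fg.time_in_zones(scaled).fractions,
                                   occ.fractions)

    def test_long_uniform_walk_near_uniform(self):
        params = fg.OccupancyModelParams.make("no_fear")
        tr = fg.generate_trajectory(params, duration=2000, seed=12)
        np.testing.assert_allclose(fg.time_in_zones(tr).fractions,
                                   np.full(9, 1 / 9), atol=0.035)

    def test_out_of_bounds_rejected_with_indices(self):
        with pytest.raises(ValidationError, match=r"\[1\]"):
            fg.Trajectory(t=[0.0, 1.0], x=[1.0, 19.0], y=[1.0, 1.0])

    def test_matches_per_sample_oracle(self, rng):
        n = 300
        t = np.cumsum(rng.uniform(0.01, 0.1, n))
        x, y = rng.uniform(0, 18, n), rng.uniform(0, 18, n)
        occ = fg.time_in_zones(fg.Trajectory(t=t, x=x, y=y))
        brute = np.zeros(9)
        for i in range(n - 1):
            brute[arena.zone_index(x[i], y[i])] += t[i + 1] - t[i]
        np.testing.assert_allclose(occ.dwell_s, brute)


class TestCornerDistance:
    def test_stationary_at_mv_corner(self):
        tr = traj_from([(0, 0, 0), (1, 0, 0)])
        d = fg.mean_corner_distance(tr)
        assert d["MV"] == pytest.approx(0.0)
        assert d["HEX"] == pytest.approx(np.hypot(18, 18))

    def test_center_equidistant(self):
        tr = traj_from([(0, 9, 9), (1, 9, 9)])
        d = fg.mean_corner_distance(tr)
        assert d.std() == pytest.approx(0.0)

    def test_matches_per_sample_oracle(self, rng):
        n = 200
        t = np.cumsum(rng.uniform(0.01, 0.2, n))
        x, y = rng.uniform(0, 18, n), rng.uniform(0, 18, n)
        tr = fg.Trajectory(t=t, x=x, y=y)
        d = fg.mean_corner_distance(tr)
        dt = np.diff(t)
        w = dt / dt.sum()
        for odor, frac in tr.corner_odors.items():
            cx, cy = frac[0] * 18, frac[1] * 18
            brute = float(np.sum(np.hypot(x[:-1] - cx, y[:-1] - cy) * w))
            assert d[odor] == pytest.approx(brute)


def _session(speed_profile, rate=25.0):
    """Build a 125-s session table with a given per-interval speed profile:
    list of (duration_s, speed)."""
    t, x = [0.0], [0.0]
    pos = 0.0
    for dur, sp in speed_profile:
        steps = int(dur * rate)
        for _ in range(steps):
            pos += sp / rate
            t.append(t[-1] + 1.0 / rate)
            x.append(pos)
    return pd.DataFrame({"time_s": t, "x": x, "y": np.zeros(len(t))})


class TestImmobility:
    def test_total_stillness_is_100(self):
        rec = fg.immobility_percent({"MV": _session([(125, 0.0)])})
        assert rec.immobility_pct["MV"] == pytest.approx(100.0)

    def test_continuous_fast_movement_is_0(self):
        rec = fg.immobility_percent({"MV": _session([(125, 10.0)])})
        assert rec.immobility_pct["MV"] == pytest.approx(0.0)

    def test_first_30s_excluded_from_scoring(self):
        rec = fg.immobility_percent({"MV": _session([(30, 10.0), (95, 0.0)])})
        assert rec.immobility_pct["MV"] == pytest.approx(100.0)

    def test_short_bouts_do_not_count(self):
        profile = []
        for _ in range(63):  # alternate 0.5-s still / 1.5-s moving
            profile += [(0.5, 0.0), (1.5, 10.0)]
        rec = fg.immobility_percent({"MV": _session(profile)},
                                    min_still_duration=1.0)
        assert rec.immobility_pct["MV"] == pytest.approx(0.0)

    def test_anti_monotone_in_speed_threshold(self, rng):
        n = 125 * 25
        t = np.arange(n + 1) / 25.0
        speeds = rng.uniform(0, 4, n)
        df = pd.DataFrame({"time_s": t, "speed": np.r_[speeds, 0.0]})
        hi = fg.immobility_percent({"MV": df}, speed_threshold=2.0)
        lo = fg.immobility_percent({"MV": df}, speed_threshold=1.0)
        assert lo.immobility_pct["MV"] <= hi.immobility_pct["MV"]

    def test_short_session_raises(self):
        with pytest.raises(ValidationError):
            fg.immobility_percent({"MV": _session([(60, 0.0)])})


class TestExclusionRule:
    @pytest.mark.parametrize("mv,ba,hex_,expected", [
        (40, 30, 20, True),   # clear gradient: retained
        (40, 38, 20, False),  # 2-point CS+ margin: excluded
        (35, 30, 20, True),   # exactly 5 points: retained ("at least")
    ])
    def test_rule(self, mv, ba, hex_, expected):
        rec = fg.FreezingRecord({"MV": mv, "BA": ba, "HEX": hex_})
        assert fg.exclusion_check(rec, "MV") is expected

    def test_missing_cs_plus_raises(self):
        with pytest.raises(ValidationError):
            fg.exclusion_check(fg.FreezingRecord({"BA": 10.0}), "MV")


class TestHabituation:
    ORDER = ("MV", "BA", "HEX")

    def test_flat_series_zero_contrasts(self):
        series = fg.InvestigationSeries(np.full(14, 10.0))
        out = fg.habituation_summary(series, self.ORDER)
        deltas = out["dishabituation_delta"].dropna()
        assert (deltas == 0).all()
        assert len(deltas) == 3  # two odor switches + final return

    def test_decay_with_switch_rebound_is_positive(self):
        v = [20.0]
        for _ in range(3):
            v += [18, 14, 10, 6]
        v += [17]
        out = fg.habituation_summary(fg.InvestigationSeries(v), self.ORDER)
        assert (out["dishabituation_delta"].dropna() > 0).all()

    def test_configured_decay_model_recovered(self, rng):
        # exponential within-odor habituation plus switch reset
        base, tau = 20.0, 1.8
        v = [12.0]
        for _ in range(3):
            v += [base * np.exp(-k / tau) + rng.normal(0, 0.2) for k in range(4)]
        v += [base + rng.normal(0, 0.2)]
        out = fg.habituation_summary(
            fg.InvestigationSeries(np.clip(v, 0, 50)), self.ORDER)
        hab = out[out["position"] > 0]
        means = hab.groupby("position")["investigation_s"].mean()
        assert means.is_monotonic_decreasing

    def test_wrong_length_raises(self):
        with pytest.raises(ValidationError):
            fg.InvestigationSeries(np.zeros(13))


class TestZoneDifferenceMap:
    def _occ(self, fractions):
        return fg.ZoneOccupancy(np.asarray(fractions, float) * 300.0,
                                labels=arena.zone_labels())

    def test_identical_inputs_zero(self):
        occ = self._occ(np.full(9, 1 / 9))
        np.testing.assert_allclose(fg.zone_time_difference_map(occ, occ),
                                   np.zeros(9))

    def test_concentrated_vs_uniform(self):
        cond = self._occ([1.0] + [0.0] * 8)
        ctrl = self._occ(np.full(9, 1 / 9))
        diff = fg.zone_time_difference_map(cond, ctrl)
        assert diff[0] == pytest.approx(100 - 100 / 9)
        np.testing.assert_allclose(diff[1:], np.full(8, -100 / 9))

    def test_elementwise_oracle(self, rng):
        a = rng.dirichlet(np.ones(9))
        b = rng.dirichlet(np.ones(9))
        diff = fg.zone_time_difference_map(self._occ(a), self._occ(b))
        np.testing.assert_allclose(diff, 100 * (a - b))

    def test_partition_mismatch_raises(self):
        occ = self._occ(np.full(9, 1 / 9))
        other = fg.ZoneOccupancy(np.full(9, 1.0), labels=["z"] * 9)
        with pytest.raises(ValidationError):
            fg.zone_time_difference_map(occ, other)
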