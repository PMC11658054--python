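"""Rayleigh statistics, orientation sampling geometry, attraction, mobility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from queenrelay.contact_geometry import GeometryConfig, nearest_point_bearing
from queenrelay.orientation_response import (
    angular_transect,
    collect_orientation_samples,
    difference_map,
    mobility_prepost,
    queen_attraction_test,
    rayleigh_rho,
)

from conftest import make_contacts

TWO_PI = 2 * np.pi


class TestRayleighRho:
    def test_perfect_alignment_gives_one(self):
        mu = np.linspace(0, TWO_PI, 100, endpoint=False)
        assert np.isclose(rayleigh_rho(mu, mu), 1.0)

    def test_facing_away_gives_minus_one(self):
        mu = np.linspace(0, TWO_PI, 50, endpoint=False)
        assert np.isclose(rayleigh_rho(mu + np.pi, mu), -1.0)

    def test_orthogonal_quartet_cancels(self):
        mu = np.zeros(4)
        theta = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert np.isclose(rayleigh_rho(theta, mu), 0.0, atol=1e-12)

    def test_empty_input_missing(self):
        assert np.isnan(rayleigh_rho(np.array([]), np.array([])))

    @settings(max_examples=50, deadline=None)
    @given(
        hnp.arrays(float, st.integers(1, 60),
                   elements=st.floats(0, TWO_PI - 1e-9)),
    )
    def test_equals_brute_force_mean_cosine(self, theta):
        mu = np.roll(theta, 1)
        brute = sum(np.cos(t - m) for t, m in zip(theta, mu)) / len(theta)
        assert np.isclose(rayleigh_rho(theta, mu), brute, atol=1e-12)
        assert -1.0 <= rayleigh_rho(theta, mu) <= 1.0


def scene_traj(frames):
    """frames: list of (bee, t, x, y, heading, side)."""
    return pd.DataFrame(
        [{"bee_id": b, "time_s": t, "x": x, "y": y, "heading_rad": h, "side": s}
         for b, t, x, y, h, s in frames]
    )


class TestOrientationSamples:
    def queen_contact(self):
        return make_contacts([("queen", "m", 10.0, 12.0, 0.0, 1.0)])

    def test_neighbour_beyond_radius_excluded(self):
        frames = [
            ("m", 13.0, 0.0, 0.0, 0.0, 0),
            ("r", 13.0, 2.5, 0.0, 0.0, 0),
        ]
        s = collect_orientation_samples(self.queen_contact(), scene_traj(frames),
                                        window=5.0)
        assert s.empty

    def test_rotation_into_messenger_frame(self):
        # messenger heading +y; receiver due north maps onto +x axis
        frames = [
            ("m", 13.0, 0.0, 0.0, np.pi / 2, 0),
            ("r", 13.0, 0.0, 1.5, np.pi / 2, 0),
        ]
        s = collect_orientation_samples(self.queen_contact(), scene_traj(frames),
                                        window=5.0)
        assert len(s) == 1
        assert np.isclose(s.iloc[0]["x_rel"], 1.5)
        assert np.isclose(s.iloc[0]["y_rel"], 0.0, atol=1e-9)
        assert np.isclose(s.iloc[0]["theta"], 0.0)

    def test_mu_matches_hand_computed_nearest_point(self):
        # messenger at origin heading 0; receiver ahead on the axis at
        # 1.5 BL: nearest trapezium point is the head-edge centre (0.5, 0)
        frames = [
            ("m", 13.0, 0.0, 0.0, 0.0, 0),
            ("r", 13.0, 1.5, 0.0, 0.0, 0),
        ]
        s = collect_orientation_samples(self.queen_contact(), scene_traj(frames),
                                        window=5.0)
        mu_world = nearest_point_bearing(1.5, 0.0, 0.0, 0.0, 0.0, "worker")
        assert np.isclose(mu_world, np.pi)          # points back at the head
        assert np.isclose(s.iloc[0]["mu"], np.pi)

    def test_queen_never_a_receiver(self):
        frames = [
            ("m", 13.0, 0.0, 0.0, 0.0, 0),
            ("queen", 13.0, 1.0, 0.0, 0.0, 0),
        ]
        s = collect_orientation_samples(self.queen_contact(), scene_traj(frames),
                                        window=5.0)
        assert s.empty

    def test_pre_and_post_phases_signed(self):
        frames = []
        for t in (8.0, 13.0):  # one pre frame, one post frame
            frames += [("m", t, 0.0, 0.0, 0.0, 0), ("r", t, 1.0, 0.0, 0.0, 0)]
        s = collect_orientation_samples(self.queen_contact(), scene_traj(frames),
                                        window=5.0)
        assert set(np.sign(s["t_rel_s"])) == {-1.0, 1.0}


def planted_samples(rng, n=4000, attracted=False, t_sign=1.0):
    """Receiver samples around a messenger; optionally facing it."""
    r = rng.uniform(0.3, 2.0, n)
    ang = rng.uniform(0, TWO_PI, n)
    x = r * np.cos(ang)
    y = r * np.sin(ang)
    mu = np.mod(np.arctan2(-y, -x), TWO_PI)  # roughly toward the messenger
    if attracted:
        theta = np.mod(mu + rng.vonmises(0, 4.0, n), TWO_PI)
    else:
        theta = rng.uniform(0, TWO_PI, n)
    return pd.DataFrame(
        {
            "messenger": "m", "receiver": "r",
            "t_rel_s": t_sign * rng.uniform(1.0, 59.0, n),
            "x_rel": x, "y_rel": y, "theta": theta, "mu": mu,
            "load": np.nan, "load_decile": np.nan,
        }
    )


class TestDifferenceMaps:
    def test_identical_strata_give_zero_map(self):
        rng = np.random.default_rng(0)
        post = planted_samples(rng, attracted=True, t_sign=1.0)
        pre = post.copy()
        pre["t_rel_s"] *= -1
        s = pd.concat([post, pre])
        m = difference_map(s, "time", k=1, min_count=5)
        vals = m.drho[~np.isnan(m.drho)]
        assert len(vals)
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_swapped_strata_negate_the_map(self):
        rng = np.random.default_rng(1)
        post = planted_samples(rng, attracted=True, t_sign=1.0)
        pre = planted_samples(rng, attracted=False, t_sign=-1.0)
        s = pd.concat([post, pre])
        m1 = difference_map(s, "time", k=1, min_count=5)
        swapped = s.copy()
        swapped["t_rel_s"] *= -1
        m2 = difference_map(swapped, "time", k=1, min_count=5)
        both = ~np.isnan(m1.drho) & ~np.isnan(m2.drho)
        assert np.allclose(m1.drho[both], -m2.drho[both], atol=1e-12)

    def test_planted_post_attraction_yields_positive_signal(self):
        rng = np.random.default_rng(2)
        post = planted_samples(rng, attracted=True, t_sign=1.0)
        pre = planted_samples(rng, attracted=False, t_sign=-1.0)
        s = pd.concat([post, pre])
        m = difference_map(s, "time", k=1, min_count=10)
        vals = m.drho[~np.isnan(m.drho)]
        assert np.nanmean(vals) > 0.3

    def test_mask_respects_min_count(self):
        rng = np.random.default_rng(3)
        s = pd.concat([planted_samples(rng, n=50, t_sign=1.0),
                       planted_samples(rng, n=50, t_sign=-1.0)])
        m = difference_map(s, "time", k=1, min_count=10_000)
        assert np.isnan(m.drho).all()

    def test_transect_zero_for_identical_strata_and_counts_add_up(self):
        rng = np.random.default_rng(4)
        post = planted_samples(rng, attracted=True, t_sign=1.0)
        pre = post.copy()
        pre["t_rel_s"] *= -1
        s = pd.concat([post, pre])
        tr = angular_transect(s, "time", k=1, min_count=1)
        assert np.allclose(tr["drho"].dropna(), 0.0, atol=1e-12)
        assert tr["n_stratum"].sum() == len(post)

    def test_transect_front_signal_with_planted_effect(self):
        rng = np.random.default_rng(5)
        post = planted_samples(rng, attracted=True, t_sign=1.0)
        pre = planted_samples(rng, attracted=False, t_sign=-1.0)
        tr = angular_transect(pd.concat([post, pre]), "time", k=1, min_count=10)
        assert np.nanmean(tr["drho"]) > 0.3


def uniform_traj(seed, n=4000, W=40.0, H=28.0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {"bee_id": "b", "time_s": np.arange(n) * 0.5,
         "x": rng.uniform(0, W, n), "y": rng.uniform(0, H, n),
         "heading_rad": 0.0, "side": 0}
    )


class TestQueenAttraction:
    def test_null_calibration_under_independence(self):
        """With worker and queen positions independent, significance at
        alpha=0.05 arises in about 5% of replicates."""
        rej = 0
        n_seeds = 120
        for s in range(n_seeds):
            r = queen_attraction_test(
                uniform_traj(2 * s), uniform_traj(2 * s + 1),
                subsample_s=0.5, seed=s,
            )
            rej += r["p"] < 0.05
        rate = rej / n_seeds
        assert rate < 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_glued_worker_strongly_significant_negative_effect(self):
        rng = np.random.default_rng(99)
        n = 4000
        q = uniform_traj(1, n=n)
        w = q.copy()
        w["x"] = np.clip(q["x"] + rng.normal(0.5, 0.1, n), 0, 40)
        r = queen_attraction_test(w, q, subsample_s=0.5, seed=0)
        assert r["p"] < 1e-10
        assert r["effect_bl"] < 0

    def test_time_shuffle_destroys_significance(self):
        q = uniform_traj(1)
        w = q.copy()
        w["x"] = np.clip(q["x"] + 0.5, 0, 40)
        shuffled = w.copy()
        shuffled[["x", "y"]] = w[["x", "y"]].sample(frac=1, random_state=7).to_numpy()
        r = queen_attraction_test(shuffled, q, subsample_s=0.5, seed=0)
        assert r["p"] > 0.01

    def test_too_few_frames_missing(self):
        r = queen_attraction_test(uniform_traj(0, n=50), uniform_traj(1, n=50))
        assert np.isnan(r["p"])

    def test_stationary_windows_restrict_queen_frames(self):
        q = uniform_traj(1)
        w = uniform_traj(2)
        r = queen_attraction_test(w, q, stationary_windows=[(0.0, 10.0)])
        assert np.isnan(r["p"])  # only 21 simultaneous frames remain


class TestMobility:
    def test_stationary_workers_zero_difference(self):
        frames = []
        for t in np.arange(0, 200, 0.5):
            frames.append(("w", t, 5.0, 5.0, 0.0, 0))
            frames.append(("queen", t, 1.0, 1.0, 0.0, 0))
        traj = scene_traj(frames)
        qc = make_contacts([("queen", "w", 90.0, 110.0, 0.0, 1.0)])
        out = mobility_prepost(qc, traj, window=60.0)
        assert np.allclose(out["speed_diff"].dropna(), 0.0)
        assert np.allclose(out["switch_rate_diff"].dropna(), 0.0)

    def test_planted_speed_boost_confined_to_boost_window(self):
        rng = np.random.default_rng(0)
        rows = []
        t_grid = np.arange(0.0, 400.0, 0.5)
        x = 0.0
        for t in t_grid:
            base = 0.1
            if 200.0 < t <= 260.0:   # 60 s boost after the contact ends
                base = 0.5
            x += base
            rows.append(("w", t, x % 300, 5.0, 0.0, 0))
            rows.append(("queen", t, 1.0, 1.0, 0.0, 0))
        traj = scene_traj(rows)
        qc = make_contacts([("queen", "w", 190.0, 200.0, 0.0, 1.0)])
        out = mobility_prepost(qc, traj, window=120.0)
        early = out[out["t_abs_s"] <= 55.0]["speed_diff"].mean()
        late = out[out["t_abs_s"] > 65.0]["speed_diff"].mean()
        assert early > 0.5   # boosted: +0.4 BL/frame = +0.8 BL/s
        assert abs(late) < 0.1

    def test_side_switch_rate_within_bounds(self, study_colony):
        out = mobility_prepost(
            study_colony.queen_contacts.head(20), study_colony.traj, window=60.0
        )
        for col in ("switch_rate_pre_mean", "switch_rate_post_mean"):
            v = out[col].dropna()
            assert ((v >= 0) & (v <= 2.0)).all()
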