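"""Seeded synthetic honeybee colonies for testing the relay pipeline.

The generator emulates the statistical structure of a double-sided
observation-hive tracking dataset: a single queen that alternates between a
slow/tortuous "stationary" state and a fast/straight "travelling" state
(two-state Markov chain with gamma step lengths and von Mises turn angles),
plus age-structured workers introduced in staggered cohorts whose movement
mixes broodnest fidelity, queen attraction and (for older bees) a drift
toward the entrance corner.  Each comb side carries one broodnest patch.

All spatial units are worker body-lengths (BL); time is seconds from
midnight on a regular frame grid (default 2 frames/s).  Every stochastic
choice derives from the colony seed, so identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "QueenStateParams",
    "WorkerAgeProfiles",
    "ColonyConfig",
    "GroundTruth",
    "simulate_queen_trajectory",
    "simulate_worker_population",
    "generate_colony_day",
    "write_dataset",
    "read_dataset",
]

TWO_PI = 2 * np.pi


@dataclass(frozen=True)
class QueenStateParams:
    """Two-state movement model of the queen.

    Step lengths are in BL/frame; ``switch`` is the per-frame state
    transition matrix with rows (from-state) summing to 1.  State 0 is
    stationary (S), state 1 travelling (T).  Defaults give mean dwell times
    of 60 s (S) and 40 s (T) at 2 frames/s, i.e. a 60% stationary share.
    """

    step_mean: tuple[float, float] = (0.04, 0.45)
    step_sd: tuple[float, float] = (0.04, 0.22)
    turn_kappa: tuple[float, float] = (0.4, 6.0)
    switch: tuple[tuple[float, float], tuple[float, float]] = (
        (1 - 1 / 120.0, 1 / 120.0),
        (1 / 80.0, 1 - 1 / 80.0),
    )

    def validate(self) -> None:
        sw = np.asarray(self.switch, dtype=float)
        if sw.shape != (2, 2) or np.any(sw < 0) or not np.allclose(sw.sum(axis=1), 1.0):
            raise ValueError("switch must be a 2x2 stochastic matrix")
        if any(m <= 0 for m in self.step_mean) or any(s <= 0 for s in self.step_sd):
            raise ValueError("step parameters must be positive")

    def stationary_distribution(self) -> np.ndarray:
        """Long-run occupancy of (S, T) for the configured chain."""
        sw = np.asarray(self.switch, dtype=float)
        p01, p10 = sw[0, 1], sw[1, 0]
        if p01 + p10 == 0:
            return np.array([0.5, 0.5])
        return np.array([p10, p01]) / (p01 + p10)


def _default_attraction(age: np.ndarray) -> np.ndarray:
    # queen attraction rises from eclosion, peaks at 3-4 d, then declines
    return np.exp(-0.5 * ((np.asarray(age, dtype=float) - 3.5) / 2.0) ** 2)


def _default_mobility(age: np.ndarray) -> np.ndarray:
    # mean step length (BL/frame) grows with age toward a forager plateau
    return 0.08 + 0.22 * (1 - np.exp(-np.asarray(age, dtype=float) / 5.0))


def _default_fidelity(age: np.ndarray) -> np.ndarray:
    # broodnest fidelity decays with age; mid-age workers roam widely
    return np.exp(-np.asarray(age, dtype=float) / 5.0)


@dataclass(frozen=True)
class WorkerAgeProfiles:
    """Age-indexed behavioural profiles of workers (ages in days)."""

    attraction: Callable[[np.ndarray], np.ndarray] = _default_attraction
    mobility: Callable[[np.ndarray], np.ndarray] = _default_mobility
    fidelity: Callable[[np.ndarray], np.ndarray] = _default_fidelity
    forager_transition_age: float = 10.0
    attraction_weight: float = 1.0
    #: queen attraction only acts within this sensing range (BL); the
    #: pheromone is non-volatile, so workers must be near to respond
    attraction_radius: float = 5.0
    #: per-frame probability (scaled by the age attraction curve) of
    #: joining the retinue when the queen is in sensing range
    engage_prob: float = 0.03
    #: time spent inspecting the queen once engaged (court residence)
    engage_duration_s: float = 60.0
    #: post-retinue refractory period before a worker re-engages
    refractory_s: float = 300.0
    #: drift weight of foragers toward the entrance corner
    entrance_weight: float = 0.5
    #: forager patrol excursions: mean rest / patrol episode lengths
    patrol_rest_s: float = 120.0
    patrol_duration_s: float = 90.0
    #: post-queen-contact excitation: speed multiplier and its duration
    #: (post-retinue bees run faster and straighter for minutes)
    excitation_boost: float = 1.8
    excitation_duration_s: float = 120.0


@dataclass(frozen=True)
class ColonyConfig:
    """Full configuration of one synthetic colony."""

    n_days: int = 7
    frame_rate: float = 2.0
    comb_width: float = 64.0
    comb_height: float = 44.0
    #: (introduction_day, cohort_size); the study design introduced eight
    #: cohorts of 290 newly-eclosed workers at three-day intervals
    cohort_schedule: tuple[tuple[int, int], ...] = tuple(
        (3 * k, 290) for k in range(8)
    )
    queen: QueenStateParams = field(default_factory=QueenStateParams)
    workers: WorkerAgeProfiles = field(default_factory=WorkerAgeProfiles)
    #: one broodnest patch per comb side
    broodnest_centres: tuple[tuple[float, float, int], ...] = (
        (21.0, 22.0, 0),
        (21.0, 22.0, 1),
    )
    broodnest_radius: float = 10.0
    #: the queen drifts back toward the broodnest when further than this
    queen_tether_radius: float = 16.0
    side_switch_prob: float = 0.005
    day_length_s: float = 86400.0
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.comb_width <= 0 or self.comb_height <= 0:
            raise ValueError("rates and sizes must be positive")
        self.queen.validate()

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def n_frames(self) -> int:
        return int(round(self.day_length_s * self.frame_rate))

    def entrance_corner(self) -> tuple[float, float]:
        return (self.comb_width, 0.0)

    def workers_present(self, day: int) -> pd.DataFrame:
        """Metadata of workers introduced on or before ``day``."""
        rows = []
        for c, (d0, size) in enumerate(self.cohort_schedule):
            if d0 > day:
                continue
            for k in range(size):
                rows.append(
                    {"bee_id": f"w{c:02d}_{k:03d}", "cohort": c,
                     "eclosion_day": d0, "age": day - d0,
                     # cohorts split across the two broodnest patches
                     "patch_side": k % 2}
                )
        return pd.DataFrame(
            rows,
            columns=["bee_id", "cohort", "eclosion_day", "age", "patch_side"],
        )


@dataclass
class GroundTruth:
    """Generating truth for one colony-day: queen states, worker labels."""

    queen_states: pd.DataFrame  # time_s, queen_state in {S, T}
    workers: pd.DataFrame       # bee_id, community in {N_A, N_B, F}, age, cohort


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi)


def _rng_for(config: ColonyConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def simulate_queen_trajectory(
    config: ColonyConfig, day: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one day of queen movement.

    Returns the trajectory table and the hidden state sequence (0=S, 1=T).
    The queen performs a correlated random walk with gamma step lengths and
    von Mises turn angles whose parameters switch with the hidden two-state
    Markov chain.
    """
    config.validate()
    qp = config.queen
    rng = _rng_for(config, 0, day)
    n = config.n_frames()
    sw = np.asarray(qp.switch, dtype=float)

    # hidden chain started from its stationary distribution
    pi = qp.stationary_distribution()
    states = np.empty(n, dtype=np.int8)
    states[0] = rng.choice(2, p=pi)
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = 1 - states[t - 1] if u[t - 1] < sw[states[t - 1], 1 - states[t - 1]] else states[t - 1]

    shapes = np.empty(n)
    scales = np.empty(n)
    kappas = np.empty(n)
    for s in (0, 1):
        sh, sc = _gamma_params(qp.step_mean[s], qp.step_sd[s])
        m = states == s
        shapes[m], scales[m], kappas[m] = sh, sc, qp.turn_kappa[s]
    steps = rng.gamma(shapes, scales)
    turns = rng.vonmises(0.0, kappas)

    heading = np.empty(n)
    heading[0] = rng.uniform(0, TWO_PI)
    heading[1:] = np.mod(heading[0] + np.cumsum(turns[1:]), TWO_PI)
    x = np.empty(n)
    y = np.empty(n)
    cx, cy, _ = config.broodnest_centres[0]
    x[0], y[0] = cx, cy
    for t in range(1, n):
        # soft tether to the broodnest: queens stay on the brood
        d_nest = np.hypot(x[t - 1] - cx, y[t - 1] - cy)
        if d_nest > config.queen_tether_radius:
            back = np.arctan2(cy - y[t - 1], cx - x[t - 1])
            heading[t:] = np.mod(heading[t:] + (back - heading[t]), TWO_PI)
        x[t] = x[t - 1] + steps[t] * np.cos(heading[t])
        y[t] = y[t - 1] + steps[t] * np.sin(heading[t])
        if not (0 <= x[t] <= config.comb_width):
            x[t] = min(max(x[t], 0.0), config.comb_width)
            heading[t] = np.mod(np.pi - heading[t], TWO_PI)
        if not (0 <= y[t] <= config.comb_height):
            y[t] = min(max(y[t], 0.0), config.comb_height)
            heading[t] = np.mod(-heading[t], TWO_PI)

    # rare side changes when close to the comb boundary
    side = np.empty(n, dtype=np.int8)
    side[0] = 0
    near_edge = (
        (x < 1.0) | (x > config.comb_width - 1.0)
        | (y < 1.0) | (y > config.comb_height - 1.0)
    )
    flips = near_edge & (rng.random(n) < config.side_switch_prob)
    side = np.mod(np.cumsum(flips) + side[0], 2).astype(np.int8)

    t_s = np.round(np.arange(n) * config.dt, 6)
    traj = pd.DataFrame(
        {"bee_id": "queen", "time_s": t_s, "x": x, "y": y,
         "heading_rad": heading, "side": side}
    )
    return traj, states


def simulate_worker_population(
    config: ColonyConfig, day: int, queen: pd.DataFrame
) -> pd.DataFrame:
    """Simulate the trajectories of all workers present on ``day``.

    Worker drift blends broodnest fidelity with attraction toward the queen
    (both age-weighted); workers past the forager transition age drift
    toward the entrance corner instead.  A worker passing within 1.5 BL of
    the queen on her side becomes "excited" for a fixed period, moving
    faster and straighter — the planted post-retinue messenger effect.
    """
    meta = config.workers_present(day)
    if meta.empty:
        warnings.warn(f"no cohorts introduced by day {day}; empty worker set")
        return pd.DataFrame(
            columns=["bee_id", "time_s", "x", "y", "heading_rad", "side"]
        )
    n = config.n_frames()
    prof = config.workers
    qx = queen["x"].to_numpy()
    qy = queen["y"].to_numpy()
    qside = queen["side"].to_numpy()
    t_s = np.round(np.arange(n) * config.dt, 6)
    nests = {s: (cx, cy) for cx, cy, s in config.broodnest_centres}
    ex_frames = int(round(prof.excitation_duration_s * config.frame_rate))

    frames_all = []
    for widx, row in enumerate(meta.itertuples()):
        rng = _rng_for(config, 1, day, widx)
        age = row.age
        w_att = prof.attraction_weight * float(prof.attraction(np.array([age]))[0])
        w_fid = float(prof.fidelity(np.array([age]))[0])
        mob = float(prof.mobility(np.array([age]))[0])
        is_forager = age >= prof.forager_transition_age

        side0 = row.patch_side if not is_forager else rng.integers(2)
        cx, cy = nests[int(side0)]
        x = np.empty(n)
        y = np.empty(n)
        hdg = np.empty(n)
        side = np.empty(n, dtype=np.int8)
        x[0] = np.clip(cx + rng.normal(0, 3.0), 0, config.comb_width)
        y[0] = np.clip(cy + rng.normal(0, 3.0), 0, config.comb_height)
        hdg[0] = rng.uniform(0, TWO_PI)
        side[0] = side0
        ex_timer = 0
        ex, ey = config.entrance_corner()

        noise = rng.vonmises(0.0, 2.0, size=n)
        sh, sc = _gamma_params(mob, 0.6 * mob)
        steps = rng.gamma(sh, sc, size=n)
        u_flip = rng.random(n)
        u_engage = rng.random(n)
        u_patrol = rng.random(n)
        engage_frames = int(round(prof.engage_duration_s * config.frame_rate))
        refr_frames = int(round(prof.refractory_s * config.frame_rate))
        p_rest_end = 1.0 / max(prof.patrol_rest_s * config.frame_rate, 1.0)
        p_patrol_end = 1.0 / max(prof.patrol_duration_s * config.frame_rate, 1.0)
        engage_timer = 0      # frames left inspecting the queen
        refr_timer = 0        # frames before the worker can re-engage
        patrolling = False
        for t in range(1, n):
            px, py, ps = x[t - 1], y[t - 1], side[t - 1]
            tx, ty = nests[int(ps)] if int(ps) in nests else (cx, cy)
            # area fidelity: drift home only when outside the patch
            if np.hypot(tx - px, ty - py) > config.broodnest_radius:
                dxv = w_fid * _unit(tx - px, ty - py)
            else:
                dxv = np.zeros(2)
            if is_forager:
                if patrolling:
                    if u_patrol[t] < p_patrol_end:
                        patrolling = False
                else:
                    if u_patrol[t] < p_rest_end:
                        patrolling = True
                if not patrolling and np.hypot(ex - px, ey - py) > 6.0:
                    dxv = dxv + prof.entrance_weight * _unit(ex - px, ey - py)

            dq = np.hypot(qx[t] - px, qy[t] - py) if ps == qside[t] else np.inf
            if engage_timer > 0 and dq > 2 * prof.attraction_radius:
                engage_timer = 0  # lost the queen
                ex_timer = ex_frames
                refr_timer = refr_frames
            if (
                engage_timer == 0 and refr_timer == 0 and w_att > 0
                and dq < prof.attraction_radius
                and u_engage[t] < prof.engage_prob * w_att
            ):
                engage_timer = engage_frames
            retinue = engage_timer > 0
            if retinue:
                dxv = dxv + 2.0 * _unit(qx[t] - px, qy[t] - py)
                if dq < 1.3:  # close enough to inspect
                    engage_timer -= 1
                    if engage_timer == 0:
                        # leaves the retinue excited: the messenger walk
                        ex_timer = ex_frames
                        refr_timer = refr_frames
            drift = np.arctan2(dxv[1], dxv[0]) if np.hypot(*dxv) > 1e-9 else hdg[t - 1]
            boost = prof.excitation_boost if ex_timer > 0 else 1.0
            wob = noise[t] / (2.0 if ex_timer > 0 else 1.0)
            hdg[t] = np.mod(drift + wob, TWO_PI)
            step = steps[t] * boost
            if retinue and dq < 1.1:
                step *= 0.05  # retinue dwell: stand and inspect the queen
                hdg[t] = np.mod(np.arctan2(qy[t] - py, qx[t] - px) + noise[t] / 4, TWO_PI)
            elif not retinue and dq < 1.2:
                # a worker the queen runs into turns to inspect her briefly
                hdg[t] = np.mod(np.arctan2(qy[t] - py, qx[t] - px) + noise[t] / 4, TWO_PI)
            x[t] = px + step * np.cos(hdg[t])
            y[t] = py + step * np.sin(hdg[t])
            x[t] = min(max(x[t], 0.0), config.comb_width)
            y[t] = min(max(y[t], 0.0), config.comb_height)
            near = (
                x[t] < 1.0 or x[t] > config.comb_width - 1.0
                or y[t] < 1.0 or y[t] > config.comb_height - 1.0
            )
            side[t] = (1 - ps) if (near and u_flip[t] < config.side_switch_prob) else ps
            if ex_timer > 0 and not retinue:
                ex_timer -= 1
            if refr_timer > 0 and not retinue:
                refr_timer -= 1

        frames_all.append(
            pd.DataFrame(
                {"bee_id": row.bee_id, "time_s": t_s, "x": x, "y": y,
                 "heading_rad": hdg, "side": side}
            )
        )
    return pd.concat(frames_all, ignore_index=True)


def _unit(dx: float, dy: float) -> np.ndarray:
    d = np.hypot(dx, dy)
    if d < 1e-9:
        return np.zeros(2)
    return np.array([dx, dy]) / d


def generate_colony_day(
    config: ColonyConfig, day: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate trajectories + metadata + ground truth for one day.

    Returns (trajectories, bees, ground_truth); trajectories include the
    queen and every worker present on ``day``.
    """
    queen_traj, states = simulate_queen_trajectory(config, day)
    workers_traj = simulate_worker_population(config, day, queen_traj)
    traj = pd.concat([queen_traj, workers_traj], ignore_index=True)

    meta = config.workers_present(day)
    prof = config.workers
    if meta.empty:
        community = pd.Series(dtype=object)
    else:
        community = np.where(
            meta["age"] >= prof.forager_transition_age,
            "F",
            np.where(meta["patch_side"] == 0, "N_A", "N_B"),
        )
    bees = pd.DataFrame(
        {
            "bee_id": ["queen"] + meta["bee_id"].tolist(),
            "role": ["queen"] + ["worker"] * len(meta),
            "eclosion_day": [np.nan] + meta["eclosion_day"].tolist(),
            "colony_id": "synthetic",
        }
    )
    gt = GroundTruth(
        queen_states=pd.DataFrame(
            {"time_s": queen_traj["time_s"],
             "queen_state": np.where(states == 0, "S", "T")}
        ),
        workers=pd.DataFrame(
            {"bee_id": meta["bee_id"], "community": community,
             "age": meta["age"], "cohort": meta["cohort"]}
        ),
    )
    return traj, bees, gt


def write_dataset(
    trajectories: pd.DataFrame,
    bees: pd.DataFrame,
    ground_truth: GroundTruth | None,
    path: str | Path,
) -> None:
    """Write trajectories.csv, bees.csv (and ground-truth sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    traj_ids = set(trajectories["bee_id"].unique())
    meta_ids = set(bees["bee_id"])
    if not traj_ids <= meta_ids:
        raise ValueError(f"trajectory ids missing from bees.csv: {sorted(traj_ids - meta_ids)}")
    trajectories.to_csv(path / "trajectories.csv", index=False)
    bees.to_csv(path / "bees.csv", index=False)
    if ground_truth is not None:
        ground_truth.queen_states.to_csv(path / "ground_truth_queen.csv", index=False)
        ground_truth.workers.to_csv(path / "ground_truth_workers.csv", index=False)


def read_dataset(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back (trajectories, bees) written by :func:`write_dataset`."""
    path = Path(path)
    traj = pd.read_csv(path / "trajectories.csv")
    bees = pd.read_csv(path / "bees.csv")
    return traj, bees
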