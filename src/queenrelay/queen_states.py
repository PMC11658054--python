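"""Two-state segmentation of queen movement into stationary/travelling bouts.

Daily queen trajectories are decomposed into step lengths and turn angles
and fitted with a two-state hidden Markov model whose emissions are
zero-inflated gamma (step lengths, BL/frame) and von Mises (turn angles).
The state with the smaller fitted mean step length is labelled S
(stationary), the other T (travelling).  The Viterbi path is segmented into
bouts; bouts shorter than 10 s or with mean posterior below 0.75 are
excluded from downstream transmission analyses, and within-bout analyses
are truncated at a 305 s horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import BaseHMM
from scipy import optimize, special, stats

__all__ = [
    "trajectory_to_steps",
    "StepGammaVonMisesHMM",
    "HmmFit",
    "fit_two_state_hmm",
    "decode_bouts",
    "filter_bouts",
    "state_encounter_stats",
    "BOUT_MIN_DURATION_S",
    "BOUT_MIN_POSTERIOR",
    "BOUT_HORIZON_S",
]

BOUT_MIN_DURATION_S = 10.0
BOUT_MIN_POSTERIOR = 0.75
BOUT_HORIZON_S = 305.0

_ZERO_STEP = 1e-9


def trajectory_to_steps(traj: pd.DataFrame, frame_rate: float = 2.0) -> pd.DataFrame:
    """Step/turn decomposition of one bee's trajectory.

    Step ``i`` is the displacement between frames ``i-1`` and ``i``; the
    turn angle is the signed change in direction of successive displacement
    vectors.  Turns are undefined (flagged) for the first step of a track
    and whenever either adjacent step is zero.  Side switches and time gaps
    larger than one frame split the track.

    Returns a DataFrame with columns ``time_s, step, turn, turn_defined,
    track_id`` (one row per step, timestamped at the step's end frame).
    """
    traj = traj.sort_values("time_s")
    t = traj["time_s"].to_numpy(dtype=float)
    if len(t) < 3:
        import warnings

        warnings.warn("trajectory too short for step decomposition")
        return pd.DataFrame(columns=["time_s", "step", "turn", "turn_defined", "track_id"])
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    side = traj["side"].to_numpy()
    dt = 1.0 / frame_rate

    dx = np.diff(x)
    dy = np.diff(y)
    step = np.hypot(dx, dy)
    direction = np.arctan2(dy, dx)
    gap = np.diff(t) > 1.5 * dt
    side_switch = np.diff(side) != 0
    new_track = gap | side_switch
    track_id = np.concatenate([[0], np.cumsum(new_track)])[1:]

    turn = np.full(len(step), np.nan)
    defined = np.zeros(len(step), dtype=bool)
    ok = (
        (step[1:] > _ZERO_STEP)
        & (step[:-1] > _ZERO_STEP)
        & (track_id[1:] == track_id[:-1])
    )
    dturn = np.angle(np.exp(1j * (direction[1:] - direction[:-1])))
    turn[1:][ok] = dturn[ok]
    defined[1:][ok] = True
    return pd.DataFrame(
        {"time_s": t[1:], "step": step, "turn": turn,
         "turn_defined": defined, "track_id": track_id}
    )


def _a1inv(r: float) -> float:
    """Inverse of the ratio A1(kappa)=I1/I0 for von Mises concentration."""
    if r < 0:
        return 0.0
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / max(r**3 - 4 * r**2 + 3 * r, 1e-8)


def _gamma_mle(mean: float, mean_log: float) -> tuple[float, float]:
    """Weighted gamma MLE (shape, scale) from sufficient statistics."""
    c = np.log(mean) - mean_log
    if not np.isfinite(c) or c <= 1e-12:
        shape = 1e6
    else:
        f = lambda k: np.log(k) - special.digamma(k) - c
        lo, hi = 1e-4, 1e7
        try:
            shape = optimize.brentq(f, lo, hi)
        except ValueError:
            shape = (3 - c + np.sqrt((c - 3) ** 2 + 24 * c)) / (12 * c)
    return shape, mean / shape


class StepGammaVonMisesHMM(BaseHMM):
    """HMM with zero-inflated gamma steps and von Mises turns.

    Observations are rows ``[step, turn, turn_defined]``; frames with
    undefined turns contribute only through the step distribution.  Zero
    steps are handled by a per-state point mass.
    """

    def __init__(self, n_components=2, n_iter=100, tol=1e-3, random_state=None):
        super().__init__(
            n_components=n_components,
            n_iter=n_iter,
            tol=tol,
            random_state=random_state,
            params="ste",
            init_params="st",
            implementation="log",
        )

    # --- emission parameters -------------------------------------------------
    def _get_n_fit_scalars_per_param(self):
        nc = self.n_components
        return {"s": nc - 1, "t": nc * (nc - 1), "e": nc * 5}

    def _init(self, X, lengths=None):
        super()._init(X, lengths=lengths)
        rng = np.random.default_rng(
            self.random_state.integers(2**31)
            if isinstance(self.random_state, np.random.Generator)
            else self.random_state
        )
        steps = X[:, 0]
        nz = steps[steps > _ZERO_STEP]
        qs = np.quantile(nz, np.linspace(0.25, 0.85, self.n_components))
        jitter = rng.uniform(0.5, 1.5, size=self.n_components)
        means = np.sort(qs * jitter)
        self.step_shape_ = np.full(self.n_components, 1.5)
        self.step_scale_ = means / self.step_shape_
        self.zero_weight_ = np.full(self.n_components, max(np.mean(steps <= _ZERO_STEP), 1e-6))
        self.turn_loc_ = np.zeros(self.n_components)
        self.turn_kappa_ = np.sort(rng.uniform(0.3, 4.0, size=self.n_components))

    def _check(self):
        super()._check()

    def _compute_log_likelihood(self, X):
        steps = X[:, 0]
        turns = X[:, 1]
        defined = X[:, 2] > 0.5
        n, k = len(X), self.n_components
        ll = np.zeros((n, k))
        zero = steps <= _ZERO_STEP
        for s in range(k):
            z = np.clip(self.zero_weight_[s], 1e-12, 1 - 1e-12)
            ll[zero, s] = np.log(z)
            ll[~zero, s] = np.log1p(-z) + stats.gamma.logpdf(
                steps[~zero], self.step_shape_[s], scale=self.step_scale_[s]
            )
            ll[defined, s] += stats.vonmises.logpdf(
                turns[defined], self.turn_kappa_[s], loc=self.turn_loc_[s]
            )
        return ll

    def _initialize_sufficient_statistics(self):
        stats_ = super()._initialize_sufficient_statistics()
        k = self.n_components
        stats_.update(
            post_zero=np.zeros(k), post_nz=np.zeros(k),
            sum_step=np.zeros(k), sum_log_step=np.zeros(k),
            post_ang=np.zeros(k), sum_cos=np.zeros(k), sum_sin=np.zeros(k),
        )
        return stats_

    def _accumulate_sufficient_statistics(
        self, stats_, X, lattice, posteriors, fwdlattice, bwdlattice
    ):
        super()._accumulate_sufficient_statistics(
            stats_, X, lattice, posteriors, fwdlattice, bwdlattice
        )
        steps = X[:, 0]
        turns = X[:, 1]
        defined = X[:, 2] > 0.5
        zero = steps <= _ZERO_STEP
        nz = ~zero
        stats_["post_zero"] += posteriors[zero].sum(axis=0)
        stats_["post_nz"] += posteriors[nz].sum(axis=0)
        stats_["sum_step"] += posteriors[nz].T @ steps[nz]
        stats_["sum_log_step"] += posteriors[nz].T @ np.log(steps[nz])
        d = defined
        stats_["post_ang"] += posteriors[d].sum(axis=0)
        stats_["sum_cos"] += posteriors[d].T @ np.cos(turns[d])
        stats_["sum_sin"] += posteriors[d].T @ np.sin(turns[d])

    def _do_mstep(self, stats_):
        super()._do_mstep(stats_)
        if "e" not in self.params:
            return
        for s in range(self.n_components):
            tot = stats_["post_zero"][s] + stats_["post_nz"][s]
            if stats_["post_nz"][s] < 1e-6 or tot < 1e-6:
                raise _DegenerateFit(f"state {s} collapsed")
            self.zero_weight_[s] = stats_["post_zero"][s] / tot
            mean = stats_["sum_step"][s] / stats_["post_nz"][s]
            mean_log = stats_["sum_log_step"][s] / stats_["post_nz"][s]
            self.step_shape_[s], self.step_scale_[s] = _gamma_mle(mean, mean_log)
            if stats_["post_ang"][s] > 1e-6:
                cbar = stats_["sum_cos"][s] / stats_["post_ang"][s]
                sbar = stats_["sum_sin"][s] / stats_["post_ang"][s]
                self.turn_loc_[s] = np.arctan2(sbar, cbar)
                self.turn_kappa_[s] = min(_a1inv(float(np.hypot(cbar, sbar))), 500.0)


class _DegenerateFit(RuntimeError):
    pass


@dataclass
class HmmFit:
    """Result of a two-state fit, states ordered (S, T) by step mean."""

    step_mean: tuple[float, float]
    step_sd: tuple[float, float]
    step_shape: tuple[float, float]
    step_scale: tuple[float, float]
    zero_weight: tuple[float, float]
    turn_loc: tuple[float, float]
    turn_kappa: tuple[float, float]
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    model: StepGammaVonMisesHMM = field(repr=False)
    state_order: np.ndarray = field(repr=False)  # raw index of (S, T)


def _steps_to_X(steps: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    X = np.column_stack(
        [
            steps["step"].to_numpy(dtype=float),
            np.nan_to_num(steps["turn"].to_numpy(dtype=float)),
            steps["turn_defined"].to_numpy(dtype=float),
        ]
    )
    lengths = steps.groupby("track_id", sort=True).size().tolist()
    return X, lengths


def fit_two_state_hmm(
    steps: pd.DataFrame, n_restarts: int = 10, seed: int = 0, n_iter: int = 100
) -> HmmFit:
    """Maximum-likelihood two-state fit with random restarts.

    The best log-likelihood over restarts is kept (ties broken by the lower
    stationary-state mean).  Raises if fewer than 200 steps are supplied or
    if every restart collapses onto a single state.
    """
    if len(steps) < 200:
        raise ValueError("need at least 200 steps for a two-state fit")
    X, lengths = _steps_to_X(steps)
    best: StepGammaVonMisesHMM | None = None
    best_ll = -np.inf
    best_s_mean = np.inf
    rng = np.random.default_rng(seed)
    failures = 0
    for _ in range(max(n_restarts, 1)):
        model = StepGammaVonMisesHMM(
            n_components=2, n_iter=n_iter,
            random_state=int(rng.integers(2**31)),
        )
        try:
            model.fit(X, lengths)
            ll = model.score(X, lengths)
        except (_DegenerateFit, ValueError):
            failures += 1
            continue
        means = model.step_shape_ * model.step_scale_
        s_mean = means.min()
        if ll > best_ll + 1e-9 or (abs(ll - best_ll) <= 1e-9 and s_mean < best_s_mean):
            best, best_ll, best_s_mean = model, ll, s_mean
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed ({failures} degenerate)")

    means = best.step_shape_ * best.step_scale_
    order = np.argsort(means)  # S first
    sd = np.sqrt(best.step_shape_) * best.step_scale_
    perm = order
    return HmmFit(
        step_mean=tuple(means[perm]),
        step_sd=tuple(sd[perm]),
        step_shape=tuple(best.step_shape_[perm]),
        step_scale=tuple(best.step_scale_[perm]),
        zero_weight=tuple(best.zero_weight_[perm]),
        turn_loc=tuple(best.turn_loc_[perm]),
        turn_kappa=tuple(best.turn_kappa_[perm]),
        transmat=best.transmat_[np.ix_(perm, perm)],
        startprob=best.startprob_[perm],
        log_likelihood=float(best_ll),
        model=best,
        state_order=perm,
    )


def decode_bouts(fit: HmmFit, steps: pd.DataFrame, frame_rate: float = 2.0) -> pd.DataFrame:
    """Viterbi-decode the step sequence and segment it into bouts.

    Returns a DataFrame ``state, t_start_s, t_end_s, duration_s,
    mean_posterior`` whose bouts tile each track without overlap;
    ``mean_posterior`` is the mean per-frame posterior probability of the
    decoded state within the bout.
    """
    X, lengths = _steps_to_X(steps)
    raw_path = fit.model.predict(X, lengths)
    post = fit.model.predict_proba(X, lengths)
    # map raw state index -> 0 (S) / 1 (T)
    label_of = np.empty(2, dtype=int)
    label_of[fit.state_order[0]] = 0
    label_of[fit.state_order[1]] = 1
    path = label_of[raw_path]
    post_decoded = post[np.arange(len(path)), raw_path]

    t = steps["time_s"].to_numpy(dtype=float)
    track = steps["track_id"].to_numpy()
    dt = 1.0 / frame_rate
    brk = np.flatnonzero((np.diff(path) != 0) | (np.diff(track) != 0)) + 1
    bounds = np.concatenate([[0], brk, [len(path)]])
    rows = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        rows.append(
            {
                "state": "S" if path[a] == 0 else "T",
                "t_start_s": t[a] - dt,
                "t_end_s": t[b - 1],
                "duration_s": t[b - 1] - t[a] + dt,
                "mean_posterior": float(post_decoded[a:b].mean()),
            }
        )
    return pd.DataFrame(rows)


def filter_bouts(
    bouts: pd.DataFrame,
    min_dur: float = BOUT_MIN_DURATION_S,
    min_post: float = BOUT_MIN_POSTERIOR,
    max_dur: float = BOUT_HORIZON_S,
) -> pd.DataFrame:
    """Apply the bout quality filters.

    Bouts shorter than ``min_dur`` or with mean posterior below ``min_post``
    are dropped.  Longer bouts are retained but get ``horizon_s =
    min(duration, max_dur)``: within-bout transmission curves are computed
    only up to that horizon.
    """
    if bouts.empty:
        out = bouts.copy()
        out["horizon_s"] = pd.Series(dtype=float)
        return out
    keep = (bouts["duration_s"] >= min_dur) & (bouts["mean_posterior"] >= min_post)
    out = bouts[keep].copy()
    out["horizon_s"] = np.minimum(out["duration_s"], max_dur)
    return out.reset_index(drop=True)


def state_encounter_stats(
    bouts: pd.DataFrame, contacts: pd.DataFrame, queen_id: str = "queen"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state queen encounter rates and durations.

    Each queen contact is assigned to the bout containing its start time.
    Returns ``(per_day, summary)``: per (day, state) encounter rate
    (1/min) and mean contact duration (s), plus a paired day-level S-vs-T
    comparison (mean difference ± SE and a Wilcoxon signed-rank p when at
    least two days are available).  ``bouts`` may carry a ``day`` column;
    otherwise a single day 0 is assumed.
    """
    bouts = bouts.copy()
    if "day" not in bouts.columns:
        bouts["day"] = 0
    qc = contacts[(contacts["i"] == queen_id) | (contacts["j"] == queen_id)].copy()
    qc["duration_s"] = qc["t_end_s"] - qc["t_start_s"]

    rows = []
    for (day, state), g in bouts.groupby(["day", "state"]):
        total_min = g["duration_s"].sum() / 60.0
        n_enc = 0
        durs = []
        for b in g.itertuples():
            m = (qc["t_start_s"] >= b.t_start_s) & (qc["t_start_s"] < b.t_end_s)
            n_enc += int(m.sum())
            durs.extend(qc.loc[m, "duration_s"].tolist())
        rows.append(
            {
                "day": day,
                "state": state,
                "encounter_rate_per_min": n_enc / total_min if total_min > 0 else np.nan,
                "mean_contact_duration_s": float(np.mean(durs)) if durs else np.nan,
                "n_encounters": n_enc,
                "state_minutes": total_min,
            }
        )
    per_day = pd.DataFrame(rows)

    summary_rows = []
    for col in ("encounter_rate_per_min", "mean_contact_duration_s"):
        wide = per_day.pivot_table(index="day", columns="state", values=col)
        if not {"S", "T"} <= set(wide.columns):
            continue
        paired = wide.dropna()
        diff = (paired["T"] - paired["S"]).to_numpy()
        if len(diff) == 0:
            continue
        if len(diff) >= 2 and np.any(diff != 0):
            p = float(stats.wilcoxon(diff).pvalue)
        else:
            p = np.nan
        summary_rows.append(
            {
                "metric": col,
                "mean_T_minus_S": float(diff.mean()),
                "se": float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else np.nan,
                "wilcoxon_p": p,
                "n_days": len(diff),
            }
        )
    return per_day, pd.DataFrame(summary_rows)
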