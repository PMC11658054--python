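"""Audience metrics and in-silico transmission experiments.

Three measures summarise how far the queen's signal has spread at time t:
audience size A(t), the proportion of tagged workers whose ensemble-mean
load exceeds the sensitivity threshold; audience coverage S(t), the mean
pairwise distance between informed workers (going around the comb edge for
cross-side pairs); and audience load L(t), the mean load of the informed
workers.

Experiments operate on edited contact sequences: per-bout runs with zeroed
initial loads, full-day runs, queen removal at noon, direct-only runs with
all worker-worker contacts deleted, and the forward versus time-reversed
post/pre-retinue comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transmission_engine import (
    EnsembleResult,
    TransmissionParams,
    integrate_contact,
    lick_probability,
    run_ensemble,
)

__all__ = [
    "cross_side_distance",
    "audience_curves",
    "within_bout_experiment",
    "daily_experiment",
    "queen_removal_experiment",
    "direct_only_experiment",
    "forward_reverse_experiment",
    "half_life",
    "grand_mean_se",
]


def cross_side_distance(
    p_i: tuple[float, float],
    p_j: tuple[float, float],
    side_i: int,
    side_j: int,
    comb_dims: tuple[float, float],
) -> float:
    """Distance between two bees, in body-lengths.

    Same side: Euclidean.  Opposite sides: the shortest straight-line path
    around the comb edge, computed as the minimum over the four edges of
    the distance to the partner reflected across that edge line.
    """
    w, h = comb_dims
    xi = float(np.clip(p_i[0], 0, w)); yi = float(np.clip(p_i[1], 0, h))
    xj = float(np.clip(p_j[0], 0, w)); yj = float(np.clip(p_j[1], 0, h))
    if side_i == side_j:
        return float(np.hypot(xi - xj, yi - yj))
    reflections = (
        (-xj, yj),            # x = 0
        (2 * w - xj, yj),     # x = w
        (xj, -yj),            # y = 0
        (xj, 2 * h - yj),     # y = h
    )
    return float(min(np.hypot(xi - rx, yi - ry) for rx, ry in reflections))


def _positions_at(traj: pd.DataFrame, times: np.ndarray) -> dict:
    """{(bee_id, t): (x, y, side)} for the grid times present in traj."""
    sub = traj[traj["time_s"].isin(times)]
    return {
        (r.bee_id, r.time_s): (r.x, r.y, int(r.side))
        for r in sub.itertuples()
    }


@dataclass
class AudienceCurve:
    """A(t), S(t), L(t) on a common grid (t relative to the run start)."""

    t: np.ndarray
    A: np.ndarray
    S: np.ndarray
    L: np.ndarray
    group: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "t_s": self.t, "A": self.A,
             "S_bl": self.S, "L_pg": self.L}
        )


def audience_curves(
    ensemble: EnsembleResult,
    traj: pd.DataFrame,
    params: TransmissionParams,
    comb_dims: tuple[float, float],
    group_members: list | None = None,
    group: str = "all",
    t0: float = 0.0,
    compute_coverage: bool = True,
) -> AudienceCurve:
    """Audience metrics from an ensemble-mean load series.

    ``group_members`` restricts both the informed set and the denominator
    of A(t) to the given workers.  S(t) and L(t) are missing (NaN) when
    fewer than two / one workers are informed.
    """
    ids = ensemble.bee_ids
    if group_members is not None:
        members = [b for b in group_members if b in set(ids)]
        col = np.array([b in set(members) for b in ids])
        denom = len(members)
    else:
        col = np.ones(len(ids), dtype=bool)
        denom = len(ids)
    if denom == 0:
        n = len(ensemble.grid)
        nanarr = np.full(n, np.nan)
        return AudienceCurve(ensemble.grid - t0, nanarr, nanarr.copy(), nanarr.copy(), group)

    informed = ensemble.informed_mask(params) & col[None, :]
    load = ensemble.mean_load
    A = informed.sum(axis=1) / denom
    L = np.full(len(ensemble.grid), np.nan)
    S = np.full(len(ensemble.grid), np.nan)
    pos = _positions_at(traj, ensemble.grid) if compute_coverage else {}
    for k, t in enumerate(ensemble.grid):
        mask = informed[k]
        if mask.any():
            L[k] = load[k, mask].mean()
        if not compute_coverage:
            continue
        inf_ids = [ids[b] for b in np.flatnonzero(mask)]
        pts = [pos[(b, t)] for b in inf_ids if (b, t) in pos]
        if len(pts) >= 2:
            ds = [
                cross_side_distance(
                    (pts[a][0], pts[a][1]), (pts[b][0], pts[b][1]),
                    pts[a][2], pts[b][2], comb_dims,
                )
                for a in range(len(pts))
                for b in range(a + 1, len(pts))
            ]
            S[k] = float(np.mean(ds))
    return AudienceCurve(ensemble.grid - t0, A, S, L, group)


def _clip_contacts(contacts: pd.DataFrame, t0: float, t1: float) -> pd.DataFrame:
    """Contacts that start and finish inside [t0, t1]."""
    m = (contacts["t_start_s"] >= t0) & (contacts["t_end_s"] <= t1)
    return contacts[m]


def _queen_mask(contacts: pd.DataFrame, queen_id: str) -> pd.Series:
    return (contacts["i"] == queen_id) | (contacts["j"] == queen_id)


def within_bout_experiment(
    bouts: pd.DataFrame,
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    traj: pd.DataFrame,
    params: TransmissionParams,
    comb_dims: tuple[float, float],
    grid_step: float = 5.0,
    compute_coverage: bool = True,
) -> dict[str, list[AudienceCurve]]:
    """Per-bout transmission with zeroed initial loads.

    For each (filtered) bout, the ensemble runs on the contacts starting
    and finishing inside the bout, on a bout-relative clock truncated at
    the bout horizon (≤ 305 s).  Returns curves keyed by bout state.
    """
    out: dict[str, list[AudienceCurve]] = {"S": [], "T": []}
    for b in bouts.itertuples():
        horizon = getattr(b, "horizon_s", min(b.t_end_s - b.t_start_s, 305.0))
        sub = _clip_contacts(contacts, b.t_start_s, b.t_end_s)
        grid = b.t_start_s + np.arange(0.0, horizon + 1e-9, grid_step)
        if sub.empty:
            n = len(grid)
            out[b.state].append(
                AudienceCurve(grid - b.t_start_s, np.zeros(n),
                              np.full(n, np.nan), np.full(n, np.nan))
            )
            continue
        ens = run_ensemble(sub, bees, params, grid=grid)
        out[b.state].append(
            audience_curves(ens, traj, params, comb_dims, t0=b.t_start_s,
                            compute_coverage=compute_coverage)
        )
    return out


def grand_mean_se(values: np.ndarray) -> tuple[float, float]:
    """Grand mean ± SE across colonies (one value per colony)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return np.nan, np.nan
    se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
    return float(v.mean()), float(se)


def aggregate_curves(curves: list[AudienceCurve], grid: np.ndarray) -> pd.DataFrame:
    """Mean ± SE of A/S/L over a list of curves on a common relative grid."""
    rows = []
    for t in grid:
        for metric in ("A", "S", "L"):
            vals = []
            for c in curves:
                k = np.searchsorted(c.t, t)
                if k < len(c.t) and np.isclose(c.t[k], t):
                    vals.append(getattr(c, metric)[k])
            m, se = grand_mean_se(np.array(vals, dtype=float))
            rows.append({"t_s": t, "metric": metric, "mean": m, "se": se,
                         "n": len(vals)})
    return pd.DataFrame(rows)


def daily_experiment(
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    traj: pd.DataFrame,
    params: TransmissionParams,
    comb_dims: tuple[float, float],
    groups: dict[str, list] | None = None,
    grid: np.ndarray | None = None,
    grid_step: float = 300.0,
    day_span: tuple[float, float] | None = None,
    compute_coverage: bool = False,
) -> tuple[dict[str, AudienceCurve], EnsembleResult]:
    """Ensemble run over one day's contact sequence, zero initial loads.

    ``groups`` maps group names (e.g. nurse/forager) to member lists; an
    "all" curve is always included.  Contacts must start and finish inside
    ``day_span`` (defaults to the observed contact span).
    """
    if day_span is None:
        day_span = (float(contacts["t_start_s"].min()), float(contacts["t_end_s"].max()))
    sub = _clip_contacts(contacts, *day_span)
    if grid is None:
        grid = np.arange(day_span[0], day_span[1] + 1e-9, grid_step)
    ens = run_ensemble(sub, bees, params, grid=grid)
    curves = {
        "all": audience_curves(ens, traj, params, comb_dims, t0=day_span[0],
                               compute_coverage=compute_coverage)
    }
    for name, members in (groups or {}).items():
        curves[name] = audience_curves(
            ens, traj, params, comb_dims, group_members=members, group=name,
            t0=day_span[0], compute_coverage=compute_coverage,
        )
    return curves, ens


def half_life(
    t: np.ndarray, informed_count: np.ndarray, removal_time: float
) -> float:
    """Minutes until the informed count halves after ``removal_time``.

    Linear interpolation between grid points; NaN when the count never
    falls to half, or when nobody is informed at removal.
    """
    t = np.asarray(t, dtype=float)
    c = np.asarray(informed_count, dtype=float)
    k0 = int(np.searchsorted(t, removal_time, side="right") - 1)
    if k0 < 0 or c[k0] <= 0:
        return np.nan
    target = c[k0] / 2.0
    for k in range(k0, len(t)):
        if c[k] <= target:
            if k == k0 or c[k] == target or c[k - 1] == c[k]:
                t_half = t[k]
            else:
                f = (c[k - 1] - target) / (c[k - 1] - c[k])
                t_half = t[k - 1] + f * (t[k] - t[k - 1])
            return float((t_half - removal_time) / 60.0)
    return np.nan


def queen_removal_experiment(
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    traj: pd.DataFrame,
    params: TransmissionParams,
    comb_dims: tuple[float, float],
    removal_time: float = 12 * 3600.0,
    groups: dict[str, list] | None = None,
    queen_id: str = "queen",
    **daily_kwargs,
) -> tuple[dict[str, AudienceCurve], pd.DataFrame]:
    """Simulated queen removal: delete queen contacts after ``removal_time``.

    Queen↔worker contacts with ``t_start >= removal_time`` are removed and
    the daily experiment re-run.  Returns the curves plus per-group
    half-life results (minutes from removal until the informed count halves).
    """
    edited = contacts[
        ~(_queen_mask(contacts, queen_id) & (contacts["t_start_s"] >= removal_time))
    ]
    curves, ens = daily_experiment(
        edited, bees, traj, params, comb_dims, groups=groups, **daily_kwargs
    )
    informed = ens.informed_mask(params)
    rows = []
    group_map = {"all": None, **(groups or {})}
    for name, members in group_map.items():
        if members is None:
            col = np.ones(len(ens.bee_ids), dtype=bool)
        else:
            ms = set(members)
            col = np.array([b in ms for b in ens.bee_ids])
        counts = (informed & col[None, :]).sum(axis=1)
        k0 = int(np.searchsorted(ens.grid, removal_time, side="right") - 1)
        n_at_removal = int(counts[k0]) if k0 >= 0 else 0
        rows.append(
            {
                "group": name,
                "t_half_min": half_life(ens.grid, counts, removal_time),
                "n_informed_at_removal": n_at_removal,
            }
        )
    return curves, pd.DataFrame(rows)


def direct_only_experiment(
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    traj: pd.DataFrame,
    params: TransmissionParams,
    comb_dims: tuple[float, float],
    queen_id: str = "queen",
    **daily_kwargs,
) -> tuple[dict[str, AudienceCurve], EnsembleResult]:
    """Daily run in which only direct (queen→worker) transmission can occur:
    every worker-to-worker contact is deleted before the ensemble run."""
    edited = contacts[_queen_mask(contacts, queen_id)]
    return daily_experiment(edited, bees, traj, params, comb_dims, **daily_kwargs)


def reverse_contacts(contacts: pd.DataFrame, t0: float, t1: float) -> pd.DataFrame:
    """Time-reverse a contact sequence inside the window [t0, t1].

    Event order is inverted and durations preserved: a contact occupying
    [a, b] maps to [t0 + t1 - b, t0 + t1 - a].  Applying the map twice
    restores the original sequence.
    """
    out = contacts.copy()
    new_start = t0 + t1 - out["t_end_s"]
    new_end = t0 + t1 - out["t_start_s"]
    out["t_start_s"] = new_start
    out["t_end_s"] = new_end
    return out.sort_values("t_start_s").reset_index(drop=True)


def forward_reverse_experiment(
    queen_contacts: pd.DataFrame,
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    params: TransmissionParams,
    window: float = 300.0,
    grid_step: float = 10.0,
    day_span: tuple[float, float] | None = None,
    queen_id: str = "queen",
    zero_seed: bool = False,
) -> pd.DataFrame:
    """Forward vs time-reversed transmission around queen encounters.

    For each queen–worker encounter ending at t0, the transmission model is
    run on the worker-to-worker contacts in the five minutes after the
    encounter ('forward') and on the time-reversed contacts of the five
    minutes before it ('reverse').  In both runs the focal worker starts
    with the load it acquired from the queen encounter (expected over the
    lick/antennate draw), so the two curves differ only through the worker
    contact sequence.  With ``zero_seed`` the focal worker instead starts
    uninformed and the queen contact itself leads each window.

    Returns a tidy frame ``t_rel_s, encounter, forward_count,
    reverse_count, rel_diff`` where counts are the ensemble-mean numbers of
    informed workers and ``rel_diff = (forward - reverse)/reverse``.
    """
    if day_span is None:
        day_span = (float(contacts["t_start_s"].min()), float(contacts["t_end_s"].max()))
    ww = contacts[~_queen_mask(contacts, queen_id)]
    rows = []
    rel_grid = np.arange(grid_step, window + 1e-9, grid_step)
    for enc_idx, qc in enumerate(queen_contacts.itertuples()):
        worker = qc.j if qc.i == queen_id else qc.i
        t_end = float(qc.t_end_s)
        t_start = float(qc.t_start_s)
        if t_end + window > day_span[1] or t_start - window < day_span[0]:
            continue
        tau = t_end - t_start
        p = float(lick_probability(tau, params))
        rem_l, acq_l = integrate_contact(0.0, tau, "lick", params, True)
        rem_a, acq_a = integrate_contact(0.0, tau, "antennate", params, True)
        seed_load = p * acq_l + (1 - p) * acq_a
        init = None if zero_seed else {worker: (seed_load, 0.0)}

        fwd = _clip_contacts(ww, t_end, t_end + window)
        rev_src = _clip_contacts(ww, t_start - window, t_start)
        rev = reverse_contacts(rev_src, t_start - window, t_start)
        if fwd.empty and rev.empty:
            continue
        # both runs on a window-relative clock starting at 0
        fwd_shift = fwd.copy()
        fwd_shift[["t_start_s", "t_end_s"]] -= t_end
        rev_shift = rev.copy()
        rev_shift[["t_start_s", "t_end_s"]] -= (t_start - window)
        counts = {}
        for name, seq in (("forward", fwd_shift), ("reverse", rev_shift)):
            ens = run_ensemble(seq, bees, params, grid=rel_grid, initial_loads=init)
            counts[name] = ens.informed_mask(params).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = (counts["forward"] - counts["reverse"]) / counts["reverse"]
        for k, t_rel in enumerate(rel_grid):
            rows.append(
                {
                    "t_rel_s": t_rel,
                    "encounter": enc_idx,
                    "forward_count": counts["forward"][k],
                    "reverse_count": counts["reverse"][k],
                    "rel_diff": rel[k],
                }
            )
    return pd.DataFrame(rows)
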