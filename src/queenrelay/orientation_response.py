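"""Receiver orientation toward messengers, queen attraction, and mobility.

Workers that have just left the queen's retinue carry fresh pheromone; the
question is whether nearby nestmates orient their bodies toward such
"messengers".  Orientation strength is measured with the specified-
direction Rayleigh statistic

    ρ = Σ cos(θ − μ) / n,

where θ is a receiver's body orientation and μ the direction from the
receiver to the nearest point of the messenger's body outline.  ρ → 1 when
receivers face the messenger, −1 when they face away, and ≈ 0 for uniform
or orthogonal orientations.  Difference maps contrast ρ̄ between strata
(post vs pre encounter minutes, or messenger-load deciles) on a spatial
grid centred on the messenger.

The module also provides the trajectory-pairing test of worker attraction
to the (stationary) queen and pre/post-encounter mobility curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contact_geometry import GeometryConfig, nearest_point_bearing

__all__ = [
    "rayleigh_rho",
    "collect_orientation_samples",
    "difference_map",
    "angular_transect",
    "queen_attraction_test",
    "mobility_prepost",
]

TWO_PI = 2 * np.pi


def rayleigh_rho(theta: np.ndarray, mu: np.ndarray) -> float:
    """Specified-direction Rayleigh statistic ρ = Σcos(θ−μ)/n."""
    theta = np.asarray(theta, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if theta.shape != mu.shape:
        raise ValueError("theta and mu must be paired")
    if theta.size == 0:
        return np.nan
    return float(np.mean(np.cos(theta - mu)))


def collect_orientation_samples(
    queen_contacts: pd.DataFrame,
    traj: pd.DataFrame,
    window: float = 300.0,
    radius: float = 2.0,
    queen_id: str = "queen",
    messenger_loads: dict | None = None,
    geometry: GeometryConfig | None = None,
) -> pd.DataFrame:
    """Receiver orientation samples around each queen encounter.

    For every queen–worker contact, every frame within ``window`` seconds
    before the contact start (t_rel < 0) or after the contact end
    (t_rel > 0) is scanned for workers within ``radius`` BL of the
    messenger on the same comb side.  Receiver positions and orientations
    are rotated into the messenger frame (messenger at the origin, heading
    along +x).  μ is the direction from the receiver to the nearest point
    of the messenger's body trapezium.  The queen is never a receiver.

    ``messenger_loads`` optionally maps messenger contact index → load
    (pg) used to assign load deciles across samples.

    Returns columns ``messenger, receiver, t_rel_s, x_rel, y_rel, theta,
    mu, load`` (positions and angles in the messenger frame).
    """
    geometry = geometry or GeometryConfig()
    traj = traj.sort_values(["time_s", "bee_id"])
    by_time = {t: g for t, g in traj.groupby("time_s")}
    times = np.array(sorted(by_time))
    rows = []
    for ci, qc in enumerate(queen_contacts.itertuples()):
        messenger = qc.j if qc.i == queen_id else qc.i
        if messenger == queen_id:
            continue
        load = (messenger_loads or {}).get(ci, np.nan)
        for phase, anchor in (("pre", qc.t_start_s), ("post", qc.t_end_s)):
            if phase == "pre":
                sel = times[(times >= anchor - window) & (times < anchor)]
            else:
                sel = times[(times > anchor) & (times <= anchor + window)]
            for t in sel:
                g = by_time[t]
                m = g[g["bee_id"] == messenger]
                if m.empty:
                    continue
                mx, my = float(m["x"].iloc[0]), float(m["y"].iloc[0])
                mh = float(m["heading_rad"].iloc[0])
                mside = int(m["side"].iloc[0])
                near = g[
                    (g["bee_id"] != messenger)
                    & (g["bee_id"] != queen_id)
                    & (g["side"] == mside)
                ]
                dx = near["x"].to_numpy() - mx
                dy = near["y"].to_numpy() - my
                d = np.hypot(dx, dy)
                sel_rows = near[d <= radius]
                dxs, dys = dx[d <= radius], dy[d <= radius]
                for (rrow, rdx, rdy) in zip(sel_rows.itertuples(), dxs, dys):
                    # rotate into messenger frame
                    c, s = np.cos(-mh), np.sin(-mh)
                    xr = rdx * c - rdy * s
                    yr = rdx * s + rdy * c
                    theta = np.mod(rrow.heading_rad - mh, TWO_PI)
                    mu_world = nearest_point_bearing(
                        rrow.x, rrow.y, mx, my, mh, "worker", geometry
                    )
                    mu = np.mod(mu_world - mh, TWO_PI)
                    rows.append(
                        {
                            "messenger": messenger,
                            "receiver": rrow.bee_id,
                            "t_rel_s": (t - anchor),
                            "x_rel": xr,
                            "y_rel": yr,
                            "theta": theta,
                            "mu": mu,
                            "load": load,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=["messenger", "receiver", "t_rel_s", "x_rel", "y_rel",
                 "theta", "mu", "load"],
    )
    if not df.empty and df["load"].notna().any():
        df["load_decile"] = (
            pd.qcut(df["load"].rank(method="first"), 10, labels=False) + 1
        )
    else:
        df["load_decile"] = np.nan
    return df


def _cell_rho(samples: pd.DataFrame, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell ρ̄, counts and mean unit vector over a square grid."""
    nb = len(edges) - 1
    ix = np.clip(np.digitize(samples["x_rel"], edges) - 1, 0, nb - 1)
    iy = np.clip(np.digitize(samples["y_rel"], edges) - 1, 0, nb - 1)
    cosd = np.cos(samples["theta"].to_numpy() - samples["mu"].to_numpy())
    ux = np.cos(samples["theta"].to_numpy())
    uy = np.sin(samples["theta"].to_numpy())
    n = np.zeros((nb, nb))
    srho = np.zeros((nb, nb))
    sux = np.zeros((nb, nb))
    suy = np.zeros((nb, nb))
    np.add.at(n, (iy, ix), 1)
    np.add.at(srho, (iy, ix), cosd)
    np.add.at(sux, (iy, ix), ux)
    np.add.at(suy, (iy, ix), uy)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = srho / n
        mvx = sux / n
        mvy = suy / n
    return rho, n, mvx, mvy


@dataclass
class DifferenceMap:
    """Per-cell Δρ̄ between two sample strata on the messenger-frame grid."""

    edges: np.ndarray            # shared x/y bin edges
    drho: np.ndarray             # (ny, nx), NaN where masked
    n_stratum: np.ndarray
    n_reference: np.ndarray
    dvx: np.ndarray              # difference of mean unit vectors
    dvy: np.ndarray
    variant: str
    stratum: str

    def to_frame(self) -> pd.DataFrame:
        centres = (self.edges[:-1] + self.edges[1:]) / 2
        rows = []
        for iy, yc in enumerate(centres):
            for ix, xc in enumerate(centres):
                rows.append(
                    {
                        "variant": self.variant, "stratum": self.stratum,
                        "x_bl": xc, "y_bl": yc,
                        "drho": self.drho[iy, ix],
                        "n": self.n_stratum[iy, ix],
                    }
                )
        return pd.DataFrame(rows)


def _select_strata(
    samples: pd.DataFrame, variant: str, k: int | None, decile: int | None
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    if variant == "time":
        if k is None:
            raise ValueError("time variant needs a minute index k")
        lo, hi = 60.0 * (k - 1), 60.0 * k
        stratum = samples[(samples["t_rel_s"] > lo) & (samples["t_rel_s"] <= hi)]
        reference = samples[(samples["t_rel_s"] < -lo) & (samples["t_rel_s"] >= -hi)]
        return stratum, reference, f"minute_{k}"
    if variant == "load":
        if decile is None:
            raise ValueError("load variant needs a decile")
        post = samples[samples["t_rel_s"] > 0]
        stratum = post[post["load_decile"] == decile]
        return stratum, post, f"decile_{decile}"
    raise ValueError(f"unknown variant {variant!r}")


def difference_map(
    samples: pd.DataFrame,
    variant: str = "time",
    k: int | None = None,
    decile: int | None = None,
    extent: float = 2.0,
    cell: float = 0.2,
    min_count: int = 50,
) -> DifferenceMap:
    """Δρ̄ map: minute-k post minus minute-k pre (time) or decile minus all
    post samples (load).  Cells with fewer than ``min_count`` samples in
    either stratum are masked (NaN)."""
    stratum, reference, name = _select_strata(samples, variant, k, decile)
    edges = np.arange(-extent, extent + cell / 2, cell)
    r1, n1, vx1, vy1 = _cell_rho(stratum, edges)
    r0, n0, vx0, vy0 = _cell_rho(reference, edges)
    mask = (n1 < min_count) | (n0 < min_count)
    drho = r1 - r0
    drho[mask] = np.nan
    dvx = vx1 - vx0
    dvy = vy1 - vy0
    dvx[mask] = np.nan
    dvy[mask] = np.nan
    return DifferenceMap(
        edges=edges, drho=drho, n_stratum=n1, n_reference=n0,
        dvx=dvx, dvy=dvy, variant=variant, stratum=name,
    )


def angular_transect(
    samples: pd.DataFrame,
    variant: str = "time",
    k: int | None = None,
    decile: int | None = None,
    n_bins: int = 24,
    min_count: int = 10,
) -> pd.DataFrame:
    """Δρ̄ by angular position of the receiver around the messenger.

    Receiver positions are binned by clockwise angle from the messenger's
    heading; Δρ̄ per bin with a large-sample SE (per-sample variance of
    cos(θ−μ) propagated through the difference).
    """
    stratum, reference, name = _select_strata(samples, variant, k, decile)
    edges = np.linspace(0, TWO_PI, n_bins + 1)

    def _binned(df):
        ang = np.mod(-np.arctan2(df["y_rel"], df["x_rel"]), TWO_PI)
        idx = np.clip(np.digitize(ang, edges) - 1, 0, n_bins - 1)
        cosd = np.cos(df["theta"].to_numpy() - df["mu"].to_numpy())
        mean = np.full(n_bins, np.nan)
        var = np.full(n_bins, np.nan)
        cnt = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            v = cosd[idx == b]
            cnt[b] = len(v)
            if len(v):
                mean[b] = v.mean()
                var[b] = v.var(ddof=1) / len(v) if len(v) > 1 else np.nan
        return mean, var, cnt

    m1, v1, c1 = _binned(stratum)
    m0, v0, c0 = _binned(reference)
    keep = (c1 >= min_count) & (c0 >= min_count)
    centres = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(
        {
            "angle_rad": centres,
            "drho": np.where(keep, m1 - m0, np.nan),
            "se": np.where(keep, np.sqrt(v1 + v0), np.nan),
            "n_stratum": c1,
            "n_reference": c0,
            "stratum": name,
        }
    )


def queen_attraction_test(
    worker_traj: pd.DataFrame,
    queen_traj: pd.DataFrame,
    stationary_windows: list[tuple[float, float]] | None = None,
    min_frames: int = 100,
    subsample_s: float = 15.0,
    max_expected_pairs: int = 100_000,
    seed: int = 0,
    paired: bool = True,
) -> dict:
    """Trajectory-pairing test of a worker's attraction to the queen.

    Observed distances are the simultaneous worker–queen distances,
    restricted to the queen's stationary bouts when given (attraction to a
    moving queen cannot be separated from the queen approaching workers).
    The expected distribution pairs worker frames with queen frames
    irrespective of simultaneity, so mutual use of the same comb region is
    controlled for.  In the default paired form, each retained worker
    frame's observed distance is converted to its quantile u within the
    distribution of distances from that worker position to queen positions
    sampled across the whole (stationary) trajectory; with no attraction u
    is uniform on (0, 1), and a one-tailed Wilcoxon signed-rank test of
    u - 1/2 asks whether observed distances sit systematically low in
    their expected distributions.  Frames are subsampled every
    ``subsample_s`` seconds so the paired quantities are approximately
    independent.  ``paired=False`` instead
    runs an unpaired one-tailed Mann-Whitney test of observed vs expected
    distances.

    Returns dict with keys ``effect_bl`` (median observed − median
    expected; negative = attracted), ``p``, ``n_frames``.
    """
    w = worker_traj.set_index("time_s")
    q = queen_traj.set_index("time_s")
    if stationary_windows is not None:
        keep_q = np.zeros(len(q), dtype=bool)
        tq = q.index.to_numpy()
        for a, b in stationary_windows:
            keep_q |= (tq >= a) & (tq <= b)
        q = q[keep_q]
    common = w.index.intersection(q.index)
    if len(common) < min_frames:
        return {"effect_bl": np.nan, "p": np.nan, "n_frames": len(common)}
    wv = w.loc[common]
    qv = q.loc[common]
    same = (wv["side"].to_numpy() == qv["side"].to_numpy())
    t_common = common.to_numpy(dtype=float)[same]
    wx = wv["x"].to_numpy()[same]
    wy = wv["y"].to_numpy()[same]
    qx = qv["x"].to_numpy()[same]
    qy = qv["y"].to_numpy()[same]
    if len(t_common) < min_frames:
        return {"effect_bl": np.nan, "p": np.nan, "n_frames": int(same.sum())}

    # decorrelate: keep at most one frame per subsample_s window
    keep = np.zeros(len(t_common), dtype=bool)
    last = -np.inf
    for k, t in enumerate(t_common):
        if t - last >= subsample_s:
            keep[k] = True
            last = t
    wx, wy, qx, qy = wx[keep], wy[keep], qx[keep], qy[keep]
    obs = np.hypot(wx - qx, wy - qy)

    rng = np.random.default_rng(seed)
    qx_all = q["x"].to_numpy()
    qy_all = q["y"].to_numpy()
    m = max(min(max_expected_pairs // max(len(obs), 1), len(qx_all)), 1)
    # queen positions drawn independently per frame: a shared subsample
    # would correlate the per-frame quantiles and break calibration
    iq = rng.integers(len(qx_all), size=(len(obs), m))
    exp_mat = np.hypot(wx[:, None] - qx_all[iq], wy[:, None] - qy_all[iq])
    effect = float(np.median(obs) - np.median(exp_mat))
    if paired:
        # per-frame probability transform: rank of the observed distance
        # within that frame's expected distribution (mid-rank, uniform
        # under the null)
        less = (exp_mat < obs[:, None]).sum(axis=1)
        ties = (exp_mat == obs[:, None]).sum(axis=1)
        u = (less + 0.5 * ties + 0.5) / (exp_mat.shape[1] + 1)
        diff = u - 0.5
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff, alternative="less").pvalue)
    else:
        p = float(stats.mannwhitneyu(obs, exp_mat.ravel(), alternative="less").pvalue)
    return {"effect_bl": effect, "p": p, "n_frames": len(obs)}


def mobility_prepost(
    queen_contacts: pd.DataFrame,
    traj: pd.DataFrame,
    window: float = 300.0,
    frame_rate: float = 2.0,
    queen_id: str = "queen",
) -> pd.DataFrame:
    """Worker mobility before vs after queen encounters.

    For each queen–worker contact, per-frame instantaneous speed (BL/s),
    unsigned turn angle (rad) and side-switch indicator are aligned on the
    contact start (pre window, t_rel < 0) and contact end (post window,
    t_rel > 0), so the contact itself contaminates neither window.  The
    returned frame has the per-|t| mean of each measure for pre and post
    plus the post-minus-pre difference at matched |t|.
    """
    dt = 1.0 / frame_rate
    per_bee = {b: g.sort_values("time_s") for b, g in traj.groupby("bee_id")}
    acc: dict[tuple[float, str, str], list[float]] = {}
    for qc in queen_contacts.itertuples():
        worker = qc.j if qc.i == queen_id else qc.i
        if worker == queen_id or worker not in per_bee:
            continue
        g = per_bee[worker]
        t = g["time_s"].to_numpy()
        x = g["x"].to_numpy()
        y = g["y"].to_numpy()
        side = g["side"].to_numpy()
        step = np.hypot(np.diff(x), np.diff(y))
        speed = step * frame_rate
        direction = np.arctan2(np.diff(y), np.diff(x))
        turn = np.full(len(step), np.nan)
        ok = (step[1:] > 1e-9) & (step[:-1] > 1e-9)
        dturn = np.abs(np.angle(np.exp(1j * (direction[1:] - direction[:-1]))))
        turn[1:][ok] = dturn[ok]
        switch = np.concatenate([[0], (np.diff(side) != 0).astype(float)])[1:]
        t_step = t[1:]
        for phase, anchor, sign in (("pre", qc.t_start_s, -1), ("post", qc.t_end_s, 1)):
            if sign < 0:
                m = (t_step >= anchor - window) & (t_step < anchor)
            else:
                m = (t_step > anchor) & (t_step <= anchor + window)
            t_rel = np.abs(t_step[m] - anchor)
            for arr, name in ((speed[m], "speed"), (turn[m], "turn"), (switch[m] * frame_rate, "switch_rate")):
                for tr, v in zip(np.round(t_rel / dt) * dt, arr):
                    if np.isfinite(v):
                        acc.setdefault((tr, phase, name), []).append(v)
    rows = []
    t_vals = sorted({k[0] for k in acc})
    for tr in t_vals:
        row = {"t_abs_s": tr}
        for name in ("speed", "turn", "switch_rate"):
            for phase in ("pre", "post"):
                v = acc.get((tr, phase, name), [])
                row[f"{name}_{phase}_mean"] = float(np.mean(v)) if v else np.nan
                row[f"{name}_{phase}_se"] = (
                    float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan
                )
            row[f"{name}_diff"] = row[f"{name}_post_mean"] - row[f"{name}_pre_mean"]
        rows.append(row)
    return pd.DataFrame(rows)
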