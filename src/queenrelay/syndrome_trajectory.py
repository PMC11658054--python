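"""The messaging syndrome and its developmental trajectory.

Six per-bee-per-day metrics summarise "messaging": m1 queen-attraction
effect (signed; larger = more attracted), m2 queen-contact count, m3
combined nurse affiliation N_A + N_B, m4 bridging score H′, m5 relay
out-degree k_out, and m6 degree difference Δk.  Because absolute values
vary between colonies and days, each metric is quantile-transformed within
each colony-day (rank/(n+1), mean ranks for ties) before a single pooled
PCA.  The per-age means of (PC1, PC2) trace a developmental path whose
sharpest bend — the maximum-curvature point of the smoothed path — marks
the behavioural transition age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

__all__ = [
    "METRICS",
    "assemble_syndrome",
    "quantile_transform",
    "pca_development",
    "smooth_and_inflect",
    "DevelopmentTrajectory",
]

METRICS = ["m1", "m2", "m3", "m4", "m5", "m6"]


def assemble_syndrome(
    bees: pd.DataFrame,
    day: int,
    attraction: dict,
    queen_contact_counts: dict,
    affiliations: pd.DataFrame,
    relay_degrees: dict,
    colony: str = "synthetic",
) -> pd.DataFrame:
    """One syndrome row per tagged worker for one observation day.

    ``attraction`` maps bee_id → signed attraction effect (negated median
    observed-minus-expected distance, so larger = more attracted);
    ``queen_contact_counts`` maps bee_id → contact count;
    ``affiliations`` is the labelled community table with H_bridge;
    ``relay_degrees`` maps bee_id → (k_out, dk).  Workers without an
    eclosion day are excluded with a warning; missing metrics propagate
    as NaN.
    """
    import warnings

    rows = []
    workers = bees[bees["role"] == "worker"]
    for b in workers.itertuples():
        if pd.isna(b.eclosion_day):
            warnings.warn(f"worker {b.bee_id} lacks an eclosion day; excluded")
            continue
        aff = (
            affiliations.loc[b.bee_id]
            if b.bee_id in affiliations.index
            else None
        )
        k_out, dk = relay_degrees.get(b.bee_id, (np.nan, np.nan))
        rows.append(
            {
                "colony": colony,
                "bee_id": b.bee_id,
                "day": day,
                "age": day - b.eclosion_day,
                "m1": attraction.get(b.bee_id, np.nan),
                "m2": queen_contact_counts.get(b.bee_id, np.nan),
                "m3": (aff["N_A"] + aff["N_B"]) if aff is not None else np.nan,
                "m4": aff["H_bridge"] if aff is not None and "H_bridge" in aff else np.nan,
                "m5": k_out,
                "m6": dk,
            }
        )
    return pd.DataFrame(
        rows, columns=["colony", "bee_id", "day", "age"] + METRICS
    )


def quantile_transform(rows: pd.DataFrame) -> pd.DataFrame:
    """Within colony-day quantile transform of each metric.

    Values are replaced by rank/(n+1) computed independently per metric and
    per colony-day; tied values receive the mean rank, and a constant
    metric-day maps to 0.5 everywhere.  Missing values stay missing.
    """
    out = rows.copy()
    for m in METRICS:
        def _q(s: pd.Series) -> pd.Series:
            v = s.dropna()
            if len(v) == 0:
                return s
            r = v.rank(method="average")
            return r / (len(v) + 1)

        out[m] = (
            rows.groupby(["colony", "day"], group_keys=False)[m].apply(_q)
        )
    return out


@dataclass
class DevelopmentTrajectory:
    """Age-resolved path of the pooled PCA scores for one colony."""

    ages: np.ndarray
    pc1: np.ndarray
    pc2: np.ndarray
    colony: str
    explained_variance: tuple[float, float]


def pca_development(
    transformed: pd.DataFrame, max_missing_fraction: float = 0.2
) -> tuple[list[DevelopmentTrajectory], pd.DataFrame, pd.DataFrame]:
    """Pooled PCA on the quantile metrics and per-colony age trajectories.

    Complete cases enter a centred PCA on the six quantile metrics
    (rejecting input with more than ``max_missing_fraction`` incomplete
    rows); the sign convention makes the PC1 loading of m5 (out-degree)
    positive.  Per colony and age, the mean (PC1, PC2) over cohort-days
    forms the developmental path.

    Returns ``(trajectories, loadings, scores)`` where loadings is a
    6×2 DataFrame and scores carries per-row PC1/PC2.
    """
    X = transformed[METRICS]
    complete = X.notna().all(axis=1)
    if (1 - complete.mean()) > max_missing_fraction:
        raise ValueError("too many incomplete syndrome rows for PCA")
    data = transformed[complete].reset_index(drop=True)
    mat = data[METRICS].to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat - mat.mean(axis=0)) < 2:
        raise ValueError("rank-deficient syndrome matrix")
    pca = PCA(n_components=2)
    scores = pca.fit_transform(mat)
    comps = pca.components_.copy()
    for pc in range(2):
        anchor = comps[pc, METRICS.index("m5")]
        if anchor < 0:
            comps[pc] *= -1
            scores[:, pc] *= -1
    loadings = pd.DataFrame(comps.T, index=METRICS, columns=["PC1", "PC2"])
    data = data.assign(PC1=scores[:, 0], PC2=scores[:, 1])

    trajectories = []
    for colony, g in data.groupby("colony"):
        by_age = g.groupby("age")[["PC1", "PC2"]].mean().sort_index()
        trajectories.append(
            DevelopmentTrajectory(
                ages=by_age.index.to_numpy(dtype=float),
                pc1=by_age["PC1"].to_numpy(),
                pc2=by_age["PC2"].to_numpy(),
                colony=str(colony),
                explained_variance=tuple(pca.explained_variance_ratio_[:2]),
            )
        )
    return trajectories, loadings, data


def smooth_and_inflect(
    trajectory: DevelopmentTrajectory,
    window: int = 7,
    polyorder: int = 3,
    weak_threshold: float = 1e-3,
) -> dict:
    """Savitzky–Golay smoothing of the (PC1, PC2) age path and its
    maximum-curvature inflection age.

    Discrete curvature κ = |x'y'' − y'x''| / (x'² + y'²)^{3/2} of the
    smoothed path, interior ages only.  Ages where the path is nearly
    stationary (speed below half the median speed) are excluded:
    curvature is ill-conditioned there, and the developmental path
    plateaus at old ages.  When the maximum curvature falls below
    ``weak_threshold`` the inflection is flagged weak; with fewer than 7
    age points the inflection is missing.
    """
    ages = trajectory.ages
    if len(ages) < 7:
        return {
            "ages": ages, "pc1_smooth": trajectory.pc1,
            "pc2_smooth": trajectory.pc2,
            "inflection_age": np.nan, "max_curvature": np.nan, "weak": True,
        }
    win = min(window, len(ages) if len(ages) % 2 == 1 else len(ages) - 1)
    if win <= polyorder:
        win = polyorder + 1 + (polyorder % 2)
    xs = savgol_filter(trajectory.pc1, win, polyorder)
    ys = savgol_filter(trajectory.pc2, win, polyorder)
    dx = np.gradient(xs, ages)
    dy = np.gradient(ys, ages)
    ddx = np.gradient(dx, ages)
    ddy = np.gradient(dy, ages)
    speed_sq = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - dy * ddx) / np.power(speed_sq, 1.5)
    kappa[speed_sq < 1e-12] = 0.0
    speed = np.sqrt(speed_sq)
    slow = speed < 0.5 * np.median(speed)
    k_sel = kappa.copy()
    k_sel[slow] = np.nan
    k_sel[0] = k_sel[-1] = np.nan
    if np.all(np.isnan(k_sel)):
        idx = int(np.nanargmax(kappa[1:-1])) + 1
    else:
        idx = int(np.nanargmax(k_sel))
    max_k = float(kappa[idx])
    return {
        "ages": ages,
        "pc1_smooth": xs,
        "pc2_smooth": ys,
        "curvature": kappa,
        "inflection_age": float(ages[idx]),
        "max_curvature": max_k,
        "weak": max_k < weak_threshold,
    }
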