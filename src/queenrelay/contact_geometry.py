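"""Trapezoidal body models and detection of transmission-relevant contacts.

Each bee's body outline is modelled as a trapezium centred on its tracking
tag, long axis along the body heading, wider at the head end than at the
tail end; the queen's trapezium is longer than a worker's.  A physical
contact relevant for pheromone transmission is any frame in which the head
half of one bee's trapezium overlaps any part of a nestmate's trapezium.
Side-by-side or tail-to-tail proximity therefore never counts as contact.

Coordinates are in worker body-lengths (BL); headings are CCW radians from
the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from scipy.spatial import cKDTree

__all__ = [
    "BodyDims",
    "GeometryConfig",
    "body_polygon",
    "head_half_polygon",
    "classify_inspection",
    "detect_contacts",
]


@dataclass(frozen=True)
class BodyDims:
    """Trapezium dimensions for one role, in body-lengths."""

    length: float
    head_width: float
    tail_width: float

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.head_width > 0 and self.tail_width > 0):
            raise ValueError("body dimensions must be positive")
        if self.head_width < self.tail_width:
            raise ValueError("head must be at least as wide as the tail")


#: Worker dimensions define the unit: length 1 BL.
WORKER_DIMS = BodyDims(length=1.0, head_width=0.55, tail_width=0.35)
#: The queen is longer and somewhat wider than a worker.
QUEEN_DIMS = BodyDims(length=1.5, head_width=0.66, tail_width=0.42)


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of contact detection.

    facing_halfangle_rad: a bee "faces" its partner when the bearing to the
        partner lies within this half-angle of its own heading (default π/2,
        i.e. the frontal half-plane).
    gap_tol_frames: dropouts of at most this many frames inside a contact
        are bridged rather than splitting the contact.
    """

    worker: BodyDims = WORKER_DIMS
    queen: BodyDims = QUEEN_DIMS
    facing_halfangle_rad: float = np.pi / 2
    gap_tol_frames: int = 1

    def dims_for(self, role: str) -> BodyDims:
        if role == "queen":
            return self.queen
        if role == "worker":
            return self.worker
        raise ValueError(f"unknown role: {role!r}")


def _trapezium_vertices(
    x: float | np.ndarray,
    y: float | np.ndarray,
    heading: float | np.ndarray,
    dims: BodyDims,
    head_only: bool = False,
) -> np.ndarray:
    """Vertex array(s) of the body trapezium, CCW, shape (..., 4, 2).

    With ``head_only`` the rear edge is the transverse centre (tag) line,
    whose width is the trapezium width at mid-body.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    heading = np.asarray(heading, dtype=float)
    c, s = np.cos(heading), np.sin(heading)
    half_len = dims.length / 2.0
    hw = dims.head_width / 2.0
    tw = (dims.head_width + dims.tail_width) / 4.0 if head_only else dims.tail_width / 2.0
    rear = 0.0 if head_only else -half_len
    # local frame: +x toward the head
    local = np.array(
        [
            [half_len, -hw],
            [half_len, hw],
            [rear, tw],
            [rear, -tw],
        ]
    )
    lx, ly = local[:, 0], local[:, 1]
    vx = x[..., None] + lx * c[..., None] - ly * s[..., None]
    vy = y[..., None] + lx * s[..., None] + ly * c[..., None]
    return np.stack([vx, vy], axis=-1)


def body_polygon(x: float, y: float, heading: float, role: str,
                 config: GeometryConfig | None = None) -> Polygon:
    """Full-body trapezium of a bee at the given pose."""
    config = config or GeometryConfig()
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(heading)):
        raise ValueError("pose must be finite")
    return Polygon(_trapezium_vertices(x, y, heading, config.dims_for(role)))


def head_half_polygon(x: float, y: float, heading: float, role: str,
                      config: GeometryConfig | None = None) -> Polygon:
    """Front half of the trapezium, split at the tag (centre) line."""
    config = config or GeometryConfig()
    return Polygon(_trapezium_vertices(x, y, heading, config.dims_for(role), head_only=True))


def _faces(xi, yi, hi, xj, yj, halfangle) -> np.ndarray:
    """True where the bearing from i to j is within halfangle of i's heading.

    Strict at the boundary: a partner exactly perpendicular to the heading
    (side-by-side stance at the default 90° half-angle) is not faced.
    """
    bearing = np.arctan2(np.asarray(yj) - np.asarray(yi), np.asarray(xj) - np.asarray(xi))
    d = np.angle(np.exp(1j * (bearing - np.asarray(hi))))
    return np.abs(d) < halfangle - 1e-12


def classify_inspection(
    pose_i: tuple[float, float, float],
    pose_j: tuple[float, float, float],
    role_i: str = "worker",
    role_j: str = "worker",
    config: GeometryConfig | None = None,
) -> tuple[bool, bool]:
    """Per-frame inspection flags (i_inspects, j_inspects).

    Bee i inspects j when i's head half overlaps j's body and i faces j.
    Both flags may be false (e.g. flank contact), in which case the frame
    carries no transmission.
    """
    config = config or GeometryConfig()
    xi, yi, hi = pose_i
    xj, yj, hj = pose_j
    body_i = body_polygon(xi, yi, hi, role_i, config)
    body_j = body_polygon(xj, yj, hj, role_j, config)
    head_i = head_half_polygon(xi, yi, hi, role_i, config)
    head_j = head_half_polygon(xj, yj, hj, role_j, config)
    i_insp = head_i.intersects(body_j) and bool(
        _faces(xi, yi, hi, xj, yj, config.facing_halfangle_rad)
    )
    j_insp = head_j.intersects(body_i) and bool(
        _faces(xj, yj, hj, xi, yi, config.facing_halfangle_rad)
    )
    return i_insp, j_insp


def _runs_with_gap(frames: np.ndarray, gap_tol: int) -> list[tuple[int, int]]:
    """Split sorted frame indices into runs, bridging gaps <= gap_tol frames."""
    runs = []
    start = prev = frames[0]
    for f in frames[1:]:
        if f - prev > gap_tol + 1:
            runs.append((start, prev))
            start = f
        prev = f
    runs.append((start, prev))
    return runs


def detect_contacts(
    traj: pd.DataFrame,
    bees: pd.DataFrame,
    config: GeometryConfig | None = None,
    frame_rate: float = 2.0,
) -> pd.DataFrame:
    """Detect transmission-relevant contacts from a trajectory table.

    Parameters
    ----------
    traj : DataFrame with columns bee_id, time_s, x, y, heading_rad, side.
        All bees must share the regular time grid (missing frames allowed).
    bees : DataFrame with columns bee_id, role.
    config : geometry configuration.
    frame_rate : frames per second of the grid.

    Returns
    -------
    DataFrame with columns
    ``i, j, t_start_s, t_end_s, side, frac_frames_i_inspects,
    frac_frames_j_inspects`` where ``t_end_s - t_start_s`` is the contact
    duration ((n_frames) × frame interval, end-exclusive convention).
    Contacts never span comb sides; a dropout of at most ``gap_tol_frames``
    inside a contact is bridged.
    """
    config = config or GeometryConfig()
    if traj.empty:
        return _empty_contacts()
    dt = 1.0 / frame_rate
    role_of = dict(zip(bees["bee_id"], bees["role"]))
    missing = set(traj["bee_id"].unique()) - set(role_of)
    if missing:
        raise ValueError(f"trajectory bees missing from metadata: {sorted(missing)}")

    traj = traj.sort_values(["time_s", "bee_id"], kind="mergesort")
    times = np.unique(traj["time_s"].to_numpy())
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    frame_idx = {tv: k for k, tv in enumerate(times)}

    reach = {
        r: config.dims_for(r).length / 2.0 for r in ("worker", "queen")
    }
    # candidate pair-frames via centroid prefilter, then exact trapezium test
    cand_rows: list[tuple] = []
    for tv, g in traj.groupby("time_s", sort=True):
        for side_val, gs in g.groupby("side"):
            if len(gs) < 2:
                continue
            ids = gs["bee_id"].to_numpy()
            xy = gs[["x", "y"]].to_numpy()
            hd = gs["heading_rad"].to_numpy()
            tree = cKDTree(xy)
            # centroid separation can never exceed the sum of half-lengths
            # for overlapping trapezia; use the queen's as a safe bound
            max_reach = 2 * max(reach.values())
            for a, b in tree.query_pairs(r=max_reach):
                ia, ib = ids[a], ids[b]
                if ia > ib:
                    a, b, ia, ib = b, a, ib, ia
                ra, rb = role_of[ia], role_of[ib]
                cand_rows.append(
                    (ia, ib, frame_idx[tv], side_val,
                     xy[a, 0], xy[a, 1], hd[a], ra,
                     xy[b, 0], xy[b, 1], hd[b], rb)
                )
    if not cand_rows:
        return _empty_contacts()

    arr = pd.DataFrame(
        cand_rows,
        columns=["i", "j", "frame", "side", "xi", "yi", "hi", "ri",
                 "xj", "yj", "hj", "rj"],
    )
    # vectorised shapely polygon arrays
    def _polys(xs, ys, hs, roles, head_only):
        out = np.empty(len(xs), dtype=object)
        for r in ("worker", "queen"):
            m = roles == r
            if not m.any():
                continue
            verts = _trapezium_vertices(
                xs[m], ys[m], hs[m], config.dims_for(r), head_only=head_only
            )
            out[m] = shapely.polygons(verts)
        return out

    xi, yi, hi = (arr[c].to_numpy() for c in ("xi", "yi", "hi"))
    xj, yj, hj = (arr[c].to_numpy() for c in ("xj", "yj", "hj"))
    ri = arr["ri"].to_numpy()
    rj = arr["rj"].to_numpy()
    body_i = _polys(xi, yi, hi, ri, head_only=False)
    body_j = _polys(xj, yj, hj, rj, head_only=False)
    head_i = _polys(xi, yi, hi, ri, head_only=True)
    head_j = _polys(xj, yj, hj, rj, head_only=True)

    hi_overlaps = shapely.intersects(head_i, body_j)
    hj_overlaps = shapely.intersects(head_j, body_i)
    is_contact = hi_overlaps | hj_overlaps
    face_i = _faces(xi, yi, hi, xj, yj, config.facing_halfangle_rad)
    face_j = _faces(xj, yj, hj, xi, yi, config.facing_halfangle_rad)
    arr["contact"] = is_contact
    arr["i_insp"] = hi_overlaps & face_i
    arr["j_insp"] = hj_overlaps & face_j

    arr = arr[arr["contact"]]
    if arr.empty:
        return _empty_contacts()

    records = []
    for (ia, ib, side_val), g in arr.groupby(["i", "j", "side"], sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        insp_i = dict(zip(frames, g["i_insp"]))
        insp_j = dict(zip(frames, g["j_insp"]))
        for f0, f1 in _runs_with_gap(frames, config.gap_tol_frames):
            span = [f for f in range(f0, f1 + 1) if f in insp_i]
            n = len(span)
            records.append(
                {
                    "i": ia,
                    "j": ib,
                    "t_start_s": times[f0],
                    "t_end_s": times[f1] + dt,
                    "side": side_val,
                    "frac_frames_i_inspects": sum(insp_i[f] for f in span) / n,
                    "frac_frames_j_inspects": sum(insp_j[f] for f in span) / n,
                }
            )
    out = pd.DataFrame.from_records(records).sort_values(
        ["t_start_s", "i", "j"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def _empty_contacts() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "i", "j", "t_start_s", "t_end_s", "side",
            "frac_frames_i_inspects", "frac_frames_j_inspects",
        ]
    )


def nearest_point_bearing(
    px: float, py: float, x: float, y: float, heading: float, role: str,
    config: GeometryConfig | None = None,
) -> float:
    """Bearing (radians, [0, 2π)) from (px, py) to the nearest point of the
    body trapezium of a bee at pose (x, y, heading)."""
    config = config or GeometryConfig()
    poly = body_polygon(x, y, heading, role, config)
    boundary = poly.exterior
    p = Point(px, py)
    if poly.contains(p):
        # receiver centre inside the messenger outline: bearing to centroid
        qx, qy = x, y
    else:
        q = boundary.interpolate(boundary.project(p))
        qx, qy = q.x, q.y
    return float(np.mod(np.arctan2(qy - py, qx - px), 2 * np.pi))
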