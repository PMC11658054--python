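"""Stochastic queen-pheromone transmission over time-ordered contacts.

The queen is the sole pheromone source and carries a constant surface load
λ_Q (production balances removal by the retinue).  Workers start every
simulation with zero load and acquire pheromone by inspecting (licking or
antennating) the queen or pheromone-carrying nestmates.  Per contact:

* the inspector is the receiver; when both participants inspect, the bee
  with the higher current load donates (exact ties: symmetric half
  transfers);
* the contact is a licking contact with probability p(τ) (a logistic in
  contact duration τ), otherwise antennation; licking extracts faster;
* extraction is first order in the donor's load, so worker donors deplete
  within a contact (diminishing returns: removed = λ0(1 − e^{−kτ})) while
  the queen acts as a clamped source (removed = k λ_Q τ);
* transmission is leaky: the receiver ingests half of what the donor
  loses, so acquired = 0.5 × removed;
* between contacts every worker's load decays exponentially at rate δ.

Loads are tracked per bee as queen-derived (λ_qw) and worker-derived
(λ_ww) fractions; whatever arrives from a worker donor counts as
worker-derived regardless of the donor's own mix.  A worker is *informed*
when its total load exceeds the sensitivity threshold λ_min = 9.03 pg, and
directly vs indirectly informed according to which fraction dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TransmissionParams",
    "LoadSeries",
    "lick_probability",
    "integrate_contact",
    "run_transmission",
    "run_ensemble",
    "EnsembleResult",
    "informed_class",
]


@dataclass(frozen=True)
class TransmissionParams:
    """Parameters of the transmission model.

    Units: loads in pg, times in s, rates in 1/s.  The defaults are a
    calibrated profile (not literature measurements): a typical ~30 s
    retinue contact delivers a load of tens of sensitivity thresholds
    λ_min, so that the acquired pheromone can support several onward
    worker-to-worker hops before attenuating below λ_min — the regime in
    which messenger relaying operates.  All values are overridable.
    """

    lambda_queen: float = 2000.0
    lambda_min: float = 9.03
    decay_rate: float = 2e-4
    k_lick: float = 0.05
    k_ant: float = 0.0125
    #: logistic duration→lick-probability curve (p_max, tau0_s, slope_s)
    lick_p_max: float = 0.8
    lick_tau0: float = 20.0
    lick_slope: float = 8.0
    ingestion_fraction: float = 0.5
    n_sims: int = 100
    seed: int = 0

    def validate(self) -> None:
        pos = (
            self.lambda_queen, self.lambda_min, self.k_lick, self.k_ant,
            self.lick_p_max, self.lick_tau0, self.lick_slope,
        )
        if any(v <= 0 for v in pos) or self.decay_rate < 0:
            raise ValueError("rate and load parameters must be positive")
        if not 0 <= self.ingestion_fraction <= 1:
            raise ValueError("ingestion_fraction must lie in [0, 1]")
        if self.lambda_min >= self.lambda_queen:
            raise ValueError("sensitivity threshold must be below the queen load")
        if self.k_lick <= self.k_ant:
            raise ValueError("licking must extract faster than antennation")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TransmissionParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclass_to_dict(self), fh)


def dataclass_to_dict(p: TransmissionParams) -> dict:
    from dataclasses import asdict

    return asdict(p)


def lick_probability(duration: float | np.ndarray, params: TransmissionParams) -> np.ndarray:
    """Probability that a contact of the given duration is a licking contact.

    Monotone non-decreasing logistic: p(τ) = p_max / (1 + exp(−(τ−τ0)/s)).
    """
    tau = np.asarray(duration, dtype=float)
    return params.lick_p_max / (1.0 + np.exp(-(tau - params.lick_tau0) / params.lick_slope))


def integrate_contact(
    donor_load: float,
    duration: float,
    mode: str,
    params: TransmissionParams,
    donor_is_queen: bool,
) -> tuple[float, float]:
    """Amount (removed, acquired) for a single one-directional contact.

    First-order extraction at rate ``k_mode``: a worker donor depletes
    (removed = λ0(1 − e^{−kτ})) whereas the queen's load is clamped
    (removed = k λ_Q τ).  The receiver acquires the ingestion-adjusted
    fraction of the removed amount.
    """
    if duration < 0:
        raise ValueError("contact duration must be non-negative")
    k = params.k_lick if mode == "lick" else params.k_ant
    if donor_is_queen:
        removed = k * params.lambda_queen * duration
    else:
        removed = donor_load * (1.0 - np.exp(-k * duration))
    acquired = params.ingestion_fraction * removed
    return removed, acquired


def informed_class(lam_qw: float, lam_ww: float, params: TransmissionParams) -> str:
    """Classify a worker as directly/indirectly informed or uninformed."""
    if lam_qw + lam_ww <= params.lambda_min:
        return "uninformed"
    return "direct" if lam_qw > lam_ww else "indirect"


@dataclass
class LoadSeries:
    """Per-bee load trajectories sampled on a regular grid."""

    grid: np.ndarray                 # (n_times,)
    bee_ids: list                    # (n_bees,), workers only
    lam_qw: np.ndarray               # (n_times, n_bees)
    lam_ww: np.ndarray               # (n_times, n_bees)

    @property
    def lam(self) -> np.ndarray:
        return self.lam_qw + self.lam_ww

    def to_frame(self, params: TransmissionParams) -> pd.DataFrame:
        rows = []
        lam = self.lam
        for k, t in enumerate(self.grid):
            for b, bee in enumerate(self.bee_ids):
                rows.append(
                    {
                        "t_s": t, "bee_id": bee,
                        "lambda_pg": lam[k, b],
                        "lambda_qw_pg": self.lam_qw[k, b],
                        "lambda_ww_pg": self.lam_ww[k, b],
                        "informed_class": informed_class(
                            self.lam_qw[k, b], self.lam_ww[k, b], params
                        ),
                    }
                )
        return pd.DataFrame(rows)


def _sorted_contacts(contacts: pd.DataFrame) -> pd.DataFrame:
    c = contacts.sort_values(["t_start_s", "i", "j"], kind="mergesort")
    return c.reset_index(drop=True)


def _contact_uniforms(contacts: pd.DataFrame, run_key: int) -> np.ndarray:
    """Deterministic uniforms in [0, 1), keyed by run and contact identity.

    Using the contact identity (rather than its position in the sequence)
    as the random key gives common random numbers across edited contact
    sequences: deleting some contacts leaves every other contact's
    lick/antennate draw unchanged, so e.g. the queen-removal run is
    bit-identical to the daily run before the removal time.
    """
    ckeys = pd.util.hash_pandas_object(
        contacts[["i", "j", "t_start_s"]], index=False
    ).to_numpy(dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = ckeys ^ np.uint64(run_key)
        # splitmix64 finaliser
        z = (z + np.uint64(0x9E3779B97F4A7C15))
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z.astype(np.float64) / float(1 << 64)


def run_transmission(
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    params: TransmissionParams,
    seed: int | np.random.SeedSequence = 0,
    grid: np.ndarray | None = None,
    initial_loads: dict | None = None,
    redraw_per_frame: bool = False,
    frame_rate: float = 2.0,
) -> tuple[list[dict], LoadSeries | None]:
    """One stochastic run of the transmission model.

    Contacts are processed in time order; the only random element is the
    per-contact lick/antennate draw (``redraw_per_frame`` redraws the mode
    each frame instead).  Between events worker loads decay exponentially;
    the queen's load never changes.  ``initial_loads`` may seed workers
    with ``{bee_id: (lam_qw, lam_ww)}`` at the run start.

    Returns ``(events, series)`` where events are dicts with keys
    ``t_s, donor, receiver, mode, removed_pg, acquired_pg`` and ``series``
    samples worker loads on ``grid`` (or None if no grid was given).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    run_key = int(np.random.SeedSequence(seed).generate_state(1, dtype=np.uint64)[0]) \
        if not isinstance(seed, np.random.SeedSequence) \
        else int(seed.generate_state(1, dtype=np.uint64)[0])
    contacts = _sorted_contacts(contacts)
    mode_u = _contact_uniforms(contacts, run_key)
    roles = dict(zip(bees["bee_id"], bees["role"]))
    queen_ids = {b for b, r in roles.items() if r == "queen"}
    workers = [b for b in bees["bee_id"] if b not in queen_ids]
    idx = {b: k for k, b in enumerate(workers)}
    known = set(roles)
    delta = params.decay_rate

    lam_qw = np.zeros(len(workers))
    lam_ww = np.zeros(len(workers))
    last_t = np.zeros(len(workers))
    if initial_loads:
        for b, (q0, w0) in initial_loads.items():
            lam_qw[idx[b]] = q0
            lam_ww[idx[b]] = w0

    def decay_to(b: int, t: float) -> None:
        dt = t - last_t[b]
        if dt > 0 and delta > 0:
            f = np.exp(-delta * dt)
            lam_qw[b] *= f
            lam_ww[b] *= f
        last_t[b] = max(last_t[b], t)

    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        out_qw = np.zeros((len(grid), len(workers)))
        out_ww = np.zeros((len(grid), len(workers)))
        gptr = 0
    else:
        out_qw = out_ww = None
        gptr = None

    def snapshot_until(t: float) -> None:
        nonlocal gptr
        if grid is None:
            return
        while gptr < len(grid) and grid[gptr] < t:
            g = grid[gptr]
            dtv = np.maximum(g - last_t, 0.0)
            f = np.exp(-delta * dtv) if delta > 0 else 1.0
            out_qw[gptr] = lam_qw * f
            out_ww[gptr] = lam_ww * f
            gptr += 1

    def transfer(donor, receiver, t0, tau, mode, weight=1.0):
        """Apply a one-directional transfer; returns the event record."""
        if donor in queen_ids:
            removed, acquired = integrate_contact(0.0, tau, mode, params, True)
            removed *= weight
            acquired = params.ingestion_fraction * removed
            r = idx[receiver]
            decay_to(r, t0 + tau)
            lam_qw[r] += acquired
        else:
            d = idx[donor]
            decay_to(d, t0)
            lam0 = lam_qw[d] + lam_ww[d]
            removed, acquired = integrate_contact(lam0, tau, mode, params, False)
            removed *= weight
            acquired = params.ingestion_fraction * removed
            if lam0 > 0:
                frac = removed / lam0
                lam_qw[d] -= lam_qw[d] * frac
                lam_ww[d] -= lam_ww[d] * frac
            last_t[d] = t0 + tau
            if receiver in queen_ids:
                # the queen's load is clamped: she retains nothing, so the
                # removed amount vanishes and no relay flow is credited
                acquired = 0.0
            else:
                r = idx[receiver]
                decay_to(r, t0 + tau)
                lam_ww[r] += acquired
        return {
            "t_s": t0, "donor": donor, "receiver": receiver, "mode": mode,
            "removed_pg": removed, "acquired_pg": acquired,
        }

    events: list[dict] = []
    for c_idx, c in enumerate(contacts.itertuples()):
        if c.i not in known or c.j not in known:
            raise ValueError(f"contact references unknown bee: {c.i!r}/{c.j!r}")
        t0 = float(c.t_start_s)
        tau = float(c.t_end_s) - t0
        if tau <= 0:
            continue
        snapshot_until(t0)
        i_insp = c.frac_frames_i_inspects >= 0.5 and c.frac_frames_i_inspects > 0
        j_insp = c.frac_frames_j_inspects >= 0.5 and c.frac_frames_j_inspects > 0
        if not (i_insp or j_insp):
            continue
        if redraw_per_frame:
            n_fr = max(int(round(tau * frame_rate)), 1)
            p = float(lick_probability(tau, params))
            n_lick = int(rng.binomial(n_fr, p))
            segs = []
            if n_lick:
                segs.append(("lick", tau * n_lick / n_fr))
            if n_fr - n_lick:
                segs.append(("antennate", tau * (n_fr - n_lick) / n_fr))
        else:
            mode = "lick" if mode_u[c_idx] < lick_probability(tau, params) else "antennate"
            segs = [(mode, tau)]

        if i_insp and j_insp:
            # mutual inspection: donor is the currently more loaded bee
            def load_of(b):
                if b in queen_ids:
                    return params.lambda_queen
                k = idx[b]
                decay_to(k, t0)
                return lam_qw[k] + lam_ww[k]

            li, lj = load_of(c.i), load_of(c.j)
            if np.isclose(li, lj):
                pairs = [(c.i, c.j, 0.5), (c.j, c.i, 0.5)]
            elif li > lj:
                pairs = [(c.i, c.j, 1.0)]
            else:
                pairs = [(c.j, c.i, 1.0)]
        elif i_insp:
            pairs = [(c.j, c.i, 1.0)]
        else:
            pairs = [(c.i, c.j, 1.0)]

        for donor, receiver, weight in pairs:
            if donor not in queen_ids and idx[donor] is not None:
                d = idx[donor]
                decay_to(d, t0)
                if lam_qw[d] + lam_ww[d] <= 0:
                    continue  # nothing to transfer
            for mode, seg_tau in segs:
                ev = transfer(donor, receiver, t0, seg_tau, mode, weight)
                if ev["removed_pg"] > 0:
                    events.append(ev)
    snapshot_until(np.inf)
    series = (
        LoadSeries(grid=grid, bee_ids=workers, lam_qw=out_qw, lam_ww=out_ww)
        if grid is not None
        else None
    )
    return events, series


@dataclass
class EnsembleResult:
    """Ensemble-averaged load series and per-pair transfer totals."""

    grid: np.ndarray
    bee_ids: list
    mean_qw: np.ndarray          # (n_times, n_bees) ensemble means
    mean_ww: np.ndarray
    pair_flow: dict              # (donor, receiver) -> Q = Σ acquired / S
    n_sims: int

    @property
    def mean_load(self) -> np.ndarray:
        return self.mean_qw + self.mean_ww

    def informed_mask(self, params: TransmissionParams) -> np.ndarray:
        """Boolean (n_times, n_bees): ensemble-mean load above λ_min."""
        return self.mean_load > params.lambda_min


def run_ensemble(
    contacts: pd.DataFrame,
    bees: pd.DataFrame,
    params: TransmissionParams,
    grid: np.ndarray,
    seed: int | np.random.SeedSequence | None = None,
    initial_loads: dict | None = None,
    collect_events: bool = False,
) -> EnsembleResult | tuple[EnsembleResult, list[list[dict]]]:
    """Run ``params.n_sims`` seeded replicates and average them.

    Informed status downstream is computed on the ensemble-*mean* loads,
    matching the averaging of the audience measures across runs.
    """
    if params.n_sims < 1:
        raise ValueError("need at least one simulation")
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    children = root.spawn(params.n_sims)
    sum_qw = sum_ww = None
    pair_flow: dict = {}
    all_events = []
    bee_ids = None
    for ss in children:
        events, series = run_transmission(
            contacts, bees, params, seed=ss, grid=grid, initial_loads=initial_loads
        )
        if sum_qw is None:
            sum_qw = series.lam_qw.copy()
            sum_ww = series.lam_ww.copy()
            bee_ids = series.bee_ids
        else:
            sum_qw += series.lam_qw
            sum_ww += series.lam_ww
        for ev in events:
            key = (ev["donor"], ev["receiver"])
            pair_flow[key] = pair_flow.get(key, 0.0) + ev["acquired_pg"]
        if collect_events:
            all_events.append(events)
    S = params.n_sims
    result = EnsembleResult(
        grid=np.asarray(grid, dtype=float),
        bee_ids=bee_ids,
        mean_qw=sum_qw / S,
        mean_ww=sum_ww / S,
        pair_flow={k: v / S for k, v in pair_flow.items()},
        n_sims=S,
    )
    if collect_events:
        return result, all_events
    return result
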