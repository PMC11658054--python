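"""Shared fixtures: small synthetic colonies and scaled study conditions.

The "study colony" is an 80-worker, 40-minute synthetic day (four cohorts
aged 14, 8, 4 and 2 days) used by the end-to-end and acceptance tests;
generating it and detecting its contacts takes tens of seconds, so it is
session-scoped.  Scaled-day transmission parameters use a faster decay
(δ = 3e-3 /s) so that load attrition is observable within the shortened
day; experiments probing 5-minute windows use the default profile.
"""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from queenrelay.contact_geometry import detect_contacts
from queenrelay.synthetic_colony import ColonyConfig, generate_colony_day
from queenrelay.transmission_engine import TransmissionParams

STUDY_COMB = (48.0, 32.0)
STUDY_DAY = 14


def study_config(seed: int = 11, n_per_cohort: int = 20) -> ColonyConfig:
    return ColonyConfig(
        cohort_schedule=((0, n_per_cohort), (6, n_per_cohort),
                         (10, n_per_cohort), (12, n_per_cohort)),
        day_length_s=2400.0,
        seed=seed,
        comb_width=STUDY_COMB[0],
        comb_height=STUDY_COMB[1],
        broodnest_centres=((18.0, 16.0, 0), (18.0, 16.0, 1)),
        broodnest_radius=14.0,
        side_switch_prob=0.02,
    )


@pytest.fixture(scope="session")
def study_colony():
    cfg = study_config()
    traj, bees, gt = generate_colony_day(cfg, STUDY_DAY)
    contacts = detect_contacts(traj, bees)
    groups = {
        "nurse": gt.workers[gt.workers.community.str.startswith("N")]["bee_id"].tolist(),
        "forager": gt.workers[gt.workers.community == "F"]["bee_id"].tolist(),
    }
    return SimpleNamespace(
        cfg=cfg, traj=traj, bees=bees, gt=gt, contacts=contacts,
        comb=STUDY_COMB, groups=groups,
        queen_contacts=contacts[(contacts["i"] == "queen") | (contacts["j"] == "queen")],
    )


@pytest.fixture(scope="session")
def scaled_params():
    """Scaled-day transmission profile (fast decay for a 40-min day)."""
    return TransmissionParams(n_sims=50, seed=5, decay_rate=3e-3)


@pytest.fixture(scope="session")
def default_params():
    return TransmissionParams(n_sims=50, seed=5)


@pytest.fixture(scope="session")
def tiny_colony():
    """A ~20-worker, 10-minute colony for fast integration checks."""
    cfg = ColonyConfig(
        cohort_schedule=((0, 6), (8, 7), (10, 7)),
        day_length_s=600.0,
        seed=3,
        comb_width=30.0,
        comb_height=20.0,
        broodnest_centres=((10.0, 10.0, 0), (10.0, 10.0, 1)),
        broodnest_radius=8.0,
    )
    traj, bees, gt = generate_colony_day(cfg, 12)
    contacts = detect_contacts(traj, bees)
    return SimpleNamespace(cfg=cfg, traj=traj, bees=bees, gt=gt,
                           contacts=contacts, comb=(30.0, 20.0))


def make_contacts(rows) -> pd.DataFrame:
    """Contact table from (i, j, t0, t1, fi, fj) tuples."""
    return pd.DataFrame(
        [
            {"i": i, "j": j, "t_start_s": t0, "t_end_s": t1, "side": 0,
             "frac_frames_i_inspects": fi, "frac_frames_j_inspects": fj}
            for i, j, t0, t1, fi, fj in rows
        ]
    )


def make_bees(workers, queen: bool = True) -> pd.DataFrame:
    rows = []
    if queen:
        rows.append({"bee_id": "queen", "role": "queen",
                     "eclosion_day": np.nan, "colony_id": "c"})
    for w in workers:
        rows.append({"bee_id": w, "role": "worker",
                     "eclosion_day": 0, "colony_id": "c"})
    return pd.DataFrame(rows)
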