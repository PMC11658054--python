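"""Daily contact networks, soft communities, relay networks and hierarchy.

Daily encounter networks (edge weight = number of physical contacts) are
factorised into three overlapping communities — two nurse groups, one per
broodnest patch, and the foragers — using a static per-day non-negative
factorisation with row-normalised soft membership scores.  A worker is a
nurse when N_A + N_B > 2/3 and a forager when F > 2/3; its bridging score
H′(N_A, N_B) is the normalised entropy of its two nurse affiliations.

Simulation-averaged pheromone transfers define the directed relay network
Q_{i→j} = Σ_s Σ_n q_n(i→j) / S, coarse-grained by age cohort into a net
flow network whose donation hierarchy is ranked with David's score.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from sklearn.decomposition import NMF

__all__ = [
    "build_contact_network",
    "soft_communities",
    "label_communities",
    "bridging_score",
    "classify_task_group",
    "build_relay_network",
    "coarse_grain_by_age",
    "dominance_ranks",
]

NURSE_THRESHOLD = 2.0 / 3.0
FORAGER_THRESHOLD = 2.0 / 3.0


def build_contact_network(contacts: pd.DataFrame) -> nx.Graph:
    """Undirected weighted daily encounter network (weight = contact count)."""
    g = nx.Graph()
    if contacts.empty:
        return g
    counts = contacts.groupby(["i", "j"]).size()
    for (i, j), w in counts.items():
        if i == j:
            continue
        if g.has_edge(i, j):
            g[i][j]["weight"] += int(w)
        else:
            g.add_edge(i, j, weight=int(w))
    return g


def soft_communities(
    network: nx.Graph, k: int = 3, seed: int = 0, n_restarts: int = 5
) -> pd.DataFrame:
    """Soft community scores via non-negative factorisation.

    The symmetrised, degree-normalised adjacency matrix is factorised as
    A ≈ W H with k components (multiplicative-update NMF, several random
    restarts, best reconstruction kept); membership is the row-normalised
    symmetric factor (W + Hᵀ)/2.  Each node's k scores sum to 1.

    Returns a DataFrame indexed by node with columns ``c0..c{k-1}``.
    """
    nodes = sorted(network.nodes)
    n = len(nodes)
    if k > n:
        raise ValueError("more communities than nodes")
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    An = A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]

    best_W = None
    best_err = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        model = NMF(
            n_components=k, init="random", solver="mu", max_iter=800,
            random_state=int(rng.integers(2**31)), tol=1e-6,
        )
        W = model.fit_transform(An)
        if model.reconstruction_err_ < best_err:
            best_err = model.reconstruction_err_
            best_W = (W + model.components_.T) / 2.0
    rows = best_W.copy()
    totals = rows.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    rows = rows / totals
    return pd.DataFrame(rows, index=pd.Index(nodes, name="bee_id"),
                        columns=[f"c{j}" for j in range(k)])


def label_communities(
    scores: pd.DataFrame,
    ages: dict,
    queen_id: str = "queen",
    patch_of: dict | None = None,
    entrance_occupancy: dict | None = None,
) -> pd.DataFrame:
    """Assign the k=3 communities to labels N_A, N_B and F.

    F is the community whose strongest members have the highest mean age
    (ties broken by entrance-corner occupancy); of the remaining two, N_A
    is the one containing more occupants of broodnest patch A (``patch_of``
    maps bee_id → 'A'/'B').  Deterministic given its inputs; raises when
    the age criterion is exactly ambiguous and no tie-break is available.

    Returns the scores with columns renamed to N_A, N_B, F (queen row
    retained if present).
    """
    if scores.shape[1] != 3:
        raise ValueError("labelling requires a k=3 factorisation")
    cols = list(scores.columns)
    assign = scores.idxmax(axis=1)
    mean_age = {}
    for c in cols:
        members = [b for b in scores.index if assign[b] == c and b in ages]
        mean_age[c] = float(np.mean([ages[b] for b in members])) if members else -np.inf
    ordered = sorted(cols, key=lambda c: mean_age[c], reverse=True)
    if mean_age[ordered[0]] == mean_age[ordered[1]]:
        if entrance_occupancy is None:
            raise ValueError("forager labelling ambiguous: supply entrance occupancy")
        occ = {
            c: float(
                np.mean(
                    [entrance_occupancy.get(b, 0.0) for b in scores.index if assign[b] == c]
                )
            )
            for c in cols
        }
        ordered = sorted(cols, key=lambda c: occ[c], reverse=True)
    f_col = ordered[0]
    nurse_cols = [c for c in cols if c != f_col]
    if patch_of:
        counts = {
            c: sum(
                1 for b in scores.index
                if assign[b] == c and patch_of.get(b) == "A"
            )
            for c in nurse_cols
        }
        nurse_cols = sorted(nurse_cols, key=lambda c: counts[c], reverse=True)
    mapping = {nurse_cols[0]: "N_A", nurse_cols[1]: "N_B", f_col: "F"}
    out = scores.rename(columns=mapping)
    return out[["N_A", "N_B", "F"]]


def bridging_score(n_a: float, n_b: float) -> float:
    """Normalised entropy of the two nurse affiliations, H′ ∈ [0, 1].

    The pair is renormalised to p = N_A/(N_A+N_B) and
    H′ = −[p ln p + (1−p) ln(1−p)] / ln 2 with 0·ln 0 = 0; equal
    affiliations give 1, single-community affiliation gives 0; missing
    when N_A + N_B = 0.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("affiliation scores must be non-negative")
    tot = n_a + n_b
    if tot == 0:
        return np.nan
    p = n_a / tot
    h = 0.0
    for q in (p, 1 - p):
        if q > 0:
            h -= q * np.log(q)
    return float(h / np.log(2.0))


def classify_task_group(labelled: pd.DataFrame) -> pd.DataFrame:
    """Nurse/forager flags and bridging scores from labelled affiliations.

    Adds columns ``group`` ∈ {nurse, forager, neither} (nurse when
    N_A + N_B > 2/3, forager when F > 2/3) and ``H_bridge``.
    """
    out = labelled.copy()
    nurse = (out["N_A"] + out["N_B"]) > NURSE_THRESHOLD
    forager = out["F"] > FORAGER_THRESHOLD
    out["group"] = np.where(nurse, "nurse", np.where(forager, "forager", "neither"))
    out["H_bridge"] = [
        bridging_score(a, b) for a, b in zip(out["N_A"], out["N_B"])
    ]
    return out


def build_relay_network(pair_flow: dict, nodes: list | None = None) -> nx.DiGraph:
    """Directed relay network from ensemble-mean per-pair transfers.

    ``pair_flow`` maps (donor, receiver) → Q_{i→j} in pg/day (already the
    ensemble mean Σ transfers / S).  Node attributes: out-degree ``k_out``
    (number of distinct receivers), in-degree ``k_in`` and ``dk`` =
    k_out − k_in.
    """
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for (i, j), q in pair_flow.items():
        if q > 0:
            g.add_edge(i, j, Q=float(q))
    for node in g.nodes:
        k_out = g.out_degree(node)
        k_in = g.in_degree(node)
        g.nodes[node]["k_out"] = k_out
        g.nodes[node]["k_in"] = k_in
        g.nodes[node]["dk"] = k_out - k_in
    return g


def coarse_grain_by_age(
    relay: nx.DiGraph,
    ages: dict,
    pool_callows: bool = True,
    queen_id: str = "queen",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Net pheromone flow between age cohorts.

    Cohort of a worker = its age in days, with 0–2 day-olds pooled as the
    callow node when ``pool_callows``.  Gross flow a→b sums Q over member
    pairs; the net flow keeps only the positive direction.  The queen is
    excluded.  Returns ``(gross, net)`` DataFrames with columns
    ``cohort_a, cohort_b, flow_pg`` / ``net_pg``.
    """

    def cohort(b):
        a = ages[b]
        return "0-2" if (pool_callows and a <= 2) else str(int(a))

    gross: dict[tuple[str, str], float] = {}
    for i, j, data in relay.edges(data=True):
        if i == queen_id or j == queen_id or i not in ages or j not in ages:
            continue
        ca, cb = cohort(i), cohort(j)
        if ca == cb:
            continue
        gross[(ca, cb)] = gross.get((ca, cb), 0.0) + data["Q"]
    gross_df = pd.DataFrame(
        [{"cohort_a": a, "cohort_b": b, "flow_pg": q} for (a, b), q in sorted(gross.items())]
    )
    net_rows = []
    seen = set()
    for (a, b) in gross:
        if (b, a) in seen or (a, b) in seen:
            continue
        seen.add((a, b))
        net = gross.get((a, b), 0.0) - gross.get((b, a), 0.0)
        if net > 0:
            net_rows.append({"cohort_a": a, "cohort_b": b, "net_pg": net})
        elif net < 0:
            net_rows.append({"cohort_a": b, "cohort_b": a, "net_pg": -net})
        # net == 0 → no edge
    net_df = pd.DataFrame(net_rows, columns=["cohort_a", "cohort_b", "net_pg"])
    return gross_df, net_df


def dominance_ranks(gross: pd.DataFrame) -> pd.DataFrame:
    """David's scores and ranks of the cohort donation hierarchy.

    Dyadic proportions P_ab = gross(a→b) / (gross(a→b) + gross(b→a)) play
    the role of win proportions; David's score DS = w + w₂ − l − l₂ where
    w_a = Σ_b P_ab, w₂ propagates opponents' w, and l mirrors losses.
    Cohorts are ranked by descending score, ties broken by total out-flow.
    """
    if gross.empty:
        raise ValueError("need flows between at least two cohorts")
    flows: dict[tuple[str, str], float] = {
        (r.cohort_a, r.cohort_b): r.flow_pg for r in gross.itertuples()
    }
    cohorts = sorted({c for ab in flows for c in ab})
    if len(cohorts) < 2:
        raise ValueError("need at least two cohorts")
    n = len(cohorts)
    P = np.full((n, n), np.nan)
    for a_i, a in enumerate(cohorts):
        for b_i, b in enumerate(cohorts):
            if a_i == b_i:
                continue
            ab = flows.get((a, b), 0.0)
            ba = flows.get((b, a), 0.0)
            if ab + ba > 0:
                P[a_i, b_i] = ab / (ab + ba)
    Pz = np.nan_to_num(P)
    w = Pz.sum(axis=1)
    l = Pz.sum(axis=0)
    w2 = Pz @ w
    l2 = Pz.T @ l
    ds = w + w2 - l - l2
    out_flow = np.array(
        [sum(q for (a, _), q in flows.items() if a == c) for c in cohorts]
    )
    df = pd.DataFrame(
        {"cohort": cohorts, "david_score": ds, "total_out_pg": out_flow}
    )
    df = df.sort_values(
        ["david_score", "total_out_pg"], ascending=[False, False]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
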