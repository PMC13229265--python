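"""Weighted contact graphs and the sensor-network statistics built on them.

Each deployment is treated as an independent measurement: all contacts inside
its window are aggregated into a static weighted graph whose edge weight is the
total time (seconds) the two sensors spent in proximity. On top of that graph
the module computes strength centrality (weighted degree, reported in hours),
the per-node Gini coefficient of edge weights (interaction selectivity),
per-day strength tables, daily-strength CDFs with zero-contact-day accounting,
Kolmogorov–Smirnov comparisons between deployments, and group contact matrices
in raw and per-pair-rescaled form.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.distributions.empirical_distribution import ECDF

from .io import SECONDS_PER_DAY, DeploymentWindow, day_of, filter_window

SECONDS_PER_HOUR = 3600.0


def present_sensors(roster: pd.DataFrame, window: DeploymentWindow) -> pd.Index:
    """Sensors whose roster presence span overlaps the window at all."""
    overlap = (roster["first_day"] < window.end_day) & (roster["last_day"] >= window.start_day)
    return roster.index[overlap]


def aggregate_graph(
    contacts: pd.DataFrame,
    window: DeploymentWindow,
    roster: pd.DataFrame,
    prefiltered: bool = False,
) -> nx.Graph:
    """Aggregate a deployment's contacts into a weighted graph.

    Nodes are all sensors present during the window (isolates included), with
    roster attributes attached; edge ``weight`` is total contact seconds.
    """
    if not prefiltered:
        contacts = filter_window(contacts, window, roster)
    weights = (
        contacts.assign(seconds=contacts["duration"])
        .groupby(["i", "j"], sort=True)["seconds"]
        .sum()
    )
    G = nx.Graph(deployment_label=window.label)
    for sensor in present_sensors(roster, window):
        row = roster.loc[sensor]
        G.add_node(
            sensor,
            kind=row["kind"],
            group=row["group"] if pd.notna(row["group"]) else None,
            room_category=row["room_category"] if pd.notna(row["room_category"]) else None,
        )
    for (i, j), w in weights.items():
        if i not in G or j not in G:
            continue
        G.add_edge(i, j, weight=float(w))
    return G


def _incident_weights(G: nx.Graph, node: str, include_rooms: bool) -> list[float]:
    out = []
    for nbr, data in G[node].items():
        if not include_rooms and G.nodes[nbr].get("kind") == "room":
            continue
        out.append(data["weight"])
    return out


def strength(G: nx.Graph, node: str, include_rooms: bool = True) -> float:
    """Strength centrality: summed incident edge weight, in hours."""
    if node not in G:
        raise KeyError(f"node {node!r} not in graph")
    return sum(_incident_weights(G, node, include_rooms)) / SECONDS_PER_HOUR


def strength_table(G: nx.Graph, include_rooms: bool = True) -> pd.Series:
    return pd.Series(
        {n: strength(G, n, include_rooms) for n in G.nodes}, name="strength_hours"
    ).sort_index()


def gini(weights) -> float:
    """Population Gini coefficient of a weight vector.

    ``G = sum_ij |w_i - w_j| / (2 n^2 mean(w))``; 0 means perfectly even
    interaction time, values near 1 mean time dominated by a single partner.
    Zero total weight leaves the coefficient undefined.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 2:
        raise ValueError("Gini needs at least two potential partners")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("Gini undefined for zero total weight")
    w = np.sort(w)
    n = w.size
    ranks = np.arange(1, n + 1)
    return float(2.0 * (ranks * w).sum() / (n * total) - (n + 1) / n)


def node_gini(
    G: nx.Graph,
    node: str,
    include_rooms: bool = False,
    partner_scope: list[str] | None = None,
) -> float:
    """Gini of one node's partner-weight distribution.

    The partner scope defaults to every other wearable sensor present in the
    deployment graph; pairs with no recorded contact enter as zero weight, so a
    member who only ever talks to one crewmate scores high even though most of
    their possible edges are silent. Rooms are excluded by default because the
    coefficient is read as interpersonal selectivity.
    """
    if node not in G:
        raise KeyError(f"node {node!r} not in graph")
    if partner_scope is None:
        partner_scope = [
            n
            for n in G.nodes
            if n != node and (include_rooms or G.nodes[n].get("kind") == "person")
        ]
    weights = [G[node][p]["weight"] if G.has_edge(node, p) else 0.0 for p in partner_scope]
    return gini(weights)


def daily_strength(
    contacts: pd.DataFrame,
    roster: pd.DataFrame,
    windows: list[DeploymentWindow],
    include_rooms: bool = True,
    day_start_hour: int = 0,
) -> pd.DataFrame:
    """Per-sensor per-day strength across all deployments.

    Returns tidy rows ``(sensor_id, kind, deployment, day, present,
    strength_hours)``. Days outside a sensor's roster presence span are marked
    ``present=False`` with missing strength — distinguishing "not there" from
    "there but zero contacts", which drives the zero-contact-day accounting.
    """
    contacts = contacts.copy()
    contacts["day"] = day_of(contacts["t"].to_numpy(), day_start_hour)
    rows = []
    for w in windows:
        sub = filter_window(contacts, w, roster, day_start_hour)
        sub_day = day_of(sub["t"].to_numpy(), day_start_hour)
        per = []
        for end, other in ((sub["i"], sub["j"]), (sub["j"], sub["i"])):
            d = pd.DataFrame(
                {
                    "sensor_id": end.to_numpy(),
                    "partner": other.to_numpy(),
                    "day": sub_day,
                    "seconds": sub["duration"].to_numpy(),
                }
            )
            per.append(d)
        both = pd.concat(per, ignore_index=True) if per else pd.DataFrame()
        if not both.empty and not include_rooms:
            partner_kind = roster["kind"].reindex(both["partner"]).to_numpy()
            both = both.loc[partner_kind != "room"]
        agg = (
            both.groupby(["sensor_id", "day"])["seconds"].sum()
            if not both.empty
            else pd.Series(dtype=float)
        )
        for sensor in present_sensors(roster, w):
            first, last = roster.loc[sensor, ["first_day", "last_day"]]
            for day in w.days:
                present = first <= day <= last
                sec = float(agg.get((sensor, day), 0.0)) if present else np.nan
                rows.append(
                    {
                        "sensor_id": sensor,
                        "kind": roster.loc[sensor, "kind"],
                        "deployment": w.label,
                        "day": day,
                        "present": bool(present),
                        "strength_hours": sec / SECONDS_PER_HOUR if present else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def strength_cdf(daily: pd.DataFrame, sensor_class: str) -> ECDF:
    """Empirical CDF of daily strength (hours) for one sensor class.

    Right-continuous step function; its value at 0 is the zero-contact-day
    proportion for that class.
    """
    values = _class_daily_values(daily, sensor_class)
    if values.size == 0:
        raise ValueError(f"no present sensor-days for class {sensor_class!r}")
    return ECDF(values)


def _class_daily_values(daily: pd.DataFrame, sensor_class: str) -> np.ndarray:
    if sensor_class not in {"person", "room"}:
        raise ValueError("sensor_class must be 'person' or 'room'")
    sel = (daily["kind"] == sensor_class) & daily["present"]
    return daily.loc[sel, "strength_hours"].to_numpy(dtype=float)


def zero_day_fraction(daily: pd.DataFrame, sensor_class: str) -> float:
    """Proportion of present sensor-days with no recorded interaction."""
    values = _class_daily_values(daily, sensor_class)
    if values.size == 0:
        raise ValueError(f"no present sensor-days for class {sensor_class!r}")
    return float((values == 0).mean())


def compare_deployments_ks(values_a, values_b, method: str = "asymp"):
    """Two-sample Kolmogorov–Smirnov test between two strength samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("KS comparison needs at least two observations per sample")
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupContactMatrix:
    """Between/within-group contact totals, raw and per-possible-pair."""

    groups: list[str]
    sizes: dict[str, int]
    raw_hours: pd.DataFrame
    rescaled: pd.DataFrame


def group_contact_matrix(
    G: nx.Graph,
    grouping: str = "group",
    exclude_groups: tuple[str, ...] = (),
) -> GroupContactMatrix:
    """Contact matrix between person groups, raw hours and pair-rescaled.

    The rescaled matrix divides each cell by the number of possible interacting
    pairs: ``n_g * n_h`` off the diagonal and ``n_g * (n_g - 1) / 2`` on it, so
    cells are comparable across groups of different size. Diagonal entries for
    singleton groups are undefined (NaN). Room edges never enter.
    """
    persons = [n for n in G.nodes if G.nodes[n].get("kind") == "person"]
    labels = {}
    for n in persons:
        g = G.nodes[n].get(grouping)
        if g is None:
            raise ValueError(f"person node {n!r} has no {grouping!r} attribute")
        labels[n] = g
    groups = sorted(set(labels.values()) - set(exclude_groups))
    if not groups:
        raise ValueError("no groups left after exclusion")
    sizes = {g: sum(1 for n in persons if labels[n] == g) for g in groups}
    raw = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b, data in G.edges(data=True):
        if a not in labels or b not in labels:
            continue
        ga, gb = labels[a], labels[b]
        if ga not in sizes or gb not in sizes:
            continue
        raw.loc[ga, gb] += data["weight"]
        if ga != gb:
            raw.loc[gb, ga] += data["weight"]
    raw /= SECONDS_PER_HOUR
    pairs = pd.DataFrame(index=groups, columns=groups, dtype=float)
    for g in groups:
        for h in groups:
            if g == h:
                npairs = sizes[g] * (sizes[g] - 1) / 2
            else:
                npairs = sizes[g] * sizes[h]
            pairs.loc[g, h] = npairs if npairs > 0 else np.nan
    return GroupContactMatrix(groups, sizes, raw, raw / pairs)


def grouped_network(G: nx.Graph) -> nx.Graph:
    """Collapse a contact graph onto categories.

    Persons map to their nationality/affiliation group, rooms to their room
    category; the category-level edge weight (self-loops included) is the sum
    of all member-pair edge weights, so total weight is conserved.
    """
    def category(n):
        data = G.nodes[n]
        cat = data.get("group") if data.get("kind") == "person" else data.get("room_category")
        if cat is None:
            raise ValueError(f"node {n!r} has neither group nor room_category")
        return cat

    H = nx.Graph(deployment_label=G.graph.get("deployment_label"))
    for n in G.nodes:
        H.add_node(category(n))
    for a, b, data in G.edges(data=True):
        ca, cb = category(a), category(b)
        w = data["weight"]
        if H.has_edge(ca, cb):
            H[ca][cb]["weight"] += w
        else:
            H.add_edge(ca, cb, weight=w)
    return H


def edge_weight_entropy(G: nx.Graph, node: str, include_rooms: bool = False) -> float:
    """Shannon entropy (nats) of a node's normalized partner-weight shares.

    Optional companion to the Gini coefficient; low entropy likewise signals
    interaction time concentrated on few partners.
    """
    w = np.asarray(_incident_weights(G, node, include_rooms), dtype=float)
    w = w[w > 0]
    if w.size == 0:
        raise ValueError("entropy undefined for zero total weight")
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())
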