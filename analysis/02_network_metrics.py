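#!/usr/bin/env python
"""Aggregate contact networks per deployment and compute sensor metrics.

Reads the mission bundle, builds the four weighted contact graphs, and writes
per-deployment edge lists, node metric tables (strength in hours, Gini
selectivity), the per-day strength table, daily-strength CDF summaries with a
first-vs-last deployment Kolmogorov–Smirnov comparison, and raw/pair-rescaled
nationality contact matrices.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from crewnet import io, networks


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    contacts = io.read_contacts(args.data / "contacts.tsv")
    roster = io.read_roster(args.data / "roster.csv")
    windows = io.read_windows(args.data / "windows.csv")

    metric_rows = []
    for w in windows:
        G = networks.aggregate_graph(contacts, w, roster)
        pd.DataFrame(
            [(a, b, d["weight"]) for a, b, d in G.edges(data=True)],
            columns=["node_a", "node_b", "seconds"],
        ).to_csv(args.out / f"edges_{w.label}.csv", index=False)
        for person in sorted(n for n in G.nodes if G.nodes[n]["kind"] == "person"):
            try:
                g = networks.node_gini(G, person)
            except ValueError:
                g = np.nan
            metric_rows.append((person, w.label, networks.strength(G, person), g))
        m = networks.group_contact_matrix(G, exclude_groups=("ESA-MD",))
        m.raw_hours.to_csv(args.out / f"group_matrix_raw_{w.label}.csv")
        m.rescaled.to_csv(args.out / f"group_matrix_rescaled_{w.label}.csv")

    metrics = pd.DataFrame(metric_rows, columns=["person_id", "wave", "strength", "gini"])
    metrics.to_csv(args.out / "node_metrics.csv", index=False)

    daily = networks.daily_strength(contacts, roster, windows)
    daily.to_csv(args.out / "daily_strength.csv", index=False)

    person_daily = daily[(daily["kind"] == "person") & daily["present"]]
    a = person_daily.loc[person_daily["deployment"] == windows[0].label, "strength_hours"]
    b = person_daily.loc[person_daily["deployment"] == windows[-1].label, "strength_hours"]
    d_stat, p = networks.compare_deployments_ks(a, b)

    print("network metrics written to", args.out)
    print(f"  zero-contact days: person {networks.zero_day_fraction(daily, 'person'):.1%}, "
          f"room {networks.zero_day_fraction(daily, 'room'):.1%}")
    print(f"  KS {windows[0].label} vs {windows[-1].label} (person daily strength): "
          f"D={d_stat:.3f}, p={p:.2g}")
    for w in windows:
        r = pd.read_csv(args.out / f"group_matrix_rescaled_{w.label}.csv", index_col=0)
        ratio = np.nanmean(np.diag(r.to_numpy())) / r.loc["IT", "FR"]
        print(f"  {w.label}: rescaled within/cross contact ratio {ratio:.2f}")


if __name__ == "__main__":
    main()
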