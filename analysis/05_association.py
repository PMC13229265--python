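#!/usr/bin/env python
"""Link sensor metrics to psychological scores.

Merges the scored outcome panel with per-deployment strength and Gini, applies
person-mean centering, and writes the within-person and across-person Spearman
correlation matrices with significance marks (``***`` p<0.001, ``**`` p<0.01,
``*`` p<0.05, ``†`` p<0.10).
"""

import argparse
from pathlib import Path

import pandas as pd

from crewnet import association


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel.csv"))
    ap.add_argument("--metrics", type=Path, default=Path("results/network/node_metrics.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = pd.read_csv(args.panel, dtype={"person_id": str})
    metrics = pd.read_csv(args.metrics, dtype={"person_id": str})
    merged = association.merge_panel(panel, metrics)
    centered = association.person_center(merged)

    for scope in ("within_person", "across_person"):
        cm = association.correlation_heatmap_table(centered, scope=scope)
        cm.rho.round(3).to_csv(args.out / f"spearman_{scope}_rho.csv")
        cm.p.round(4).to_csv(args.out / f"spearman_{scope}_p.csv")
        cm.stars.to_csv(args.out / f"spearman_{scope}_stars.csv")

    cm = association.correlation_heatmap_table(centered, scope="within_person")
    print("within-person Spearman correlations (pooled deviations):")
    annotated = cm.rho.round(2).astype(str) + cm.stars
    print(annotated.to_string())
    n = cm.n.to_numpy()
    print(f"pairs per cell: {n[n > 0].min()}-{n.max()}")
    print(f"tables written to {args.out}/spearman_*.csv")


if __name__ == "__main__":
    main()
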