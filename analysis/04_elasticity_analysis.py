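#!/usr/bin/env python
"""Elasticity analysis across clusters and conservation status.

Per-species eigenvalue elasticities are summed into survival, growth,
and fertility processes and compared across clusters (restricted to
clusters with at least 5 species) and between listed and nonlisted
species via medians and reflected-kernel density curves on [0, 1].
"""

from pathlib import Path

import pandas as pd

from plantdemog import elasticity as el
from plantdemog.pipeline import PipelineConfig, filter_records
from plantdemog.records import read_records

DATA = Path("results/data")
CLUSTERS = Path("results/clustering")
OUT = Path("results/elasticity")
MIN_CLUSTER = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_records(DATA / "records.json", "json")
    accepted, _, _ = filter_records(records, PipelineConfig())
    labels = pd.read_csv(CLUSTERS / "clusters.csv", index_col=0)["cluster"]

    table = el.elasticity_table(accepted)
    table["cluster"] = labels.reindex(table.index)
    table.to_csv(OUT / "elasticities.csv")

    sizes = labels.value_counts()
    kept = {int(c) for c in sizes.index[sizes >= MIN_CLUSTER]}
    print(f"clusters compared (>= {MIN_CLUSTER} species): {sorted(kept)}")
    summary, curves, grid = el.elasticity_density_summary(
        table, labels, clusters_kept=kept)
    summary.to_csv(OUT / "density_summary.csv", index=False)
    rows = []
    for (cluster, listed, process), dens in curves.items():
        for x, d in zip(grid, dens):
            rows.append({"cluster": cluster, "listed": listed,
                         "process": process, "x": x, "density": d})
    pd.DataFrame(rows).to_csv(OUT / "density_curves.csv", index=False)

    medians = summary.pivot_table(index="cluster", columns="process",
                                  values="median", aggfunc="mean").round(3)
    print("median elasticity by cluster (listed and nonlisted pooled):")
    print(medians)


if __name__ == "__main__":
    main()
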