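#!/usr/bin/env python
"""Screen the records and extract life-history traits.

Applies the nine eligibility conditions (natural conditions, A = T + F
decomposition, annual periodicity, >= 2 stages, survival issue < 1.05,
irreducibility, ...), then computes lambda and the six demographic
traits (Lmax, H, Lalpha, Lmean, S, Ro) per accepted species and the
min-max-normalized trait table used by the clustering.
"""

from pathlib import Path

import pandas as pd

from plantdemog.lifetable import normalize_trait_table, trait_table
from plantdemog.pipeline import PipelineConfig, filter_records
from plantdemog.records import CONDITION_DESCRIPTIONS, read_records

DATA = Path("results/data")
OUT = Path("results/traits")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_records(DATA / "records.json", "json")
    accepted, counts, _ = filter_records(records, PipelineConfig())
    pd.DataFrame(
        [{"condition": c, "description": CONDITION_DESCRIPTIONS[c],
          "n_rejections": counts[c]} for c in sorted(counts)]
    ).to_csv(OUT / "filter_report.csv", index=False)
    print(f"{len(accepted)}/{len(records)} records pass all nine conditions")

    traits = trait_table(accepted)
    traits.to_csv(OUT / "traits.csv")
    normalize_trait_table(traits).to_csv(OUT / "traits_normalized.csv")
    print(traits.drop(columns="listed").describe().loc[["min", "50%", "max"]].round(3))
    print(f"trait tables written to {OUT}/")


if __name__ == "__main__":
    main()
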