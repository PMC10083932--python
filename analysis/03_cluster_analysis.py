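#!/usr/bin/env python
"""Cluster species by life history and test the groups.

Bray-Curtis dissimilarities on the normalized traits, UPGMA dendrogram
cut at height 0.3 (sanity-checked against the K-means elbow), global
and pairwise PERMANOVA across the resulting clusters, and a PCA showing
which traits dominate the ordination.
"""

from pathlib import Path

import pandas as pd

from plantdemog import cluster as cl
from plantdemog.lifetable import TRAIT_COLUMNS
from plantdemog.pipeline import stage_seed

SEED = 20220524
TRAITS = Path("results/traits")
OUT = Path("results/clustering")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    X = pd.read_csv(TRAITS / "traits_normalized.csv", index_col=0)[TRAIT_COLUMNS]
    D = cl.bray_curtis(X)
    pd.DataFrame(D, index=X.index, columns=X.index).to_csv(OUT / "bray_curtis.csv")

    dend = cl.upgma(D, labels=list(X.index))
    (OUT / "dendrogram.nwk").write_text(cl.dendrogram_to_newick(dend))
    labels = cl.cut_dendrogram(dend, height=0.3)
    labels.to_frame().to_csv(OUT / "clusters.csv")
    k, profile = cl.select_k(X.to_numpy(), range(1, 9), seed=stage_seed(SEED, "kmeans"))
    profile.to_csv(OUT / "kmeans_profile.csv", index=False)
    print(f"cut at 0.3 gives {labels.nunique()} clusters "
          f"(sizes: {labels.value_counts().sort_index().to_dict()}); "
          f"K-means elbow recommends k={k}")

    f_stat, p = cl.permanova(D, labels.to_numpy(), n_perm=999,
                             seed=stage_seed(SEED, "permanova"))
    print(f"global PERMANOVA: pseudo-F = {f_stat:.2f}, p = {p:.4f}")
    pd.DataFrame([{"pseudo_F": f_stat, "p_value": p}]).to_csv(
        OUT / "permanova_global.csv", index=False)
    pairwise = cl.pairwise_permanova(D, labels.to_numpy(), n_perm=999,
                                     seed=stage_seed(SEED, "permanova_pairwise"))
    pairwise.to_csv(OUT / "permanova_pairwise.csv", index=False)

    loadings, scores, varexp = cl.pca(X)
    loadings.to_csv(OUT / "pca_loadings.csv")
    pd.DataFrame(scores, index=X.index,
                 columns=[f"PC{i+1}" for i in range(scores.shape[1])]
                 ).to_csv(OUT / "pca_scores.csv")
    pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(varexp))],
                  "variance_pct": varexp}).to_csv(OUT / "pca_variance.csv", index=False)
    print("PCA variance explained (%):", [round(v, 1) for v in varexp[:3]], "...")
    top = loadings["PC1"].abs().sort_values(ascending=False).head(3)
    print("traits dominating PC1:", list(top.index))


if __name__ == "__main__":
    main()
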