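"""Eigenvalue elasticities of population growth and their decomposition
into survival, growth, and fertility processes.

The elasticity ``e_ij = (a_ij / lam) * d lam / d a_ij`` measures the
proportional response of the asymptotic growth rate to a proportional
perturbation of one matrix element.  Elasticities of a single matrix sum
to one (de Kroon et al.), so grouped sums are comparable across species
with different stage structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .records import ProjectionMatrixRecord, dominant_eigen

__all__ = [
    "ElasticityDecomposition",
    "elasticity_matrix",
    "group_elasticities",
    "elasticity_table",
    "elasticity_density_summary",
]

PROCESSES = ("survival", "growth", "fertility")


@dataclass
class ElasticityDecomposition:
    """Per-element elasticity matrix E and its process-grouped sums."""

    E: np.ndarray
    groups: dict[str, float] | None = None
    species_id: str | None = None


def elasticity_matrix(rec: ProjectionMatrixRecord) -> ElasticityDecomposition:
    """Elasticity of lam to every element of the projection matrix.

    Sensitivities come from the dominant eigen-pair,
    ``s_ij = v_i w_j / <v, w>``; elasticities scale by ``a_ij / lam``.
    Structural zeros of A have elasticity exactly zero.
    """
    eig = dominant_eigen(rec.A)
    # <v, w> = 1 by the EigenTriple normalization
    S = np.outer(eig.v, eig.w)
    E = (rec.A / eig.lam) * S
    E[rec.A == 0] = 0.0
    return ElasticityDecomposition(E=E, species_id=rec.species_id)


def group_elasticities(
    E: np.ndarray,
    T: np.ndarray,
    F: np.ndarray,
    retrogression_in: str = "survival",
) -> dict[str, float]:
    """Sum elasticities into survival, growth, and fertility processes.

    Fertility takes the positions where F is positive; among the
    remaining T-positions, progression to later stages (below-diagonal,
    i > j) counts as growth and stasis (diagonal) as survival.
    Retrogression (above-diagonal shrinkage, i < j) goes with survival
    by default but may be grouped with growth instead.  Positions
    positive in both T and F split their elasticity in proportion to
    T:F so the three sums still total one.
    """
    if retrogression_in not in ("survival", "growth"):
        raise ValueError("retrogression_in must be 'survival' or 'growth'")
    E = np.asarray(E, dtype=float)
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    n = E.shape[0]
    i_idx, j_idx = np.indices((n, n))
    denom = T + F
    with np.errstate(invalid="ignore", divide="ignore"):
        t_share = np.where(denom > 0, T / np.where(denom > 0, denom, 1.0), 0.0)
    f_share = np.where(denom > 0, 1.0 - t_share, 0.0)
    fertility = float((E * f_share * (F > 0)).sum())
    e_T = E * np.where(F > 0, t_share, 1.0) * (T > 0)
    prog = i_idx > j_idx
    stasis = i_idx == j_idx
    retro = i_idx < j_idx
    growth = float(e_T[prog].sum())
    survival = float(e_T[stasis].sum())
    retro_sum = float(e_T[retro].sum())
    if retrogression_in == "survival":
        survival += retro_sum
    else:
        growth += retro_sum
    return {"survival": survival, "growth": growth, "fertility": fertility}


def elasticity_table(
    records, retrogression_in: str = "survival"
) -> pd.DataFrame:
    """Grouped elasticities for a collection of records, indexed by
    species_id with the listing flag carried along."""
    rows = []
    for rec in records:
        dec = elasticity_matrix(rec)
        groups = group_elasticities(dec.E, rec.T, rec.F, retrogression_in)
        rows.append(
            {
                "species_id": rec.species_id,
                "listed": rec.listed,
                "e_survival": groups["survival"],
                "e_growth": groups["growth"],
                "e_fertility": groups["fertility"],
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


def _reflected_kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray | None:
    """Gaussian KDE (Silverman bandwidth) with boundary reflection on
    [0, 1]; elasticities are bounded so unreflected kernels leak mass."""
    if len(values) < 2 or np.allclose(values, values[0]):
        return None
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return dens


def elasticity_density_summary(
    elasticities: pd.DataFrame,
    cluster_labels: pd.Series,
    clusters_kept: set[int] | None = None,
    grid_size: int = 256,
) -> tuple[pd.DataFrame, dict[tuple, np.ndarray], np.ndarray]:
    """Density curves and medians of grouped elasticities per
    (cluster x listing x process) stratum.

    Strata outside ``clusters_kept`` (when given) are excluded; the
    comparative analysis typically restricts to the few largest
    clusters, the rest having too few species for a robust comparison.
    Strata with fewer than two species report a median but no density.

    Returns (summary table, {stratum key: density curve}, x grid).
    """
    labels = cluster_labels.reindex(elasticities.index)
    if labels.isna().any():
        missing = list(elasticities.index[labels.isna()])
        raise ValueError(f"cluster labels missing for species: {missing}")
    grid = np.linspace(0.0, 1.0, grid_size)
    rows = []
    curves: dict[tuple, np.ndarray] = {}
    for cluster in sorted(labels.unique()):
        if clusters_kept is not None and cluster not in clusters_kept:
            continue
        in_cluster = labels == cluster
        for listed in (False, True):
            mask = in_cluster & (elasticities["listed"] == listed)
            if not mask.any():
                continue
            for process in PROCESSES:
                vals = elasticities.loc[mask, f"e_{process}"].to_numpy()
                dens = _reflected_kde(vals, grid)
                if dens is not None:
                    curves[(cluster, listed, process)] = dens
                rows.append(
                    {
                        "cluster": cluster,
                        "listed": listed,
                        "process": process,
                        "n_species": int(mask.sum()),
                        "median": float(np.median(vals)),
                        "min": float(vals.min()),
                        "max": float(vals.max()),
                        "has_density": dens is not None,
                    }
                )
    return pd.DataFrame(rows), curves, grid
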