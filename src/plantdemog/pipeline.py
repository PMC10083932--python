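"""Pipeline orchestration: filter -> traits -> normalize -> cluster ->
PERMANOVA/PCA -> elasticities -> densities -> phylogenetic signal.

A single config object (YAML-loadable) carries every knob; the default
values are the analysis conventions used throughout: longevity
criterion 0.01, dendrogram cut 0.3, survival-issue limit 1.05, one
million MCMC generations with 20% burn-in, ESS convergence threshold
200.  One master seed fans out deterministically to per-stage seeds so
the whole artifact bundle is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import elasticity as el
from . import lifetable as lt
from . import phylo
from .records import CONDITION_DESCRIPTIONS, read_records, validate_record

logger = logging.getLogger("plantdemog")

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    records_path: str | None = None
    records_format: str = "json"
    tree_path: str | None = None
    output_dir: str = "results/pipeline"
    # eligibility filter: conditions 1-9 individually toggleable
    conditions_enabled: list[int] = field(default_factory=lambda: list(range(1, 10)))
    # trait extraction
    w0_convention: str = "first_stage"
    lx_tol: float = 1e-7
    x_cap: int = 1000
    lmax_crit: float = 0.01
    # clustering
    cut_height: float = 0.3
    k_min: int = 1
    k_max: int = 10
    kmeans_n_init: int = 10
    n_perm: int = 999
    # elasticity grouping / densities
    retrogression_in: str = "survival"
    min_cluster_size: int = 5
    # phylogenetic signal
    mcmc_n_gen: int = 1_000_000
    mcmc_burn_in_frac: float = 0.2
    mcmc_thin: int = 100
    ess_threshold: float = 200.0
    # reproducibility
    seed: int = 0

    def trait_options(self) -> lt.TraitOptions:
        return lt.TraitOptions(
            w0_convention=self.w0_convention,
            lx_tol=self.lx_tol,
            x_cap=self.x_cap,
            lmax_crit=self.lmax_crit,
        )


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (kept
    below 2**31 so any consumer accepts it)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; unspecified fields take the defaults above,
    unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    for fld in dataclasses.fields(PipelineConfig):
        val = getattr(cfg, fld.name)
        if val is None or fld.name in ("conditions_enabled",):
            continue
        expected = {
            "records_path": str, "records_format": str, "tree_path": str,
            "output_dir": str, "w0_convention": str, "retrogression_in": str,
        }.get(fld.name)
        if expected and not isinstance(val, expected):
            raise ValueError(f"config key '{fld.name}': expected {expected.__name__}")
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)))


def filter_records(records, cfg: PipelineConfig):
    """Apply the eligibility screen; returns (accepted records,
    per-condition rejection counts, per-record violation lists)."""
    enabled = set(cfg.conditions_enabled)
    accepted = []
    counts = {c: 0 for c in range(1, 10)}
    details = {}
    for rec in records:
        violations = [v for v in validate_record(rec) if v in enabled]
        details[rec.species_id] = violations
        for v in violations:
            counts[v] += 1
        if not violations:
            accepted.append(rec)
    return accepted, counts, details


def run_pipeline(cfg: PipelineConfig, records=None, tree=None) -> dict:
    """Run every stage and write the artifact bundle under
    ``cfg.output_dir``.  Records/tree may be passed in memory (as the
    analysis drivers do) or read from the configured paths.  The
    phylogenetic-signal stage is skipped with a logged notice when no
    tree is available.  Returns a dict of the in-memory artifacts."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    try:
        if records is None:
            if cfg.records_path is None:
                raise ValueError("no records supplied and no records_path configured")
            records = read_records(cfg.records_path, cfg.records_format)
        if tree is None and cfg.tree_path:
            tree = phylo.read_tree(cfg.tree_path)

        # --- filter ---------------------------------------------------
        accepted, counts, details = filter_records(records, cfg)
        logger.info("filter: %d records in, %d accepted", len(records), len(accepted))
        report = pd.DataFrame(
            [
                {"condition": c, "description": d, "n_rejections": counts[c]}
                for c, d in sorted(CONDITION_DESCRIPTIONS.items())
            ]
        )
        report.to_csv(out / "filter_report.csv", index=False)
        artifacts["filter_counts"] = counts
        artifacts["accepted"] = accepted
        if not accepted:
            logger.warning("no records passed the filter; writing empty trait table")
            pd.DataFrame(columns=["listed", *lt.TRAIT_COLUMNS]).to_csv(out / "traits.csv")
            _write_manifest(cfg, out, stages_done=["filter"])
            return artifacts

        # --- traits ---------------------------------------------------
        traits = lt.trait_table(accepted, cfg.trait_options())
        traits.to_csv(out / "traits.csv")
        normalized = lt.normalize_trait_table(traits)
        normalized.to_csv(out / "traits_normalized.csv")
        artifacts["traits"] = traits
        artifacts["traits_normalized"] = normalized

        # --- clustering -----------------------------------------------
        X = normalized[lt.TRAIT_COLUMNS]
        D = cl.bray_curtis(X)
        pd.DataFrame(D, index=X.index, columns=X.index).to_csv(out / "bray_curtis.csv")
        dend = cl.upgma(D, labels=list(X.index))
        (out / "dendrogram.nwk").write_text(cl.dendrogram_to_newick(dend))
        labels = cl.cut_dendrogram(dend, height=cfg.cut_height)
        labels.to_frame().to_csv(out / "clusters.csv")
        k_rec, profile = cl.select_k(
            X.to_numpy(),
            range(cfg.k_min, min(cfg.k_max, len(X) - 1) + 1),
            n_init=cfg.kmeans_n_init,
            seed=stage_seed(cfg.seed, "kmeans"),
        )
        profile.to_csv(out / "kmeans_profile.csv", index=False)
        artifacts["clusters"] = labels
        artifacts["k_recommended"] = k_rec

        # --- PERMANOVA / PCA ------------------------------------------
        if labels.nunique() >= 2:
            f_global, p_global = cl.permanova(
                D, labels.to_numpy(), n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, "permanova"),
            )
            pairwise = cl.pairwise_permanova(
                D, labels.to_numpy(), n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, "permanova_pairwise"),
            )
            pd.DataFrame(
                [{"pseudo_F": f_global, "p_value": p_global}]
            ).to_csv(out / "permanova_global.csv", index=False)
            pairwise.to_csv(out / "permanova_pairwise.csv", index=False)
            artifacts["permanova"] = (f_global, p_global)
            artifacts["permanova_pairwise"] = pairwise
        else:
            logger.info("single cluster: PERMANOVA skipped")
        loadings, scores, varexp = cl.pca(X)
        loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            scores, index=X.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ).to_csv(out / "pca_scores.csv")
        pd.DataFrame(
            {"component": [f"PC{i + 1}" for i in range(len(varexp))],
             "variance_pct": varexp}
        ).to_csv(out / "pca_variance.csv", index=False)
        artifacts["pca_variance"] = varexp

        # --- elasticities ---------------------------------------------
        etable = el.elasticity_table(accepted, cfg.retrogression_in)
        etable["cluster"] = labels.reindex(etable.index)
        etable.to_csv(out / "elasticities.csv")
        sizes = labels.value_counts()
        kept = {int(c) for c in sizes.index[sizes >= cfg.min_cluster_size]}
        summary, curves, grid = el.elasticity_density_summary(
            etable, labels, clusters_kept=kept or None
        )
        summary.to_csv(out / "elasticity_density_summary.csv", index=False)
        dens_rows = []
        for (cluster_id, listed, process), dens in curves.items():
            for xval, dval in zip(grid, dens):
                dens_rows.append(
                    {"cluster": cluster_id, "listed": listed,
                     "process": process, "x": xval, "density": dval}
                )
        pd.DataFrame(dens_rows).to_csv(out / "elasticity_densities.csv", index=False)
        artifacts["elasticities"] = etable
        artifacts["elasticity_summary"] = summary

        # --- phylogenetic signal --------------------------------------
        if tree is not None:
            tree_tips = set(phylo.tip_labels(tree))
            species = [s for s in traits.index if s in tree_tips]
            missing = sorted(set(traits.index) - tree_tips)
            if missing:
                logger.info("species not in tree (skipped): %s", missing)
            sub = phylo.trim_tree(tree, set(species)) if species else None
            results = {}
            if sub is not None and len(species) >= 3:
                order = phylo.tip_labels(sub)
                for i, trait in enumerate(lt.TRAIT_COLUMNS):
                    if trait == "lam":
                        continue  # signal is assessed for the six traits
                    y = traits.loc[order, trait].to_numpy(dtype=float)
                    res = phylo.pagel_mcmc(
                        sub, y,
                        n_gen=cfg.mcmc_n_gen,
                        burn_in_frac=cfg.mcmc_burn_in_frac,
                        thin=cfg.mcmc_thin,
                        seed=stage_seed(cfg.seed, f"mcmc_{trait}"),
                        ess_threshold=cfg.ess_threshold,
                        trait=trait,
                    )
                    results[trait] = res
                    pd.DataFrame(
                        res.chain, columns=["lambda", "sigma2", "mu"]
                    ).to_csv(out / f"mcmc_chain_{trait}.csv", index=False)
                rows = [
                    {"trait": t, "eta": r.eta, "ci_lower": r.ci95[0],
                     "ci_upper": r.ci95[1], "ess": r.ess,
                     "converged": r.converged}
                    for t, r in results.items()
                ]
                pd.DataFrame(rows).to_csv(out / "phylo_signal.csv", index=False)
                artifacts["phylo_signal"] = results
            else:
                logger.info("too few species on tree; phylo stage skipped")
        else:
            logger.info("no tree supplied; phylo stage skipped")

        _write_manifest(cfg, out, stages_done=["all"])
        return artifacts
    except Exception:
        (out / "FAILED").write_text("pipeline aborted; see logs\n")
        raise


def _write_manifest(cfg: PipelineConfig, out: Path, stages_done: list[str]) -> None:
    cfg_dict = dataclasses.asdict(cfg)
    blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": cfg.seed,
        "stages_done": stages_done,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
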