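"""Phylogenetic signal of demographic traits: tree handling and Bayesian
Pagel's lambda under Brownian motion.

Pagel's lambda rescales the off-diagonal (shared-history) part of the
Brownian-motion covariance of tip values: lambda = 0 means traits are
phylogenetically independent, lambda = 1 means they evolved by plain
Brownian motion along the tree.  The posterior over
(lambda, sigma2, mu) is sampled by Metropolis-Hastings; convergence is
judged by the effective sample size of the lambda chain (ESS > 200 by
convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "read_tree",
    "write_tree",
    "trim_tree",
    "graft_missing",
    "tip_labels",
    "phylo_covariance",
    "bm_loglik",
    "pagel_mcmc",
    "ess",
    "PhyloSignalResult",
]


def read_tree(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    if source.strip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def trim_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on the tip set ``keep``.

    Degree-2 internal nodes left by pruning are suppressed with branch
    lengths summed, so root-to-tip path lengths of kept tips are
    preserved (an ultrametric tree stays ultrametric).
    """
    labels = set(tip_labels(tree))
    unknown = sorted(set(keep) - labels)
    if unknown:
        raise ValueError(f"species not in tree: {unknown}")
    out = tree.clone(depth=1)
    out.retain_taxa_with_labels(sorted(keep))
    # drop a dangling root edge so depths are measured from the new root
    if out.seed_node.edge.length:
        out.seed_node.edge.length = None
    return out


def _tree_height(tree: dendropy.Tree) -> float:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return max(leaf.root_distance for leaf in tree.leaf_node_iter())


def _is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    h = max(depths)
    return h == 0 or (max(depths) - min(depths)) <= rel_tol * h


def graft_missing(
    tree: dendropy.Tree, species: str, sister: str
) -> dendropy.Tree:
    """Attach a missing species at the midpoint of its sister lineage.

    ``sister`` may be a tip label or an internal-node (clade) label.  A
    new node is inserted halfway along the sister's subtending branch
    and the new terminal branch is sized so that, on an ultrametric
    tree, the grafted tip is contemporaneous with the others (on
    non-ultrametric trees it gets half the sister's subtending branch).
    """
    out = tree.clone(depth=1)
    target = None
    for node in out.preorder_node_iter():
        label = node.taxon.label if node.taxon else node.label
        if label == sister:
            target = node
            break
    if target is None:
        raise ValueError(f"sister lineage {sister!r} not found in tree")
    if target.parent_node is None:
        raise ValueError("sister lineage is the root: no subtending branch to split")
    ultrametric = _is_ultrametric(out)
    height = _tree_height(out)
    edge_len = target.edge.length or 0.0
    parent = target.parent_node
    parent_depth = parent.root_distance
    # split the subtending branch at its midpoint
    mid = dendropy.Node()
    parent.remove_child(target)
    parent.add_child(mid)
    mid.edge.length = edge_len / 2.0
    mid.add_child(target)
    target.edge.length = edge_len / 2.0
    tip = dendropy.Node()
    taxon = dendropy.Taxon(label=species)
    out.taxon_namespace.add_taxon(taxon)
    tip.taxon = taxon
    mid.add_child(tip)
    if ultrametric:
        tip.edge.length = height - (parent_depth + edge_len / 2.0)
    else:
        tip.edge.length = edge_len / 2.0
    return out


def phylo_covariance(tree: dendropy.Tree, lambda_pagel: float = 1.0) -> np.ndarray:
    """Tip covariance under the lambda-transformed Brownian model.

    ``C[a, b]`` is the shared root-to-MRCA path length of tips a and b,
    multiplied by lambda off the diagonal; diagonals (root-to-tip path
    lengths) are left unscaled.  Tip order follows ``tip_labels``.
    """
    if not (0.0 <= lambda_pagel <= 1.0):
        raise ValueError("lambda_pagel must lie in [0, 1]")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    m = len(leaves)
    depths = np.array([leaf.root_distance for leaf in leaves])
    pdm = tree.phylogenetic_distance_matrix()
    C = np.zeros((m, m))
    for a in range(m):
        C[a, a] = depths[a]
        for b in range(a + 1, m):
            d_ab = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
            shared = (depths[a] + depths[b] - d_ab) / 2.0
            C[a, b] = C[b, a] = lambda_pagel * shared
    return C


def bm_loglik(y: np.ndarray, C: np.ndarray, sigma2: float, mu: float) -> float:
    """Multivariate-normal log-likelihood of tip values under Brownian
    motion: y ~ N(mu 1, sigma2 C), computed via Cholesky factorization."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    try:
        factor = cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    resid = y - mu
    quad = float(resid @ cho_solve(factor, resid))
    return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + quad / sigma2)


def ess(chain: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence rule.

    ``n / (1 + 2 sum rho_k)`` with autocorrelations summed until the
    first non-positive pairwise sum (rho_{2k} + rho_{2k+1}); floored at
    1.  A constant chain returns 1.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 10:
        raise ValueError("chain too short for ESS (need >= 10 samples)")
    x = chain - chain.mean()
    var = float(x @ x) / n
    if var == 0:
        return 1.0
    # autocovariance via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    rho = acov / acov[0]
    s = 0.0
    k = 1
    while k + 1 < n:
        pair = rho[k] + rho[k + 1]
        if pair <= 0:
            break
        s += pair
        k += 2
    return max(1.0, n / (1 + 2 * s))


@dataclass
class PhyloSignalResult:
    """Posterior summary of Pagel's lambda for a single trait."""

    chain: np.ndarray  # columns: lambda_pagel, sigma2, mu
    eta: float  # posterior median of lambda
    ci95: tuple[float, float]
    ess: float
    converged: bool
    trait: str | None = None
    n_gen: int = 0
    seed: int | None = None
    acceptance: dict[str, float] = field(default_factory=dict)


def _reflect01(x: float) -> float:
    """Reflect a real number into [0, 1] (preserves detailed balance for
    a symmetric random walk on a bounded interval)."""
    x = math.fmod(x, 2.0)
    if x < 0:
        x += 2.0
    return 2.0 - x if x > 1.0 else x


def pagel_mcmc(
    tree: dendropy.Tree,
    y: np.ndarray,
    n_gen: int = 1_000_000,
    burn_in_frac: float = 0.2,
    thin: int = 100,
    seed: int | None = None,
    ess_threshold: float = 200.0,
    trait: str | None = None,
    mu_prior_sd_factor: float = 10.0,
) -> PhyloSignalResult:
    """Metropolis-Hastings sampler for (lambda, sigma2, mu) under the
    lambda-transformed Brownian model.

    Priors: lambda ~ Uniform(0, 1); log sigma2 ~ Uniform(-10, 10);
    mu ~ Normal(sample mean, 10 x sample SD).  Proposals: reflective
    Gaussian walk for lambda on [0, 1], log-scale walk for sigma2,
    Gaussian walk for mu; step sizes adapt toward 20-40% acceptance
    during burn-in only, preserving detailed balance afterwards.  The
    burn-in fraction of generations is discarded, the rest thinned; the
    posterior median of lambda (eta), its central 95% credible interval
    and the ESS of the retained lambda chain are reported.  The result
    is flagged unconverged when ESS falls below ``ess_threshold``.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    C1 = phylo_covariance(tree, 1.0)
    diag = np.diag(C1).copy()
    off = C1 - np.diag(diag)
    n = len(y)
    if C1.shape[0] != n:
        raise ValueError("trait vector length does not match number of tips")

    mu_hat = float(y.mean())
    sd_hat = float(y.std(ddof=1)) if n > 1 else 1.0
    if sd_hat == 0:
        sd_hat = 1.0
    mu_prior_sd = mu_prior_sd_factor * sd_hat

    def log_prior(lam: float, s2: float, mu: float) -> float:
        if not (0.0 <= lam <= 1.0):
            return -math.inf
        ls2 = math.log(s2)
        if not (-10.0 <= ls2 <= 10.0):
            return -math.inf
        return -0.5 * ((mu - mu_hat) / mu_prior_sd) ** 2

    # cached Cholesky pieces for the current lambda
    cache: dict[str, object] = {}

    def refresh(lam: float) -> None:
        C = off * lam + np.diag(diag)
        factor = cho_factor(C, lower=True)
        L = factor[0]
        cache["logdet"] = 2.0 * float(np.log(np.diag(L)).sum())
        cache["zy"] = cho_solve(factor, y)
        cache["z1"] = cho_solve(factor, np.ones(n))
        cache["yzy"] = float(y @ cache["zy"])
        cache["yz1"] = float(y @ cache["z1"])
        cache["z11"] = float(np.ones(n) @ cache["z1"])

    def loglik(s2: float, mu: float) -> float:
        quad = cache["yzy"] - 2.0 * mu * cache["yz1"] + mu * mu * cache["z11"]
        return -0.5 * (
            n * math.log(2 * math.pi * s2) + cache["logdet"] + quad / s2
        )

    lam, s2, mu = 0.5, sd_hat**2 if sd_hat > 0 else 1.0, mu_hat
    s2 = min(max(s2, math.exp(-9.9)), math.exp(9.9))
    refresh(lam)
    lp = log_prior(lam, s2, mu) + loglik(s2, mu)

    steps = {"lam": 0.1, "s2": 0.5, "mu": 0.5 * sd_hat}
    accept = {"lam": 0, "s2": 0, "mu": 0}
    tries = {"lam": 0, "s2": 0, "mu": 0}
    burn = int(burn_in_frac * n_gen)
    kept: list[tuple[float, float, float]] = []
    adapt_window = 200

    for gen in range(n_gen):
        which = ("lam", "s2", "mu")[int(rng.integers(3))]
        tries[which] += 1
        if which == "lam":
            prop = _reflect01(lam + steps["lam"] * rng.standard_normal())
            C_saved = dict(cache)
            refresh(prop)
            lp_new = log_prior(prop, s2, mu) + loglik(s2, mu)
            if math.log(rng.random()) < lp_new - lp:
                lam, lp = prop, lp_new
                accept["lam"] += 1
            else:
                cache.update(C_saved)
        elif which == "s2":
            prop = s2 * math.exp(steps["s2"] * rng.standard_normal())
            lpri = log_prior(lam, prop, mu)
            if lpri == -math.inf:
                lp_new = -math.inf
            else:
                lp_new = lpri + loglik(prop, mu)
            # log-scale walk: Jacobian term log(prop/s2)
            if lp_new > -math.inf and math.log(rng.random()) < (
                lp_new - lp + math.log(prop / s2)
            ):
                s2, lp = prop, lp_new
                accept["s2"] += 1
        else:
            prop = mu + steps["mu"] * rng.standard_normal()
            lp_new = log_prior(lam, s2, prop) + loglik(s2, prop)
            if math.log(rng.random()) < lp_new - lp:
                mu, lp = prop, lp_new
                accept["mu"] += 1
        if gen < burn:
            if (gen + 1) % adapt_window == 0:
                for key in steps:
                    if tries[key] == 0:
                        continue
                    rate = accept[key] / tries[key]
                    if rate < 0.20:
                        steps[key] *= 0.7
                    elif rate > 0.40:
                        steps[key] *= 1.4
                    accept[key] = 0
                    tries[key] = 0
        elif (gen - burn) % thin == 0:
            kept.append((lam, s2, mu))

    chain = np.array(kept)
    lam_chain = chain[:, 0]
    eta = float(np.median(lam_chain))
    lo, hi = np.quantile(lam_chain, [0.025, 0.975])
    ess_val = ess(lam_chain)
    rates = {
        k: (accept[k] / tries[k] if tries[k] else float("nan")) for k in steps
    }
    return PhyloSignalResult(
        chain=chain,
        eta=eta,
        ci95=(float(lo), float(hi)),
        ess=ess_val,
        converged=bool(ess_val >= ess_threshold),
        trait=trait,
        n_gen=n_gen,
        seed=seed,
        acceptance=rates,
    )
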