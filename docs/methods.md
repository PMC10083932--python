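# Methods

This note documents the models implemented in `plantdemog`, the
defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical choices that matter.

## Projection-matrix records and screening

A record is one species' annual projection matrix decomposed as
A = T + F.  T is substochastic in the intended interpretation: column
*j* sums to the annual survival of stage *j*, and death is implicit as
one minus that column sum (no explicit dead state).  Nine eligibility
conditions screen records before analysis; conditions 1 and 3–6
(natural conditions, duration ≥ 1 yr, annual periodicity, stage/size
classification, mean/pooled/individual composition) are metadata flags
taken on trust, since they cannot be derived from the matrix itself —
this mirrors how demographic databases annotate records.  Conditions
2 and 7–9 are computed: A = T + F within 1e-9, dimension ≥ 2,
survival issue (maximum column sum of T) strictly below 1.05, and
irreducibility of A (strong connectivity of the life-cycle graph,
checked via Tarjan's algorithm on the sparse adjacency structure).
The 1.05 boundary is strict: a record at exactly 1.05 is rejected.
Maximum versus "any" column sum is immaterial for the pass/fail rule;
the maximum is what `survival_issue` reports.

Eigen-analysis returns the Perron root.  For imprimitive (periodic)
life cycles several eigenvalues share the spectral radius; the
implementation selects the one with largest real part, which by
Perron–Frobenius is the real non-negative root with non-negative
eigenvectors.  Eigenvectors are normalized to `sum(w) = 1` and
`<v, w> = 1`.

## Age-from-stage decomposition

Treating T as a Markov chain with death absorbing gives the
fundamental matrix N = (I − T)⁻¹ (expected years spent in each stage;
requires spectral radius of T below 1, otherwise an "immortal stage
structure" error is raised).  The age schedules are

    l(x) = 1ᵀ Tˣ w0        m(x) = 1ᵀ F Tˣ w0 / l(x)

with w0 the stage distribution at birth.  The default w0 puts all mass
in the first stage — offspring of plant matrices enter the seedling or
smallest class — with an offspring-weighted alternative (row sums of F,
normalized) available for sensitivity analysis.  Schedules stop at the
first age with l(x) < 1e-7 or at the age cap 1000 (configurable); a
capped schedule carries a truncation flag and all traits computed from
it inherit that caveat.  The defaults keep every trait finite for any
substochastic T while contributing truncation error far below the
reporting precision.

Traits:

- **L_max**: first age with l(x) below the criterion (default 0.01).
- **L_mean** = 1ᵀ N w0, which counts the birth year (a life cycle with
  zero survival has L_mean = 1).  Computing it from the survivorship
  schedule instead gives the same value for consistent w0.
- **L_α**: reproductive stages (positive F column sums) are made
  absorbing, and the expectation of the absorption age is taken
  *conditional on ever being absorbed* — individuals that die first do
  not contribute.  This is robust to trace reproduction at early ages,
  unlike "first age with m(x) > 0", which is nonetheless available as
  an option.
- **H** (Keyfitz life-table entropy) = −Σ l ln l / Σ l over tabulated
  ages with l > 0.  H = 1 for constant-hazard (log-linear, "Type II")
  survivorship, a benchmark the test suite checks on a finely
  discretized exponential schedule; the ratio form makes H invariant
  to the age-grid spacing.  The conventional direction of the
  type-I/II/III labels differs between sources, so the package reports
  the numeric H only and leaves any labeling to the user.
- **S** (degree of iteroparity): the age distribution of reproduction
  is formed as p(x) ∝ λ^−(x+1) l(x) m(x) and renormalized; S is its
  Shannon entropy in nats.  The renormalization makes S independent of
  the census convention hidden in the λ exponent and guarantees S = 0
  exactly for semelparity; the unnormalized Euler–Lotka sum is ≈ 1
  anyway for consistent birth distributions (a property the suite
  asserts on random matrices).
- **R_o**: dominant eigenvalue of F·N.  All logarithms are natural;
  the entropy conventions and the H = 1 benchmark both presuppose
  that.

Min–max normalization maps each trait column to [0, 1]; a constant
column maps to zeros (the clustering then simply ignores it).

## Clustering and ordination

Bray–Curtis dissimilarity on the normalized traits (two all-zero
profiles are defined as identical), UPGMA (size-weighted average
linkage — monotone, so no dendrogram inversions), and a fixed-height
cut at 0.3 define the clusters.  The cut height is a config value;
alongside it the pipeline records a K-means within-cluster
sum-of-squares profile and its elbow.  The elbow is located at the
maximum curvature of the **log** WSS profile: on the absolute scale the
first split always dominates the second difference and the rule would
recommend k = 2 for any nested structure, while relative drops
correctly flag where the profile flattens.  K-means tie-breaking and
restarts are seeded; UPGMA ties resolve to the lowest current-node
indices (scipy's convention), which makes the dendrogram deterministic.

PERMANOVA partitions Σd²: SS_total = Σ_{a<b} d²/m, SS_within summed per
group with its own size, pseudo-F = ((SS_total − SS_within)/(g−1)) /
(SS_within/(m−g)), and p = (1 + #{F_perm ≥ F_obs})/(n_perm + 1) over
seeded label permutations (999 by default).  Degenerate partitions
(all singletons, or zero within-group variance) return NaN/inf rather
than raising.  P-values are only computed when every group has ≥ 2
members; the pairwise variant restricts the distance matrix to each
label pair and reports raw and Holm-adjusted p-values, since no single
multiplicity convention is canonical here.

PCA runs on the normalized traits, centered but *not* re-standardized:
the min–max normalization already equalizes ranges, and double scaling
would distort the relative trait weighting the distances use.
Component signs are fixed (largest-magnitude loading entry positive)
so output is reproducible across BLAS builds.

## Elasticities

e_ij = (a_ij/λ) v_i w_j / <v, w>, zero exactly at structural zeros;
the matrix sums to one (de Kroon), which the suite verifies against a
finite-difference perturbation oracle on random matrices.  Grouping
into processes: fertility takes positions with F > 0; among
T-positions, progression (below-diagonal) is growth and stasis
(diagonal) is survival.  Retrogression (above-diagonal T) goes with
survival by default — both stasis and shrinkage keep an individual in
the standing population — but can be grouped with growth, since usage
differs between authors.  Positions positive in both T and F split
their elasticity in proportion to T:F, preserving the sum-to-one
partition.  Density summaries use a Gaussian KDE with Silverman
bandwidth and boundary reflection on [0, 1] (elasticities are bounded;
an unreflected kernel leaks mass past the endpoints); strata with
fewer than two distinct values report a median but no curve, and the
cluster comparison is restricted to clusters with at least 5 species
by default — smaller strata are reported but not density-smoothed.

## Phylogenetic signal

Pagel's λ scales the off-diagonal entries of the Brownian-motion tip
covariance C (C_ab = shared root-to-MRCA path length; diagonals stay
at the root-to-tip depths).  The trait model is y ~ N(μ1, σ²C(λ)),
evaluated by Cholesky factorization.  The sampler is
Metropolis–Hastings over (λ, σ², μ): reflective Gaussian walk for λ on
[0, 1], log-scale walk for σ² (with the Jacobian in the acceptance
ratio), Gaussian walk for μ.  Priors: λ ~ U(0, 1), log σ² ~ U(−10, 10),
μ ~ N(ȳ, 10·SD(y)) — weakly informative, with bounded support matching
the λ transform.  Step sizes adapt toward 20–40% acceptance during
burn-in only and are frozen afterwards, preserving detailed balance
for the retained samples.  Defaults: 1M generations, 20% burn-in,
thinning 100; the λ-chain ESS is computed by the initial-positive-
sequence rule and a result with ESS < 200 is flagged unconverged.
Each trait is analyzed in a separate univariate run.  One parameter
update is proposed per generation, and the Cholesky factor is cached
between λ-moves so σ²/μ updates cost O(n) — this is what keeps
100k-generation runs on 100-tip trees at a few seconds each.

Tree utilities: trimming preserves root-to-tip path lengths (degree-2
nodes suppressed with branch lengths summed); grafting inserts a new
tip at the midpoint of its sister lineage's subtending branch, sized to
be contemporaneous on ultrametric trees (half the subtending branch
otherwise).  Non-ultrametric trees are accepted for likelihood
computation.

## Synthetic data

Three archetypes span the fast–slow continuum: *fast* (2–3 stages,
stasis ≤ 0.1, progression ≥ 0.5, fertility 3–10 from the stages
reached within a year — annual/semelparous), *intermediate* (3–5
stages, stasis 0.3–0.6, fertility 1–5), *slow* (5–8 stages, stasis
0.7–0.95, progression 0.05–0.2, fertility 0.1–1 — long-lived,
late-maturing).  One template life cycle is drawn per archetype spec;
the generated records are multiplicative lognormal perturbations
(σ = 0.1 by default) of that template, emulating independent studies
of demographically similar species.  T columns exceeding 0.99 after
noise are renormalized, so every generated record passes the screen by
construction.  Listing labels are assigned independently at 30%,
approximating the listed fraction of screened database records; note
that in these synthetic data listing is *independent* of life history
by construction, so listed-vs-nonlisted contrasts estimate a true null.
Random valid matrices place fertility in the first row (offspring
enter the smallest stage), which is both the dominant plant-matrix
convention and the premise of the first-stage birth distribution.

The cohort oracle is an individual-based simulation of the survival
process only — fully independent of the analytic machinery — and is
used to validate lx, L_mean, L_max and L_α on random matrices (100 000
individuals, exact binomial bands at the 3σ familywise level).  Yule
trees are pure-birth forward constructions, exactly ultrametric, with
tips labeled in traversal order (hence neighboring labels are
phylogenetically close; mapping records to tips in order makes
archetypes form clades, which is why the demo analysis finds strong
phylogenetic signal).

What the synthetic data do **not** emulate: real matrices' reducible
and quasi-periodic pathologies beyond what the screen rejects,
seed-bank and clonal stages, correlated listing status, taxonomy, and
the heavy-tailed dimension distribution of real databases.  Passing
tests demonstrate the machinery is correct, not that any particular
empirical trait table or cluster count will be reproduced.

## Problem sizes in the shipped analyses and tests

The five analysis drivers use 36 records (12 per archetype), a 36-tip
tree, 999 permutations, and 100k MCMC generations per trait — sizes
chosen so the full sequence reruns in well under a minute while every
estimate is stable at the reported precision; the MCMC production
default (1M generations) is one config line away.  The validation
suite uses 50–100 random matrices per property, cohorts of 100 000
individuals, 1000 null replicates for the PERMANOVA calibration, and
ten 100-tip replicates per condition for λ recovery.

## Known limitations

- L_α is a conditional expectation on the *stage* process; species
  whose F matrix deposits offspring into non-initial stages combined
  with a non-matching w0 make the Euler–Lotka premise approximate.
- The MCMC is a plain random-walk sampler; for very small trees
  (< ~10 tips) the λ posterior is broad and ESS-based flags should be
  heeded rather than point medians.
- PERMANOVA p-values are permutation-based and seeded; with tiny
  groups the discrete p floor (1/(n_perm+1)) matters.
- No stochastic environments, periodic matrix products, vital-rate
  (lower-level) elasticities, or alternative signal statistics
  (Blomberg's K, Moran's I) are implemented.
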