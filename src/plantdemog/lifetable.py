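"""Age-from-stage demography: life tables and scalar life-history traits.

Stage-structured matrices carry no explicit age axis, but treating the
survival matrix ``T`` as a substochastic Markov chain (death is the
implicit absorbing state) recovers age-specific schedules: survivorship
``lx`` (probability of being alive at age x) and fertility ``mx``
(offspring per survivor at age x).  From those schedules and the
fundamental matrix ``N = (I - T)^-1`` the traits of the fast-slow
continuum follow:

- ``lam``    asymptotic population growth rate (dominant eigenvalue of A)
- ``Lmax``   longevity: age at which survivorship drops below a criterion
- ``H``      survivorship-curve shape (Keyfitz' life-table entropy);
             H = 1 for log-linear (constant hazard) survivorship
- ``Lalpha`` age at first reproduction (absorbing-chain expectation)
- ``Lmean``  mean life expectancy at birth
- ``S``      degree of iteroparity (entropy of the age distribution of
             reproduction); S = 0 for strict semelparity
- ``Ro``     net reproductive rate (dominant eigenvalue of F N)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ProjectionMatrixRecord, dominant_eigen

__all__ = [
    "LifeTable",
    "TraitVector",
    "FundamentalMatrix",
    "ImmortalStageStructureError",
    "fundamental_matrix",
    "age_schedules",
    "longevity_lmax",
    "mean_life_expectancy",
    "age_at_first_reproduction",
    "keyfitz_entropy",
    "net_reproductive_rate",
    "iteroparity_entropy",
    "trait_vector",
    "trait_table",
    "normalize_trait_table",
    "birth_distribution",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ["lam", "Lmax", "H", "Lalpha", "Lmean", "S", "Ro"]


class ImmortalStageStructureError(ValueError):
    """Raised when spectral radius of T >= 1: some individuals never die,
    so the fundamental matrix and age schedules diverge."""


@dataclass
class LifeTable:
    """Age-indexed survivorship and fertility schedules.

    ``lx[x]`` is the probability of surviving from birth to age x
    (``lx[0] = 1``); ``mx[x]`` the expected sexual offspring of a
    survivor at age x (0 where ``lx`` is 0).  ``truncated`` flags a
    schedule cut at the age cap before survivorship fell below the
    tolerance.
    """

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    w0: np.ndarray
    truncated: bool = False


@dataclass
class FundamentalMatrix:
    """``N = (I - T)^-1``; entry (i, j) is the expected number of yearly
    time steps an individual starting in stage j spends in stage i."""

    N: np.ndarray


@dataclass
class TraitVector:
    lam: float
    Lmax: float
    H: float
    Lalpha: float
    Lmean: float
    S: float
    Ro: float
    species_id: str | None = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in TRAIT_COLUMNS}


def birth_distribution(rec: ProjectionMatrixRecord, convention: str = "first_stage") -> np.ndarray:
    """Stage mixing at birth, w0.

    ``first_stage`` puts all newborn mass in stage 1 (the dominant
    convention for plant matrices, where stage 1 is the seedling or
    smallest class); ``offspring_weighted`` distributes mass across
    stages in proportion to the row sums of F (where offspring actually
    arrive).
    """
    n = rec.n_stages
    if convention == "first_stage":
        w0 = np.zeros(n)
        w0[0] = 1.0
        return w0
    if convention == "offspring_weighted":
        rows = rec.F.sum(axis=1)
        if rows.sum() <= 0:
            raise ValueError("F has no positive entries; cannot weight by offspring")
        return rows / rows.sum()
    raise ValueError(f"unknown birth-distribution convention {convention!r}")


def fundamental_matrix(T: np.ndarray) -> FundamentalMatrix:
    """Expected stage occupancy times ``N = (I - T)^-1``.

    Requires the spectral radius of T to be below one (every individual
    eventually dies), otherwise the Neumann series diverges.
    """
    T = np.asarray(T, dtype=float)
    rho = float(np.max(np.abs(np.linalg.eigvals(T)))) if T.size else 0.0
    if rho >= 1.0:
        raise ImmortalStageStructureError(
            f"spectral radius of T is {rho:.6g} >= 1 (immortal stage structure)"
        )
    N = np.linalg.inv(np.eye(T.shape[0]) - T)
    return FundamentalMatrix(N=N)


def age_schedules(
    T: np.ndarray,
    F: np.ndarray,
    w0: np.ndarray,
    lx_tol: float = 1e-7,
    x_cap: int = 1000,
) -> LifeTable:
    """Markov-chain decomposition of (T, F) into age-specific schedules.

    ``lx(x)`` is the total mass of ``T^x w0`` (survival to age x along
    any stage path); ``mx(x)`` the per-survivor fertility
    ``sum(F T^x w0) / lx(x)``.  The schedule stops at the first age
    where survivorship falls below ``lx_tol`` (that age is included,
    closing the table) or at ``x_cap``, whichever comes first.
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if not np.isclose(w0.sum(), 1.0):
        raise ValueError("w0 must sum to 1")
    lx_list: list[float] = []
    mx_list: list[float] = []
    p = w0.copy()
    truncated = False
    x = 0
    while True:
        lx = float(p.sum())
        lx_list.append(lx)
        mx_list.append(float((F @ p).sum() / lx) if lx > 0 else 0.0)
        if lx < lx_tol:
            break
        if x >= x_cap:
            truncated = True
            warnings.warn(
                f"age schedule truncated at x_cap={x_cap} before lx < {lx_tol:g}",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        p = T @ p
        x += 1
    return LifeTable(
        ages=np.arange(len(lx_list)),
        lx=np.array(lx_list),
        mx=np.array(mx_list),
        w0=w0,
        truncated=truncated,
    )


def longevity_lmax(lt: LifeTable, crit: float = 0.01) -> float:
    """Age at which survivorship first drops below ``crit``.

    Returns the truncation age (with a warning) if the criterion is
    never reached within the tabulated schedule.
    """
    if not (0 < crit <= 1):
        raise ValueError(f"crit must lie in (0, 1], got {crit}")
    below = np.nonzero(lt.lx < crit)[0]
    if below.size == 0:
        warnings.warn(
            f"survivorship never dropped below {crit:g}; returning truncation age",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(lt.ages[-1])
    return float(lt.ages[below[0]])


def mean_life_expectancy(N: FundamentalMatrix, w0: np.ndarray) -> float:
    """Expected total time steps lived, ``sum(N w0)`` (counts the birth
    step, so a life cycle with no survival gives 1)."""
    w0 = np.asarray(w0, dtype=float)
    return float((N.N @ w0).sum())


def age_at_first_reproduction(
    T: np.ndarray, F: np.ndarray, w0: np.ndarray
) -> float:
    """Expected age at first reproduction, conditional on reproducing.

    Stages whose F column has positive sum are "reproductive"; they are
    made absorbing and the expectation of the absorption time from the
    birth distribution is taken over the individuals that are ever
    absorbed (those that die first do not contribute).  Mass of w0
    already sitting on a reproductive stage reproduces at age 0.
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    repro = F.sum(axis=0) > 0
    if not repro.any():
        raise ValueError("non-reproducing life cycle: no F column has positive sum")
    nonrep = ~repro
    w_rep = float(w0[repro].sum())
    w_non = w0[nonrep]
    if w_non.sum() == 0:
        return 0.0
    Q = T[np.ix_(nonrep, nonrep)]  # among non-reproductive stages
    R = T[np.ix_(repro, nonrep)]  # non-reproductive -> reproductive
    r = R.sum(axis=0)  # one-step absorption probability
    I = np.eye(Q.shape[0])
    M = I - Q.T
    h = np.linalg.solve(M, r)  # P(ever reproduce | start j)
    u = np.linalg.solve(M, h)  # h_j * E[age | reproduce, start j]
    p_rep = w_rep + float(w_non @ h)
    if p_rep <= 0:
        raise ValueError("non-reproducing life cycle: reproduction unreachable from w0")
    return float(w_non @ u) / p_rep


def keyfitz_entropy(lx: np.ndarray) -> float:
    """Keyfitz' life-table entropy H = (-sum lx ln lx) / (sum lx).

    Shape statistic of the survivorship curve: H = 1 for log-linear
    (constant-hazard) survivorship, with deviations either side for
    concave/convex curves.  Ages with lx = 0 contribute nothing.
    """
    lx = np.asarray(lx, dtype=float)
    pos = lx > 0
    if not pos.any() or lx[pos].sum() == 0:
        return 0.0
    lp = lx[pos]
    return float(-(lp * np.log(lp)).sum() / lp.sum())


def net_reproductive_rate(F: np.ndarray, N: FundamentalMatrix, imag_tol: float = 1e-10) -> float:
    """Net reproductive rate Ro: dominant eigenvalue of F N (expected
    lifetime offspring per newborn)."""
    F = np.asarray(F, dtype=float)
    if not F.any():
        return 0.0
    vals = np.linalg.eigvals(F @ N.N)
    lam = vals[int(np.argmax(np.abs(vals)))]
    if abs(lam.imag) > imag_tol * max(1.0, abs(lam.real)):
        raise ValueError(f"Ro eigenvalue has imaginary part {lam.imag:g}")
    return float(lam.real)


def iteroparity_entropy(lt: LifeTable, lam: float) -> float:
    """Degree of iteroparity S: Shannon entropy (nats) of the normalized
    age distribution of reproduction.

    The distribution weights each age's net fertility ``lx mx`` by the
    discrete Euler-Lotka factor ``lam^-(x+1)`` and renormalizes, so S is
    exactly 0 when all reproduction falls at a single age (semelparity)
    and grows with the spread of reproductive events.
    """
    net = lt.lx * lt.mx
    if not (net > 0).any():
        raise ValueError("no reproduction: lx*mx is zero at every age")
    x = lt.ages.astype(float)
    p = lam ** (-(x + 1)) * net
    p = p[p > 0]
    p = p / p.sum()
    return max(0.0, float(-(p * np.log(p)).sum()))


@dataclass
class TraitOptions:
    """Shared knobs for trait extraction."""

    w0_convention: str = "first_stage"
    lx_tol: float = 1e-7
    x_cap: int = 1000
    lmax_crit: float = 0.01


def trait_vector(
    rec: ProjectionMatrixRecord, options: TraitOptions | None = None
) -> TraitVector:
    """Compute lam plus the six demographic traits for one record.

    Composes the eigen-analysis, fundamental matrix and age schedules
    with a shared birth distribution and truncation settings.
    """
    opts = options or TraitOptions()
    try:
        w0 = birth_distribution(rec, opts.w0_convention)
        eig = dominant_eigen(rec.A)
        N = fundamental_matrix(rec.T)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            lt = age_schedules(rec.T, rec.F, w0, lx_tol=opts.lx_tol, x_cap=opts.x_cap)
            lmax = longevity_lmax(lt, crit=opts.lmax_crit)
        notes = [str(c.message) for c in caught]
        return TraitVector(
            lam=eig.lam,
            Lmax=lmax,
            H=keyfitz_entropy(lt.lx),
            Lalpha=age_at_first_reproduction(rec.T, rec.F, w0),
            Lmean=mean_life_expectancy(N, w0),
            S=iteroparity_entropy(lt, eig.lam),
            Ro=net_reproductive_rate(rec.F, N),
            species_id=rec.species_id,
            warnings=notes,
        )
    except Exception as exc:
        raise type(exc)(f"{rec.species_id}: {exc}") from exc


def trait_table(
    records, options: TraitOptions | None = None
) -> pd.DataFrame:
    """Trait vectors for a collection of records as a DataFrame indexed
    by species_id, with the `listed` flag carried along."""
    rows = []
    for rec in records:
        tv = trait_vector(rec, options)
        row = {"species_id": rec.species_id, "listed": rec.listed}
        row.update(tv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id")


def normalize_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each trait column to [0, 1].

    Applies (y - min) / (max - min) per column; a constant column maps
    to all zeros.  Non-numeric/bookkeeping columns (e.g. `listed`) pass
    through unchanged.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 species to normalize")
    out = table.copy()
    for col in table.columns:
        if col not in TRAIT_COLUMNS:
            continue
        y = table[col].astype(float)
        rng = y.max() - y.min()
        out[col] = 0.0 if rng == 0 else (y - y.min()) / rng
    return out
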