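"""Trait architecture and pedigree-based BLUP machinery.

A trait is additive: the true breeding value (TBV) of an animal is the sum
of allele-count × effect over its QTLs, centred on the base generation, and
the phenotype adds an independent normal residual so that the base
phenotypic variance is ``sigma2_p`` and the base additive fraction is the
configured narrow-sense heritability h².

The pedigree side implements Wright's numerator relationship matrix A: a
dense tabular construction for small pedigrees (the oracle), a sparse
A⁻¹ with inbreeding via the Meuwissen–Luo recursion for production use, and
the animal-model mixed-model equations (overall mean as the only fixed
effect, variance ratio λ = (1 − h²)/h²) solved sparsely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

__all__ = [
    "TraitModel",
    "RelationshipFactors",
    "sample_qtl_effects",
    "scale_to_heritability",
    "compute_tbv",
    "simulate_phenotype",
    "relationship_matrix",
    "build_A_inverse",
    "pedigree_blup",
]


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitModel:
    """Additive trait: h², phenotypic variance, signed QTL effects.

    ``direction`` is +1 to select high phenotypes (live body weight) or
    -1 to select low (fiber diameter); it is a property of the breeding
    goal, not a sign flip of the effects.
    """

    h2: float
    sigma2_p: float
    qtl_effects: np.ndarray
    direction: int = 1
    tbv_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        if self.sigma2_p <= 0:
            raise ValueError("phenotypic variance must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 (select high) or -1 (select low)")
        object.__setattr__(self, "qtl_effects", np.asarray(self.qtl_effects, dtype=float))

    @property
    def sigma2_a(self) -> float:
        return self.h2 * self.sigma2_p

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.h2) * self.sigma2_p


def sample_qtl_effects(n_qtl: int, rng: np.random.Generator, shape: float = 0.40) -> np.ndarray:
    """Raw signed QTL effects: Gamma(shape, scale=1) magnitudes, random sign."""
    if n_qtl < 1:
        raise ValueError("need at least one QTL")
    mags = rng.gamma(shape, 1.0, size=n_qtl)
    signs = rng.integers(0, 2, size=n_qtl) * 2 - 1
    return mags * signs


def scale_to_heritability(
    raw_effects: np.ndarray,
    base_qtl_genotypes: np.ndarray,
    h2: float,
    sigma2_p: float = 1.0,
    direction: int = 1,
) -> TraitModel:
    """Rescale effects so base-generation Var(TBV) = h² · sigma2_p.

    ``base_qtl_genotypes`` is the (n_individuals, n_qtl) allele-count matrix
    of the base generation.  A single multiplicative constant is applied, so
    the result is invariant to the scale of ``raw_effects``; the offset
    centres base-mean TBV at zero.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    raw_effects = np.asarray(raw_effects, dtype=float)
    g = base_qtl_genotypes @ raw_effects
    v = float(np.var(g))
    if v <= 0:
        raise ValueError("no genetic variance in base generation")
    c = np.sqrt(h2 * sigma2_p / v)
    effects = raw_effects * c
    offset = float(np.mean(base_qtl_genotypes @ effects))
    return TraitModel(h2=h2, sigma2_p=sigma2_p, qtl_effects=effects,
                      direction=direction, tbv_offset=offset)


def compute_tbv(qtl_genotypes: np.ndarray, trait: TraitModel) -> np.ndarray:
    """TBV = allele counts · effects − centring offset."""
    return qtl_genotypes @ trait.qtl_effects - trait.tbv_offset


def simulate_phenotype(
    tbv: np.ndarray,
    trait: TraitModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phenotype = TBV + N(0, sigma2_p(1 − h²)) residual."""
    tbv = np.asarray(tbv, dtype=float)
    return tbv + rng.normal(0.0, np.sqrt(trait.sigma2_e), size=tbv.shape)


# ---------------------------------------------------------------------------
# pedigree relationships
# ---------------------------------------------------------------------------

def _pedigree_arrays(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a pedigree frame (id, sire, dam; 0 = unknown) to 0-based arrays.

    Requires parents to precede offspring; this also rules out cycles.
    """
    ids = np.asarray(pedigree["id"], dtype=np.int64)
    if np.unique(ids).size != ids.size:
        raise ValueError("duplicate animal ids in pedigree")
    pos = {int(a): i for i, a in enumerate(ids)}

    def code(col: np.ndarray) -> np.ndarray:
        out = np.full(ids.size, -1, dtype=np.int64)
        for i, a in enumerate(col):
            a = int(a)
            if a == 0:
                continue
            j = pos.get(a)
            if j is None:
                raise ValueError(f"parent {a} not in pedigree")
            if j >= i:
                raise ValueError("parents must precede offspring (acyclic order)")
            out[i] = j
        return out

    sire = code(np.asarray(pedigree["sire"], dtype=np.int64))
    dam = code(np.asarray(pedigree["dam"], dtype=np.int64))
    return ids, sire, dam


@njit(cache=True)
def _inbreeding_ml(sire, dam):  # pragma: no cover - numba kernel
    """Meuwissen–Luo style inbreeding coefficients (parents precede offspring)."""
    n = sire.size
    F = np.zeros(n)
    coef = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            continue
        coef[: i + 1] = 0.0
        coef[i] = 1.0
        a_ii = 0.0
        for j in range(i, -1, -1):
            c = coef[j]
            if c == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                coef[sj] += 0.5 * c
            if dj >= 0:
                coef[dj] += 0.5 * c
            if sj >= 0 and dj >= 0:
                Dj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                Dj = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                Dj = 0.75 - 0.25 * F[dj]
            else:
                Dj = 1.0
            a_ii += c * c * Dj
        F[i] = a_ii - 1.0
    return F


@njit(cache=True)
def _tabular_A(sire, dam):  # pragma: no cover - numba kernel
    """Dense numerator relationship matrix by the tabular method."""
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = a
            A[j, i] = a
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


@dataclass
class RelationshipFactors:
    """Sparse A⁻¹ with per-animal inbreeding, in pedigree order."""

    ids: np.ndarray
    a_inverse: sparse.csr_matrix
    inbreeding: np.ndarray

    def index_of(self, animal_ids) -> np.ndarray:
        pos = pd.Index(self.ids)
        idx = pos.get_indexer(np.asarray(animal_ids, dtype=np.int64))
        if np.any(idx < 0):
            raise KeyError("animal id not in pedigree")
        return idx


def relationship_matrix(pedigree: pd.DataFrame) -> np.ndarray:
    """Dense A by the tabular method (small pedigrees / oracle use)."""
    _, sire, dam = _pedigree_arrays(pedigree)
    return _tabular_A(sire, dam)


def build_A_inverse(pedigree: pd.DataFrame) -> RelationshipFactors:
    """Sparse A⁻¹ with inbreeding, Henderson rules + Meuwissen–Luo F."""
    ids, sire, dam = _pedigree_arrays(pedigree)
    n = ids.size
    F = _inbreeding_ml(sire, dam)
    Fs = np.where(sire >= 0, F[np.maximum(sire, 0)], 0.0)
    Fd = np.where(dam >= 0, F[np.maximum(dam, 0)], 0.0)
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    D = np.where(both, 0.5 - 0.25 * (Fs + Fd),
                 np.where(one, 0.75 - 0.25 * (Fs + Fd), 1.0))
    dinv = 1.0 / D
    rows, cols, vals = [], [], []
    idx = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, dinv)
    for parent in (sire, dam):
        has = parent >= 0
        p = parent[has]
        add(p, idx[has], -0.5 * dinv[has])
        add(idx[has], p, -0.5 * dinv[has])
        add(p, p, 0.25 * dinv[has])
    # sire-dam cross terms
    s, d = sire[both], dam[both]
    add(s, d, 0.25 * dinv[both])
    add(d, s, 0.25 * dinv[both])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipFactors(ids=ids, a_inverse=ainv, inbreeding=F)


def pedigree_blup(
    phenotypes: np.ndarray,
    pedigree: pd.DataFrame,
    h2: float,
    solver: str = "direct",
) -> tuple[np.ndarray, float]:
    """Animal-model BLUP: EBV for every pedigree member and the fitted mean.

    ``phenotypes`` is aligned with the pedigree rows; NaN marks animals
    without a record.  Mixed-model equations with the overall mean as the
    only fixed effect and λ = (1 − h²)/h²::

        [ n_obs   1'W      ] [mu]   [ 1'y ]
        [ W'1  W'W + λA⁻¹ ] [u ] = [ W'y ]

    solver : "direct" (sparse LU) or "cg" (conjugate gradient).
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    y = np.asarray(phenotypes, dtype=float)
    factors = build_A_inverse(pedigree)
    n = factors.ids.size
    if y.shape != (n,):
        raise ValueError("phenotype vector must align with pedigree rows")
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("no phenotyped animals")
    lam = (1.0 - h2) / h2
    w = obs.astype(float)
    C = sparse.bmat(
        [
            [sparse.coo_matrix([[float(n_obs)]]), sparse.coo_matrix(w[None, :])],
            [sparse.coo_matrix(w[:, None]), sparse.diags(w) + lam * factors.a_inverse],
        ],
        format="csr",
    )
    rhs = np.concatenate([[np.nansum(y)], np.where(obs, y, 0.0)])
    if solver == "direct":
        sol = spsolve(C.tocsc(), rhs)
    elif solver == "cg":
        sol, info = cg(C, rhs, rtol=1e-12, atol=0.0, maxiter=20 * (n + 1))
        if info != 0:
            raise RuntimeError("conjugate-gradient MME solve did not converge")
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return sol[1:], float(sol[0])
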