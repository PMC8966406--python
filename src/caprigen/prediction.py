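"""Genomic breeding-value prediction: GBLUP, ssGBLUP, and the Bayesian alphabet.

All marker-based methods share the whole-genome regression model

    y = 1 mu + sum_j z_j a_j + e

on allele counts centred at twice the reference allele frequency, and
differ only in the prior on the marker effects ``a_j``:

* GBLUP / BayesRR — one common normal variance for every marker
  (equivalently, an animal effect with covariance G sigma2_a);
* BayesA — a per-marker variance with a scaled-inverse-chi-square prior;
* BayesB — BayesA plus a point mass ``pi`` at zero variance;
* BayesLasso — a double-exponential (Laplace) prior via the
  exponential-mixture-of-normals hierarchy.

ssGBLUP replaces the genomic relationship matrix by the unified matrix H
that blends pedigree (A) and genomic (G) information, so ungenotyped
relatives contribute phenotypes.

The marker-based estimators follow scikit-learn conventions
(``fit(X, y)`` / ``predict(X)`` returning GEBV = centred genotypes times
posterior-mean effects); ssGBLUP takes id-indexed pedigree/phenotype/
genotype inputs because its information flow is not row-i.i.d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu, spsolve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import quantgen

__all__ = [
    "GenomicRelationship",
    "MarkerEffectPosterior",
    "GEBVResult",
    "build_grm",
    "GBLUP",
    "SSGBLUP",
    "BayesA",
    "BayesB",
    "BayesRR",
    "BayesLasso",
    "BAYES_METHODS",
    "gblup",
    "ssgblup",
    "bayes_gibbs",
    "predict_gebv",
]


# ---------------------------------------------------------------------------
# genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GenomicRelationship:
    """VanRaden G with the frequencies and denominator used to build it."""

    G: np.ndarray
    p: np.ndarray
    denom: float


def _allele_freqs(counts: np.ndarray) -> np.ndarray:
    return counts.mean(axis=0) / 2.0


def build_grm(counts: np.ndarray, freq_rows: np.ndarray | None = None) -> GenomicRelationship:
    """VanRaden genomic relationship matrix.

    ``counts`` is (n, m) allele counts in {0, 1, 2}.  Frequencies are
    computed on ``freq_rows`` (row indices; default all rows), the matrix is
    M_c M_c' / (2 sum p_j q_j) with M_c = counts − 2p.
    """
    counts = np.asarray(counts, dtype=float)
    src = counts if freq_rows is None else counts[np.asarray(freq_rows)]
    p = _allele_freqs(src)
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic in the frequency source")
    Mc = counts - 2.0 * p
    return GenomicRelationship(G=(Mc @ Mc.T) / denom, p=p, denom=denom)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP on centred allele counts.

    Solved in covariance (kernel) form: with K = M_c M_c'/(2 sum p q),
    V = sigma2_a K + sigma2_e I, the GLS mean and BLUP effects are

        mu  = (1'V^-1 y)/(1'V^-1 1)
        u_j = sigma2_a / (2 sum p q) * m_cj' V^-1 (y - mu)

    so predict() is exactly the joint mixed-model GEBV for new genotyped
    animals with missing phenotypes.  ``blend`` shrinks K toward the
    identity (0 disables; the V-form is positive definite without it).

    Parameters
    ----------
    h2 : float
        Trait heritability; fixes the variance ratio.
    sigma2_p : float
        Phenotypic variance (scale only; cancels in the GEBV).
    blend : float in [0, 1)
        Weight moving K toward the identity.
    """

    def __init__(self, h2: float = 0.5, sigma2_p: float = 1.0, blend: float = 0.0):
        self.h2 = h2
        self.sigma2_p = sigma2_p
        self.blend = blend

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        n = X.shape[0]
        self.p_ = _allele_freqs(X)
        self.denom_ = float(2.0 * np.sum(self.p_ * (1.0 - self.p_)))
        if self.denom_ <= 0:
            raise ValueError("all markers monomorphic in the reference")
        Zc = X - 2.0 * self.p_
        sa = self.h2 * self.sigma2_p
        se = (1.0 - self.h2) * self.sigma2_p
        K = (Zc @ Zc.T) / self.denom_
        V = sa * ((1.0 - self.blend) * K + self.blend * np.eye(n)) + se * np.eye(n)
        cho = cho_factor(V, lower=True)
        ones = np.ones(n)
        Vi1 = cho_solve(cho, ones)
        Viy = cho_solve(cho, y)
        self.mu_ = float(ones @ Viy / (ones @ Vi1))
        alpha = Viy - self.mu_ * Vi1
        self.effects_ = (sa * (1.0 - self.blend) / self.denom_) * (Zc.T @ alpha)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "effects_")
        X = check_array(X)
        return (X - 2.0 * self.p_) @ self.effects_


# ---------------------------------------------------------------------------
# single-step GBLUP
# ---------------------------------------------------------------------------

class SSGBLUP(BaseEstimator):
    """Single-step GBLUP: animal model with H replacing A.

    H^-1 = A^-1 + [0, 0; 0, G_w^-1 − A22^-1] on the genotyped block, where
    G is the VanRaden matrix tuned (a + bG) so its mean diagonal and mean
    element match A22, and G_w = (1 − blend) G_tuned + blend A22.
    ``blend = 1`` reduces exactly to pedigree BLUP.

    fit() takes a pedigree frame (id, sire, dam; parents precede
    offspring), phenotypes as an id-indexed Series (NaN = no record), and
    genotypes as an id-indexed DataFrame of allele counts.
    """

    def __init__(self, h2: float = 0.5, blend: float = 0.05, tune: bool = True):
        self.h2 = h2
        self.blend = blend
        self.tune = tune

    def fit(self, pedigree: pd.DataFrame, phenotypes: pd.Series,
            genotypes: pd.DataFrame, G: np.ndarray | None = None):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        factors = quantgen.build_A_inverse(pedigree)
        n = factors.ids.size
        gidx = factors.index_of(genotypes.index.to_numpy())
        ng = gidx.size
        if ng == 0:
            raise ValueError("no genotyped animals")
        A22 = self._a_submatrix(factors.a_inverse, gidx)
        if G is None:
            G = build_grm(genotypes.to_numpy(dtype=float)).G
        else:
            G = np.asarray(G, dtype=float)
        if self.tune:
            m_diag_g, m_g = float(np.mean(np.diag(G))), float(np.mean(G))
            m_diag_a, m_a = float(np.mean(np.diag(A22))), float(np.mean(A22))
            if abs(m_diag_g - m_g) > 1e-12:
                b = (m_diag_a - m_a) / (m_diag_g - m_g)
                a = m_a - b * m_g
                G = a + b * G
        Gw = (1.0 - self.blend) * G + self.blend * A22
        try:
            correction = np.linalg.inv(Gw) - np.linalg.inv(A22)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular blended genomic matrix") from err
        Hinv = factors.a_inverse.tolil()
        Hinv[np.ix_(gidx, gidx)] = Hinv[np.ix_(gidx, gidx)].toarray() + correction
        Hinv = Hinv.tocsr()

        y = phenotypes.reindex(pd.Index(factors.ids)).to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError("no phenotyped animals")
        lam = (1.0 - self.h2) / self.h2
        w = obs.astype(float)
        C = sparse.bmat(
            [
                [sparse.coo_matrix([[float(obs.sum())]]), sparse.coo_matrix(w[None, :])],
                [sparse.coo_matrix(w[:, None]), sparse.diags(w) + lam * Hinv],
            ],
            format="csc",
        )
        rhs = np.concatenate([[np.nansum(y)], np.where(obs, y, 0.0)])
        if n + 1 <= 4000:
            sol = np.linalg.solve(C.toarray(), rhs)
        else:
            sol = spsolve(C, rhs)
        self.mu_ = float(sol[0])
        self.gebv_ = pd.Series(sol[1:], index=pd.Index(factors.ids, name="id"))
        self.factors_ = factors
        return self

    @staticmethod
    def _a_submatrix(a_inverse: sparse.csr_matrix, idx: np.ndarray) -> np.ndarray:
        """A22 = rows/cols ``idx`` of (A^-1)^-1 via one sparse factorisation."""
        lu = splu(a_inverse.tocsc())
        n = a_inverse.shape[0]
        out = np.empty((idx.size, idx.size))
        for start in range(0, idx.size, 512):
            block = idx[start : start + 512]
            rhs = np.zeros((n, block.size))
            rhs[block, np.arange(block.size)] = 1.0
            out[:, start : start + 512] = lu.solve(rhs)[idx]
        return (out + out.T) / 2.0

    def predict(self, ids) -> np.ndarray:
        check_is_fitted(self, "gebv_")
        return self.gebv_.loc[np.asarray(ids, dtype=np.int64)].to_numpy()


# ---------------------------------------------------------------------------
# Bayesian alphabet Gibbs samplers
# ---------------------------------------------------------------------------

_BRR, _BAYESA, _BAYESB, _BL = 0, 1, 2, 3


@njit(cache=True)
def _rinvgauss(mu, lam):  # pragma: no cover - numba kernel
    v = np.random.normal() ** 2
    x = mu + mu * mu * v / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * v + mu * mu * v * v)
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def _rchisq(df):  # pragma: no cover - numba kernel
    return 2.0 * np.random.gamma(0.5 * df, 1.0)


@njit(cache=True)
def _gibbs_kernel(ZT, y, method, n_iter, burn_in, thin, nu, S, nu_e, Se,
                  pi, bl_shape, bl_rate, update_var, sg0, se0,
                  seed):  # pragma: no cover - numba kernel
    np.random.seed(seed)
    m, n = ZT.shape
    zz = np.empty(m)
    for j in range(m):
        zz[j] = np.dot(ZT[j], ZT[j])
    a = np.zeros(m)
    delta = np.ones(m, dtype=np.int8)
    sg = np.full(m, sg0)
    tau2 = np.ones(m)
    lam2 = bl_shape / bl_rate
    mu = y.mean()
    e = y - mu
    se = se0
    a_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    sg_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    se_sumsq = 0.0
    kept = 0
    for it in range(n_iter):
        # intercept
        mu_new = mu + e.mean() + np.random.normal() * np.sqrt(se / n)
        e += mu - mu_new
        mu = mu_new
        for j in range(m):
            zj = ZT[j]
            if zz[j] <= 1e-12:
                a[j] = 0.0
                delta[j] = 0
                continue
            if method == _BAYESB:
                if a[j] != 0.0:
                    e += zj * a[j]
                r = np.dot(zj, e)
                if delta[j] == 0:
                    sg[j] = nu * S / _rchisq(nu)
                v0 = zz[j] * se
                v1 = zz[j] * zz[j] * sg[j] + zz[j] * se
                log_odds = (np.log((1.0 - pi) / pi)
                            + 0.5 * (np.log(v0 / v1)
                                     + r * r * (1.0 / v0 - 1.0 / v1)))
                p1 = 1.0 / (1.0 + np.exp(-log_odds))
                if np.random.random() < p1:
                    delta[j] = 1
                    C = zz[j] + se / sg[j]
                    a[j] = r / C + np.random.normal() * np.sqrt(se / C)
                    e -= zj * a[j]
                    if update_var:
                        sg[j] = (nu * S + a[j] * a[j]) / _rchisq(nu + 1.0)
                else:
                    delta[j] = 0
                    a[j] = 0.0
            else:
                if method == _BL:
                    var_j = se * tau2[j]
                else:
                    var_j = sg[j]
                aj = a[j]
                r = np.dot(zj, e) + zz[j] * aj
                C = zz[j] + se / var_j
                a[j] = r / C + np.random.normal() * np.sqrt(se / C)
                e += zj * (aj - a[j])
                if method == _BAYESA and update_var:
                    sg[j] = (nu * S + a[j] * a[j]) / _rchisq(nu + 1.0)
                elif method == _BL and update_var:
                    a2 = a[j] * a[j]
                    if a2 < 1e-12:
                        a2 = 1e-12
                    inv_t = _rinvgauss(np.sqrt(lam2 * se / a2), lam2)
                    tau2[j] = 1.0 / inv_t
        if method == _BRR and update_var:
            ssa = np.dot(a, a)
            sgc = (nu * S + ssa) / _rchisq(nu + m)
            for j in range(m):
                sg[j] = sgc
        if method == _BL and update_var:
            lam2 = np.random.gamma(bl_shape + m, 1.0 / (bl_rate + 0.5 * np.sum(tau2)))
        if update_var:
            se = (nu_e * Se + np.dot(e, e)) / _rchisq(nu_e + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            a_sum += a
            sg_sum += sg
            for j in range(m):
                incl_sum[j] += delta[j]
            mu_sum += mu
            se_sum += se
            se_sumsq += se * se
    return a_sum / kept, sg_sum / kept, incl_sum / kept, mu_sum / kept, \
        se_sum / kept, se_sumsq / kept, kept


@dataclass
class MarkerEffectPosterior:
    """Posterior summaries of a Bayesian whole-genome regression fit."""

    method: str
    effects: np.ndarray          # posterior-mean marker effects
    marker_vars: np.ndarray      # posterior-mean per-marker variances
    inclusion: np.ndarray        # posterior inclusion probability (BayesB)
    mu: float
    resid_var: float
    resid_var_sd: float
    allele_freqs: np.ndarray
    nu: float
    S: float
    pi: float
    chain: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.marker_vars < 0):
            raise ValueError("marker variances must be non-negative")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")


class _BayesBase(BaseEstimator, RegressorMixin):
    """Shared single-site Gibbs machinery for the Bayesian alphabet."""

    _method_code: int = _BRR
    method_name: str = ""

    def __init__(self, h2=0.5, sigma2_p=1.0, n_iter=20000, burn_in=5000,
                 thin=10, nu=4.2, pi=0.95, bl_shape=0.55, bl_rate=0.1,
                 update_variances=True, fixed_marker_var=None,
                 fixed_resid_var=None, random_state=0):
        self.h2 = h2
        self.sigma2_p = sigma2_p
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.nu = nu
        self.pi = pi
        self.bl_shape = bl_shape
        self.bl_rate = bl_rate
        self.update_variances = update_variances
        self.fixed_marker_var = fixed_marker_var
        self.fixed_resid_var = fixed_resid_var
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.n_iter <= 0:
            raise ValueError("chain length must be positive")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn-in must be shorter than the chain")
        if X.shape[0] < 2:
            raise ValueError("need at least two reference animals")
        self.p_ = _allele_freqs(X)
        Zc = np.ascontiguousarray((X - 2.0 * self.p_).T)
        denom = float(2.0 * np.sum(self.p_ * (1.0 - self.p_)))
        denom = max(denom, 1e-12)
        sigma2_a = self.h2 * self.sigma2_p
        target = sigma2_a / denom
        if self._method_code == _BAYESB:
            target = target / max(1.0 - self.pi, 1e-12)
        # scaled-inverse-chi-square scale matching E[sg] to the target
        S = target * (self.nu - 2.0) / self.nu
        Se = (1.0 - self.h2) * self.sigma2_p * (self.nu - 2.0) / self.nu
        sg0 = self.fixed_marker_var if self.fixed_marker_var is not None else target
        se0 = (self.fixed_resid_var if self.fixed_resid_var is not None
               else (1.0 - self.h2) * self.sigma2_p)
        update = self.update_variances and self.fixed_marker_var is None
        seed = int(self.random_state) % (2**31 - 1)
        (effects, sg, incl, mu, se_mean, se_sq, kept) = _gibbs_kernel(
            Zc, np.asarray(y, dtype=float), self._method_code,
            int(self.n_iter), int(self.burn_in), int(self.thin),
            float(self.nu), float(S), float(self.nu), float(Se),
            float(self.pi), float(self.bl_shape), float(self.bl_rate),
            update, float(sg0), float(se0), seed,
        )
        self.effects_ = effects
        self.marker_vars_ = sg
        self.inclusion_ = incl
        self.mu_ = float(mu)
        self.resid_var_ = float(se_mean)
        self.resid_var_sd_ = float(np.sqrt(max(se_sq - se_mean**2, 0.0)))
        self.n_kept_ = int(kept)
        self.posterior_ = MarkerEffectPosterior(
            method=self.method_name, effects=effects, marker_vars=sg,
            inclusion=incl, mu=self.mu_, resid_var=self.resid_var_,
            resid_var_sd=self.resid_var_sd_, allele_freqs=self.p_,
            nu=self.nu, S=S, pi=(self.pi if self._method_code == _BAYESB else 0.0),
            chain={"n_iter": self.n_iter, "burn_in": self.burn_in,
                   "thin": self.thin, "seed": seed, "kept": self.n_kept_},
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "effects_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker panel does not match the fitted panel")
        return (X - 2.0 * self.p_) @ self.effects_


class BayesRR(_BayesBase):
    """Bayesian ridge regression: one common marker-effect variance."""

    _method_code = _BRR
    method_name = "BRR"


class BayesA(_BayesBase):
    """Per-marker scaled-inverse-chi-square variances."""

    _method_code = _BAYESA
    method_name = "BayesA"


class BayesB(_BayesBase):
    """BayesA prior with point mass ``pi`` at zero variance."""

    _method_code = _BAYESB
    method_name = "BayesB"


class BayesLasso(_BayesBase):
    """Double-exponential prior via the exponential-mixture hierarchy."""

    _method_code = _BL
    method_name = "BL"


BAYES_METHODS = {
    "BayesA": BayesA,
    "BayesB": BayesB,
    "BRR": BayesRR,
    "BL": BayesLasso,
}


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

@dataclass
class GEBVResult:
    """GEBV per individual for one method."""

    method: str
    gebv: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gebv.index.has_duplicates:
            raise ValueError("duplicate individual ids in GEBV result")


def gblup(ref_phenotypes: pd.Series, genotypes: pd.DataFrame, h2: float,
          blend: float = 0.0) -> GEBVResult:
    """Joint GBLUP: fit on the reference rows, return GEBV for all rows."""
    ref_ids = ref_phenotypes.index
    est = GBLUP(h2=h2, blend=blend)
    est.fit(genotypes.loc[ref_ids].to_numpy(dtype=float),
            ref_phenotypes.to_numpy(dtype=float))
    gebv = pd.Series(est.predict(genotypes.to_numpy(dtype=float)),
                     index=genotypes.index)
    return GEBVResult("GBLUP", gebv, {"mu": est.mu_})


def ssgblup(phenotypes: pd.Series, pedigree: pd.DataFrame,
            genotypes: pd.DataFrame, h2: float, blend: float = 0.05,
            G: np.ndarray | None = None) -> GEBVResult:
    """Single-step GBLUP over the full pedigree."""
    est = SSGBLUP(h2=h2, blend=blend)
    est.fit(pedigree, phenotypes, genotypes, G=G)
    return GEBVResult("ssGBLUP", est.gebv_, {"mu": est.mu_})


def bayes_gibbs(method: str, ref_phenotypes: pd.Series,
                ref_genotypes: pd.DataFrame, rng_seed: int = 0,
                **chain_kwargs) -> MarkerEffectPosterior:
    """Fit one Bayesian-alphabet sampler on the reference set."""
    cls = BAYES_METHODS[method]
    est = cls(random_state=rng_seed, **chain_kwargs)
    est.fit(ref_genotypes.loc[ref_phenotypes.index].to_numpy(dtype=float),
            ref_phenotypes.to_numpy(dtype=float))
    return est.posterior_


def predict_gebv(posterior: MarkerEffectPosterior,
                 genotypes: pd.DataFrame) -> GEBVResult:
    """GEBV = centred genotype rows times posterior-mean effects."""
    X = genotypes.to_numpy(dtype=float)
    if X.shape[1] != posterior.effects.size:
        raise ValueError("marker panel does not match the fitted panel")
    gebv = (X - 2.0 * posterior.allele_freqs) @ posterior.effects
    return GEBVResult(posterior.method, pd.Series(gebv, index=genotypes.index))
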