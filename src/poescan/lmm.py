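"""Kinship-structured linear mixed model and the parent-of-origin tests.

The model for a quantitative offspring phenotype y is

    y = b0 + b1*PD + b2*MD + g'Z + u + e,      u ~ N(0, C sb2),  e ~ N(0, I se2)

where C is the block-diagonal offspring relatedness matrix (entries twice
the kinship coefficient: 1 on the diagonal, 0.5 between full siblings and
dizygotic co-twins, 1 between monozygotic co-twins, 0 across families).
The comparison model replaces (PD, MD) with the plain minor-allele dosage
G = PD + MD.

Variance components are estimated by REML, profiled to a one-dimensional
search over the ratio lam = sb2/se2: with C = U S U' fixed, V(lam) =
lam*C + I diagonalizes once per offspring subset and every candidate lam
costs one weighted least squares solve.  Because C is block diagonal with
exchangeable-correlation blocks, the eigendecomposition is assembled block
by block (and cached per offspring subset), so a fit is O(n p^2) per
likelihood evaluation even at thousands of offspring.

Hypothesis tests: Wald tests on b1 and b2 (normal reference), and an F test
with 1 numerator and n - p denominator degrees of freedom for the imprinting
contrast b1 = b2.  A flag switches the contrast to the chi-square reference;
at family-study sample sizes the two are numerically indistinguishable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .families import Family

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)


class LmmError(ValueError):
    pass


# ---------------------------------------------------------------------------
# kinship


@dataclass
class KinshipMatrix:
    """Block-diagonal offspring relatedness matrix (2 x kinship).

    Each family contributes one exchangeable-correlation block: unit
    diagonal, constant off-diagonal ``corr`` (0.5 for full sibs / DZ twins,
    1.0 for MZ twins).  Stored as (family_id, offspring_ids, corr) triples;
    the dense matrix and per-subset eigendecompositions are derived on
    demand and cached.
    """

    blocks: list[tuple[str, tuple[str, ...], float]]

    _decomp_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam_id, ids, corr in self.blocks:
            if not (0.0 <= corr <= 1.0):
                raise LmmError(
                    f"family {fam_id!r}: correlation {corr} outside [0, 1]"
                )
            for i in ids:
                if i in seen:
                    raise LmmError(f"offspring {i!r} appears in two blocks")
                seen.add(i)

    @property
    def offspring_ids(self) -> list[str]:
        return [i for _, ids, _ in self.blocks for i in ids]

    def dense(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(ids) if ids is not None else self.offspring_ids
        pos = {iid: i for i, iid in enumerate(ids)}
        n = len(ids)
        C = np.zeros((n, n))
        for _, members, corr in self.blocks:
            present = [pos[i] for i in members if i in pos]
            for a in present:
                for b in present:
                    C[a, b] = 1.0 if a == b else corr
        for i in range(n):
            C[i, i] = 1.0
        return C

    def decomposition(self, ids: Sequence[str]) -> "KinshipDecomposition":
        """Eigendecomposition of C restricted to ``ids`` (cached)."""
        key = tuple(ids)
        if key not in self._decomp_cache:
            self._decomp_cache[key] = _decompose(self.blocks, key)
        return self._decomp_cache[key]


class KinshipDecomposition(NamedTuple):
    """C = U S U' in block form: per-block (input positions, eigenvectors)."""

    eigenvalues: np.ndarray
    block_positions: list[np.ndarray]
    block_vectors: list[np.ndarray]
    n: int

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """U' @ M for a vector or matrix aligned with the subset order."""
        M = np.asarray(M, dtype=float)
        out = np.empty_like(M)
        start = 0
        for pos, Q in zip(self.block_positions, self.block_vectors):
            k = len(pos)
            out[start : start + k] = Q.T @ M[pos]
            start += k
        return out


def _decompose(blocks, ids: tuple[str, ...]) -> KinshipDecomposition:
    pos = {iid: i for i, iid in enumerate(ids)}
    covered = np.zeros(len(ids), dtype=bool)
    eigvals: list[np.ndarray] = []
    block_positions: list[np.ndarray] = []
    block_vectors: list[np.ndarray] = []
    eig_cache: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
    for _, members, corr in blocks:
        present = np.array([pos[i] for i in members if i in pos], dtype=int)
        if present.size == 0:
            continue
        covered[present] = True
        k = present.size
        key = (k, corr)
        if key not in eig_cache:
            B = np.full((k, k), corr)
            np.fill_diagonal(B, 1.0)
            eig_cache[key] = np.linalg.eigh(B)
        s, Q = eig_cache[key]
        eigvals.append(s)
        block_positions.append(present)
        block_vectors.append(Q)
    if not covered.all():
        missing = [ids[i] for i in np.nonzero(~covered)[0][:5]]
        raise LmmError(f"offspring not in any kinship block: {missing}")
    return KinshipDecomposition(
        eigenvalues=np.concatenate(eigvals) if eigvals else np.empty(0),
        block_positions=block_positions,
        block_vectors=block_vectors,
        n=len(ids),
    )


def build_kinship(
    families: Sequence[Family], mz_corr: float = 1.0, sib_corr: float = 0.5
) -> KinshipMatrix:
    """Pedigree-defined relatedness blocks for the filtered families.

    MZ twin pairs (both offspring flagged MZ) get ``mz_corr``; every other
    within-family offspring pair — full sibs, DZ twins, zygosity-unknown
    twins — gets ``sib_corr``.  Off-block entries are zero.
    """
    for name, v in (("mz_corr", mz_corr), ("sib_corr", sib_corr)):
        if not (0.0 <= v <= 1.0):
            raise LmmError(f"{name} must lie in [0, 1], got {v}")
    blocks = []
    for fam in families:
        ids = tuple(o.id for o in fam.offspring)
        if not ids:
            continue
        is_mz = len(ids) == 2 and all(
            o.zygosity == "MZ" for o in fam.offspring
        )
        blocks.append((fam.family_id, ids, mz_corr if is_mz else sib_corr))
    return KinshipMatrix(blocks)


# ---------------------------------------------------------------------------
# estimator


class KinshipMixedLM(RegressorMixin, BaseEstimator):
    """REML linear mixed model with a fixed offspring correlation matrix.

    Parameters
    ----------
    kinship : KinshipMatrix
        Relatedness structure; rows of X/y must be aligned with
        ``sample_ids`` passed to :meth:`fit`.
    fit_intercept : bool
        Prepend an intercept column (default True).
    lambda_bounds : (float, float)
        Search interval for the variance ratio sb2/se2; the boundary
        sb2 = 0 is always also checked explicitly.
    tol : float
        Absolute convergence tolerance on log(lambda) in the scalar search.
    use_chi2_contrast : bool
        Use the chi-square instead of the F reference for contrast tests.

    Fitted attributes (trailing underscore): ``coef_`` (without intercept),
    ``intercept_``, ``beta_`` (full fixed-effect vector, intercept first
    when fitted), ``cov_beta_``, ``sigma_b2_``, ``sigma_e2_``, ``lambda_``,
    ``loglik_reml_``, ``converged_``, ``n_used_``, ``df_resid_``.
    """

    def __init__(
        self,
        kinship: Optional[KinshipMatrix] = None,
        fit_intercept: bool = True,
        lambda_bounds: tuple[float, float] = (1e-6, 1e6),
        tol: float = 1e-8,
        use_chi2_contrast: bool = False,
    ):
        self.kinship = kinship
        self.fit_intercept = fit_intercept
        self.lambda_bounds = lambda_bounds
        self.tol = tol
        self.use_chi2_contrast = use_chi2_contrast

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, sample_ids: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        n = y.size
        if X.shape[0] != n:
            raise LmmError(f"X has {X.shape[0]} rows, y has {n}")
        if np.isnan(X).any() or np.isnan(y).any():
            raise LmmError("X and y must be complete (drop missing rows first)")
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
        p = X.shape[1]
        if n <= p + 1:
            raise LmmError(f"n={n} too small for {p} fixed effects")
        _check_full_rank(X, self.fit_intercept)

        if self.kinship is None:
            s = np.zeros(n)
            yt, Xt = y.copy(), X.copy()
        else:
            if sample_ids is None:
                sample_ids = self.kinship.offspring_ids
                if len(sample_ids) != n:
                    raise LmmError(
                        "sample_ids required when y is not aligned with the "
                        "full kinship matrix"
                    )
            decomp = self.kinship.decomposition(tuple(sample_ids))
            order = np.concatenate(decomp.block_positions)
            s = decomp.eigenvalues
            yt = decomp.rotate(y)
            Xt = decomp.rotate(X)
            self._row_order_ = order

        crit = lambda loglam: _neg2_reml(math.exp(loglam), s, yt, Xt)
        lo, hi = math.log(self.lambda_bounds[0]), math.log(self.lambda_bounds[1])
        res = optimize.minimize_scalar(
            crit, bounds=(lo, hi), method="bounded",
            options={"xatol": max(self.tol, 1e-10)},
        )
        lam = float(math.exp(res.x))
        best = crit(res.x)
        # explicit boundary: no family variance at all
        boundary = _neg2_reml(0.0, s, yt, Xt)
        if boundary <= best + 1e-10:
            lam, best = 0.0, boundary
        self.converged_ = bool(getattr(res, "success", True))

        beta, cov_unit, sigma_e2, _ = _gls(lam, s, yt, Xt)
        self.lambda_ = lam
        self.sigma_e2_ = sigma_e2
        self.sigma_b2_ = lam * sigma_e2
        self.beta_ = beta
        self.cov_beta_ = sigma_e2 * cov_unit
        self.loglik_reml_ = -0.5 * best
        self.n_used_ = n
        self.n_fixed_ = p
        self.df_resid_ = n - p
        if self.fit_intercept:
            self.intercept_ = beta[0]
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    # -- inference ----------------------------------------------------------

    def wald_test(self, index: int, level: float = 0.95):
        """Wald test and CI for one fixed effect (index into ``beta_``)."""
        se = math.sqrt(self.cov_beta_[index, index])
        if se == 0.0:
            raise LmmError("singular covariance: zero standard error")
        z = self.beta_[index] / se
        p = 2.0 * stats.norm.sf(abs(z))
        half = stats.norm.ppf(0.5 + level / 2.0) * se
        return p, (self.beta_[index] - half, self.beta_[index] + half)

    def contrast_test(self, contrast: Sequence[float], level: float = 0.95):
        """Single-df test of c'beta = 0 (F with residual df, or chi-square)."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.beta_)
        var = float(c @ self.cov_beta_ @ c)
        if var <= 0.0:
            raise LmmError("singular covariance for contrast")
        stat = est * est / var
        if self.use_chi2_contrast:
            p = stats.chi2.sf(stat, df=1)
            half = stats.norm.ppf(0.5 + level / 2.0) * math.sqrt(var)
        else:
            p = stats.f.sf(stat, 1, self.df_resid_)
            half = stats.t.ppf(0.5 + level / 2.0, self.df_resid_) * math.sqrt(var)
        return p, (est - half, est + half), stat


def _check_full_rank(X: np.ndarray, has_intercept: bool) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        cols = list(range(X.shape[1]))
        for j in cols:
            others = [k for k in cols if k != j]
            if np.linalg.matrix_rank(X[:, others]) == rank:
                bad.append(j - (1 if has_intercept else 0))
        raise LmmError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns (0-based, excluding intercept): {bad}"
        )


def _gls(lam, s, yt, Xt):
    """Weighted LS at fixed lambda on rotated data; returns
    (beta, (X'W^-1X)^-1, sigma_e2_reml, rss_w)."""
    w = lam * s + 1.0
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    n, p = Xt.shape
    sigma_e2 = rss / (n - p)
    return beta, np.linalg.inv(A), sigma_e2, rss


def _neg2_reml(lam, s, yt, Xt):
    """-2 x REML log-likelihood (profiled over sigma_e2), up to an additive
    constant shared across lambda."""
    w = lam * s + 1.0
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, Xw.T @ yt)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    n, p = Xt.shape
    if rss <= 0:
        return np.inf
    sigma_e2 = rss / (n - p)
    return (
        (n - p) * (math.log(sigma_e2) + _LOG2PI + 1.0)
        + float(np.sum(np.log(w)))
        + logdet_A
    )


# ---------------------------------------------------------------------------
# record types and functional wrappers


@dataclass
class LmmFit:
    model: str  # "poe" or "genotype"
    beta0: float
    beta1: Optional[float]  # PD effect (poe model)
    beta2: Optional[float]  # MD effect (poe model)
    beta: Optional[float]  # G effect (genotype model)
    gamma: np.ndarray
    cov_beta: np.ndarray  # covariance of the full fixed-effect vector
    sigma_b2: float
    sigma_e2: float
    n_used: int
    converged: bool
    loglik_reml: float
    estimator: KinshipMixedLM


class PoeTestTriple(NamedTuple):
    p_paternal: float
    p_maternal: float
    p_diff: float
    ci_paternal: tuple[float, float]
    ci_maternal: tuple[float, float]
    ci_diff: tuple[float, float]


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    kinship: Optional[KinshipMatrix] = None,
    sample_ids: Sequence[str] | None = None,
    model: str = "poe",
    **estimator_kwargs,
) -> LmmFit:
    """Fit one SNP-phenotype mixed model.

    ``X`` holds the non-intercept fixed effects in order: (PD, MD,
    covariates...) for the poe model or (G, covariates...) for the genotype
    model; an intercept is added internally.
    """
    if model not in ("poe", "genotype"):
        raise ValueError(f"unknown model {model!r}")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    est = KinshipMixedLM(kinship=kinship, **estimator_kwargs).fit(
        X, y, sample_ids=sample_ids
    )
    n_gen = 2 if model == "poe" else 1
    return LmmFit(
        model=model,
        beta0=est.intercept_,
        beta1=est.coef_[0] if model == "poe" else None,
        beta2=est.coef_[1] if model == "poe" else None,
        beta=est.coef_[0] if model == "genotype" else None,
        gamma=est.coef_[n_gen:].copy(),
        cov_beta=est.cov_beta_,
        sigma_b2=est.sigma_b2_,
        sigma_e2=est.sigma_e2_,
        n_used=est.n_used_,
        converged=est.converged_,
        loglik_reml=est.loglik_reml_,
        estimator=est,
    )


def poe_tests(fit: LmmFit, level: float = 0.95) -> PoeTestTriple:
    """The three parent-of-origin tests: b1 = 0, b2 = 0 (Wald) and b1 = b2
    (single-df F on the contrast)."""
    if fit.model != "poe":
        raise ValueError("poe_tests requires a poe-model fit")
    est = fit.estimator
    p1, ci1 = est.wald_test(1, level)  # beta_ index 1 = PD (0 is intercept)
    p2, ci2 = est.wald_test(2, level)
    contrast = np.zeros(est.n_fixed_)
    contrast[1], contrast[2] = 1.0, -1.0
    p3, ci3, _ = est.contrast_test(contrast, level)
    return PoeTestTriple(p1, p2, p3, ci1, ci2, ci3)


def genotype_test(fit: LmmFit, level: float = 0.95):
    """Wald test and CI for the genotype-model allele effect b."""
    if fit.model != "genotype":
        raise ValueError("genotype_test requires a genotype-model fit")
    return fit.estimator.wald_test(1, level)
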