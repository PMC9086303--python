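"""Phenotype preparation: rank-based inverse normal transform and the
offspring Spearman correlation screen.

The five behavioral-disinhibition composites (nicotine, alcohol consumption,
alcohol dependence, illicit drugs, non-substance BD) are heavily skewed;
mixed-model Wald tests on raw scores would inflate type-I error, so each
phenotype is mapped to normal quantiles of its shifted ranks before any
testing.  Because siblings are correlated, the descriptive between-phenotype
correlation screen samples one offspring per family.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .families import Family

PHENOTYPE_NAMES = (
    "nicotine",
    "alcohol_consumption",
    "alcohol_dependence",
    "illicit_drugs",
    "BD",
)


def rank_inverse_normal(values: Sequence[float], offset: float = 0.375) -> np.ndarray:
    """Blom-type rank-based inverse normal transform.

    A non-missing value with (mean-tie) rank r among n non-missing values
    maps to Phi^-1((r - offset) / (n - 2*offset + 1)).  Missing entries stay
    missing.  The default offset 0.375 is the Blom constant.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"need at least 2 non-missing values, got {n}")
    obs = x[mask]
    if np.all(obs == obs[0]):
        warnings.warn(
            "all values identical; rank inverse normal maps them all to 0",
            stacklevel=2,
        )
    ranks = stats.rankdata(obs, method="average")
    out = np.full_like(x, np.nan)
    out[mask] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


class RankInverseNormal(TransformerMixin, BaseEstimator):
    """Column-wise rank-based inverse normal transform.

    ``fit_transform`` applies the transform to the data itself (the usual
    use: transform the full offspring phenotype table once).  ``transform``
    on new data interpolates against the fitted reference sample, so the
    estimator composes with sklearn pipelines and model selection.
    """

    def __init__(self, offset: float = 0.375):
        self.offset = offset

    def fit(self, X, y=None):
        X = self._as_array(X)
        self.n_features_in_ = X.shape[1]
        self.reference_ = [np.sort(col[~np.isnan(col)]) for col in X.T]
        self.reference_transformed_ = [
            rank_inverse_normal(ref, self.offset) if ref.size >= 2 else ref
            for ref in self.reference_
        ]
        return self

    def transform(self, X):
        X = self._as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        out = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            ref, ref_t = self.reference_[j], self.reference_transformed_[j]
            mask = ~np.isnan(X[:, j])
            out[mask, j] = np.interp(X[mask, j], ref, ref_t)
        return out

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X)
        arr = self._as_array(X)
        out = np.column_stack(
            [rank_inverse_normal(arr[:, j], self.offset) for j in range(arr.shape[1])]
        )
        return out

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X


def transform_phenotypes(
    pheno: pd.DataFrame,
    columns: Iterable[str] | None = None,
    offset: float = 0.375,
) -> pd.DataFrame:
    """Return a copy of ``pheno`` with the named columns INT-transformed."""
    out = pheno.copy()
    cols = list(columns) if columns is not None else [
        c for c in PHENOTYPE_NAMES if c in pheno.columns
    ]
    for c in cols:
        out[c] = rank_inverse_normal(pheno[c].to_numpy(dtype=float), offset)
    return out


def spearman_screen(
    pheno: pd.DataFrame,
    families: Sequence[Family],
    seed: int,
    columns: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pairwise Spearman correlations on one random offspring per family.

    ``pheno`` must be indexed by individual ID (or contain an ``iid``
    column) and hold the phenotype columns.  Returns (rho, p_values,
    sampled_ids); the diagonal of rho is 1 and of p_values is 0.
    """
    if "iid" in pheno.columns:
        pheno = pheno.set_index("iid")
    cols = list(columns) if columns is not None else [
        c for c in PHENOTYPE_NAMES if c in pheno.columns
    ]
    if not cols:
        raise ValueError("no phenotype columns found")

    rng = np.random.default_rng(seed)
    sampled: list[str] = []
    for fam in families:
        candidates = [o.id for o in fam.offspring if o.id in pheno.index]
        if not candidates:
            continue
        sampled.append(candidates[rng.integers(len(candidates))])
    if len(sampled) < 3:
        raise ValueError(
            f"need at least 3 sampled offspring, got {len(sampled)}"
        )

    sub = pheno.loc[sampled, cols].to_numpy(dtype=float)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.spearmanr(sub[:, i], sub[:, j], nan_policy="omit")
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
        sampled,
    )


def qq_export(values: Sequence[float]) -> pd.DataFrame:
    """Theoretical vs empirical normal quantiles for Q-Q plotting.

    Returns a DataFrame (theoretical, empirical) sorted by quantile; plotting
    itself is left to the caller.
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[~np.isnan(x)])
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return pd.DataFrame(
        {"theoretical": stats.norm.ppf(probs), "empirical": x}
    )
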