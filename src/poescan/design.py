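"""Parental-origin coding of offspring minor alleles from trio genotypes.

For a biallelic SNP with minor allele A, the paternally derived indicator
PD and maternally derived indicator MD count the minor alleles an offspring
inherited from each parent.  With both parental genotypes known, the trio
determines (PD, MD) uniquely for every Mendelian-consistent combination
except the triple heterozygote Aa x Aa -> Aa, where either parent may have
transmitted the minor allele; that trio is coded (0.5, 0.5).  Trios that are
impossible under biparental transmission are flagged as Mendelian errors and
coded missing, as is any trio with a missing genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .families import Family
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)


class PdMd(NamedTuple):
    pd: float  # nan when undetermined
    md: float
    mendelian_error: bool


class SkipSnp(Exception):
    """No usable offspring for this SNP; the scan records it as untested."""


def _transmissible(dosage: int) -> tuple[int, ...]:
    # minor-allele count a parent can transmit in one gamete
    return ((0,), (0, 1), (1,))[dosage]


def derive_pd_md(
    father_dosage: float, mother_dosage: float, offspring_dosage: float
) -> PdMd:
    """Code one trio into (PD, MD).

    Dosages count the minor allele (0, 1, 2, or NaN/None for missing).
    Returns (nan, nan, False) for missing input, (nan, nan, True) for a
    Mendelian-inconsistent trio, and (0.5, 0.5, False) for the ambiguous
    all-heterozygous trio.
    """
    doses = []
    for name, d in (
        ("father", father_dosage),
        ("mother", mother_dosage),
        ("offspring", offspring_dosage),
    ):
        if d is None or (isinstance(d, float) and np.isnan(d)):
            return PdMd(np.nan, np.nan, False)
        if d not in (0, 1, 2):
            raise ValueError(f"{name} dosage {d!r} outside {{0, 1, 2, missing}}")
        doses.append(int(d))
    f, m, o = doses

    consistent = {
        (p, q)
        for p in _transmissible(f)
        for q in _transmissible(m)
        if p + q == o
    }
    if not consistent:
        return PdMd(np.nan, np.nan, True)
    if len(consistent) == 1:
        p, q = next(iter(consistent))
        return PdMd(float(p), float(q), False)
    # both (0,1) and (1,0) fit: only the Aa x Aa -> Aa trio
    return PdMd(0.5, 0.5, False)


def derive_pd_md_array(
    father: np.ndarray, mother: np.ndarray, offspring: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized trio coding: returns (pd, md, mendelian_error) arrays."""
    f = np.asarray(father, dtype=float)
    m = np.asarray(mother, dtype=float)
    o = np.asarray(offspring, dtype=float)
    pd_out = np.full(f.shape, np.nan)
    md_out = np.full(f.shape, np.nan)
    err = np.zeros(f.shape, dtype=bool)
    table = _lookup_table()
    complete = ~(np.isnan(f) | np.isnan(m) | np.isnan(o))
    idx = (
        f[complete].astype(int) * 9
        + m[complete].astype(int) * 3
        + o[complete].astype(int)
    )
    pd_out[complete] = table[0][idx]
    md_out[complete] = table[1][idx]
    err[complete] = table[2][idx]
    return pd_out, md_out, err


_TABLE_CACHE: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _lookup_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        pd_t = np.empty(27)
        md_t = np.empty(27)
        er_t = np.empty(27, dtype=bool)
        for f in range(3):
            for m in range(3):
                for o in range(3):
                    r = derive_pd_md(f, m, o)
                    pd_t[f * 9 + m * 3 + o] = r.pd
                    md_t[f * 9 + m * 3 + o] = r.md
                    er_t[f * 9 + m * 3 + o] = r.mendelian_error
        _TABLE_CACHE = (pd_t, md_t, er_t)
    return _TABLE_CACHE


@dataclass
class DesignReport:
    snp_id: str
    n_offspring: int
    n_used: int
    n_mendelian_errors: int
    n_missing: int


def build_design(
    geno: GenotypeMatrix,
    families: Sequence[Family],
    snp_id: str,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, DesignReport]:
    """Per-offspring (PD, MD) rows for one SNP.

    Returns a DataFrame indexed by offspring ID with columns family_id, pd,
    md plus any covariate columns (joined on individual ID), restricted to
    offspring whose trio yields a non-missing coding and whose covariates
    are complete.  Raises :class:`SkipSnp` when no offspring is usable.
    """
    pos = {iid: i for i, iid in enumerate(geno.individuals)}
    fids, oids, f_idx, m_idx, o_idx = [], [], [], [], []
    for fam in families:
        if not fam.is_complete:
            continue
        if fam.father.id not in pos or fam.mother.id not in pos:
            continue
        for off in fam.offspring:
            if off.id not in pos:
                continue
            fids.append(fam.family_id)
            oids.append(off.id)
            f_idx.append(pos[fam.father.id])
            m_idx.append(pos[fam.mother.id])
            o_idx.append(pos[off.id])

    n_total = len(oids)
    if n_total == 0:
        raise SkipSnp(f"{snp_id}: no genotyped trios")
    col = geno.snp_column(snp_id)
    pd_v, md_v, err = derive_pd_md_array(col[f_idx], col[m_idx], col[o_idx])
    design = pd.DataFrame(
        {"family_id": fids, "pd": pd_v, "md": md_v},
        index=pd.Index(oids, name="offspring_id"),
    )
    usable = ~np.isnan(pd_v)
    n_err = int(err.sum())
    if covariates is not None:
        cov = covariates.set_index("iid") if "iid" in covariates.columns else covariates
        design = design.join(cov, how="left")
        usable &= ~design.drop(columns=["family_id"]).isna().any(axis=1).to_numpy()
    design = design.loc[usable]
    report = DesignReport(
        snp_id=snp_id,
        n_offspring=n_total,
        n_used=int(usable.sum()),
        n_mendelian_errors=n_err,
        n_missing=n_total - int(usable.sum()) - n_err,
    )
    if report.n_used == 0:
        raise SkipSnp(f"{snp_id}: no informative offspring")
    if n_err:
        logger.debug("%s: %d Mendelian-inconsistent trios set missing", snp_id, n_err)
    return design, report
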