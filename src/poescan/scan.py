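"""Genome scan driver: per-SNP, per-phenotype POE tests and imprinting calls.

For every autosomal SNP and phenotype the driver codes the trios into
(PD, MD), fits the parent-of-origin mixed model (or the plain genotype
model), applies the three tests, and classifies the SNP: a genome-wide
significant paternally derived effect (p_paternal < alpha_gw) together
with a significant asymmetry (p_diff < alpha_diff) is evidence that the
maternal copy is silenced — maternal imprinting — and symmetrically for
paternal imprinting.  Thresholds are strict inequalities; per-SNP failures
are recorded as "untested" and never abort the scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import SkipSnp, build_design
from .families import Family
from .genotypes import GenotypeMatrix
from .lmm import KinshipMatrix, LmmError, build_kinship, fit_lmm, genotype_test, poe_tests

logger = logging.getLogger(__name__)

CLASSIFICATIONS = (
    "maternal_imprinting",
    "paternal_imprinting",
    "maternal_imprinting+paternal_imprinting",
    "none",
    "untested",
)

#: conventional genome-wide significance for the per-parent Wald tests
ALPHA_GENOME_WIDE = 5e-8
#: nominal level for the imprinting-asymmetry (b1 = b2) test
ALPHA_DIFF = 0.05

DEFAULT_COVARIATES = ("sex", "age", "birth_year")


def classify_imprinting(
    p_paternal: float,
    p_maternal: float,
    p_diff: float,
    alpha_gw: float = ALPHA_GENOME_WIDE,
    alpha_diff: float = ALPHA_DIFF,
) -> str:
    """Imprinting call from the three test p-values (strict thresholds).

    Significant paternally derived effect plus significant asymmetry means
    the maternally inherited copy is inert: maternal imprinting.  The dual
    holds for paternal imprinting.  Both at once is possible in principle
    and reported as a combined label with a warning.
    """
    for name, p in (
        ("p_paternal", p_paternal),
        ("p_maternal", p_maternal),
        ("p_diff", p_diff),
    ):
        if not (0.0 <= p <= 1.0) or np.isnan(p):
            raise ValueError(f"{name}={p!r} is not a valid p-value")
    maternal = p_paternal < alpha_gw and p_diff < alpha_diff
    paternal = p_maternal < alpha_gw and p_diff < alpha_diff
    if maternal and paternal:
        warnings.warn(
            "both paternally and maternally derived effects are genome-wide "
            "significant with significant asymmetry",
            stacklevel=2,
        )
        return "maternal_imprinting+paternal_imprinting"
    if maternal:
        return "maternal_imprinting"
    if paternal:
        return "paternal_imprinting"
    return "none"


@dataclass
class PoeResult:
    snp_id: str
    chromosome: str
    position: int
    allele_minor: str
    maf: Optional[float]
    phenotype: str
    model: str
    beta1: float = np.nan
    beta2: float = np.nan
    beta: float = np.nan
    ci1_low: float = np.nan
    ci1_high: float = np.nan
    ci2_low: float = np.nan
    ci2_high: float = np.nan
    ci_diff_low: float = np.nan
    ci_diff_high: float = np.nan
    p_paternal: float = np.nan
    p_maternal: float = np.nan
    p_diff: float = np.nan
    p_genotype: float = np.nan
    n_used: int = 0
    classification: str = "untested"
    skip_reason: str = ""


def run_scan(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    families: Sequence[Family],
    model: str = "poe",
    phenotypes: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    kinship: KinshipMatrix | None = None,
    alpha_gw: float = ALPHA_GENOME_WIDE,
    alpha_diff: float = ALPHA_DIFF,
    center_covariates: bool = True,
) -> pd.DataFrame:
    """Scan all SNPs x phenotypes; returns one row per pair.

    ``pheno`` is indexed by individual ID (or has an ``iid`` column) and
    holds already-transformed phenotype columns plus the covariate columns.
    The genotype model uses exactly the offspring usable under the POE
    coding at each SNP, so the two scans are comparable SNP by SNP.
    """
    if "iid" in pheno.columns:
        pheno = pheno.set_index("iid")
    if phenotypes is None:
        phenotypes = [
            c for c in pheno.columns if c not in covariates and c != "family_id"
        ]
    if kinship is None:
        kinship = build_kinship(families)
    covariates = list(covariates)
    cov_table = pheno[covariates].apply(pd.to_numeric) if covariates else None

    results: list[PoeResult] = []
    for snp in geno.snps:
        base = dict(
            snp_id=snp.snp_id,
            chromosome=snp.chromosome,
            position=snp.position,
            allele_minor=snp.allele_minor,
            maf=snp.maf,
        )
        try:
            design, _ = build_design(geno, families, snp.snp_id, cov_table)
        except SkipSnp as exc:
            for ph in phenotypes:
                results.append(
                    PoeResult(
                        **base, phenotype=ph, model=model,
                        skip_reason=str(exc),
                    )
                )
            continue
        for ph in phenotypes:
            results.append(
                _scan_one(
                    base, design, pheno[ph], ph, covariates, kinship, model,
                    alpha_gw, alpha_diff, center_covariates,
                )
            )
    logger.info("scan finished: %d results", len(results))
    return results_frame(results)


def _scan_one(
    base, design, y_series, phenotype, covariates, kinship, model,
    alpha_gw, alpha_diff, center_covariates,
) -> PoeResult:
    rows = design.join(y_series.rename("_y"), how="inner").dropna(subset=["_y"])
    if rows.empty:
        return PoeResult(
            **base, phenotype=phenotype, model=model,
            skip_reason="no offspring with phenotype",
        )
    y = rows["_y"].to_numpy(dtype=float)
    Z = rows[covariates].to_numpy(dtype=float) if covariates else np.empty((len(rows), 0))
    if center_covariates and Z.size:
        Z = Z - Z.mean(axis=0)
        if "sex" in covariates:  # keep the 0/1 indicator uncentered
            j = covariates.index("sex")
            Z[:, j] = rows["sex"].to_numpy(dtype=float)
    if model == "poe":
        X = np.column_stack([rows["pd"], rows["md"], Z])
    else:
        X = np.column_stack([rows["pd"] + rows["md"], Z])
    try:
        fit = fit_lmm(
            y, X, kinship, sample_ids=list(rows.index), model=model
        )
        if model == "poe":
            tests = poe_tests(fit)
            classification = classify_imprinting(
                tests.p_paternal, tests.p_maternal, tests.p_diff,
                alpha_gw, alpha_diff,
            )
            return PoeResult(
                **base, phenotype=phenotype, model=model,
                beta1=fit.beta1, beta2=fit.beta2,
                ci1_low=tests.ci_paternal[0], ci1_high=tests.ci_paternal[1],
                ci2_low=tests.ci_maternal[0], ci2_high=tests.ci_maternal[1],
                ci_diff_low=tests.ci_diff[0], ci_diff_high=tests.ci_diff[1],
                p_paternal=tests.p_paternal, p_maternal=tests.p_maternal,
                p_diff=tests.p_diff, n_used=fit.n_used,
                classification=classification,
            )
        p, ci = genotype_test(fit)
        return PoeResult(
            **base, phenotype=phenotype, model=model,
            beta=fit.beta, ci1_low=ci[0], ci1_high=ci[1],
            p_genotype=p, n_used=fit.n_used,
            classification="none",
        )
    except LmmError as exc:
        logger.warning("%s/%s: %s", base["snp_id"], phenotype, exc)
        return PoeResult(
            **base, phenotype=phenotype, model=model, skip_reason=str(exc)
        )


def results_frame(results: Sequence[PoeResult]) -> pd.DataFrame:
    import dataclasses

    columns = [f.name for f in dataclasses.fields(PoeResult)]
    return pd.DataFrame([vars(r) for r in results], columns=columns)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write the scan results as TSV (round-trips with pandas.read_csv)."""
    results.to_csv(path, sep="\t", index=False)


def manhattan_export(results: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """One row per SNP-phenotype-test with -log10 p, for Manhattan plots."""
    tests = (
        ("paternal", "p_paternal"),
        ("maternal", "p_maternal"),
        ("difference", "p_diff"),
        ("genotype", "p_genotype"),
    )
    rows = []
    for _, r in results.iterrows():
        for test, col in tests:
            p = r.get(col, np.nan)
            if pd.isna(p):
                continue
            rows.append(
                {
                    "snp_id": r["snp_id"],
                    "chromosome": r["chromosome"],
                    "position": r["position"],
                    "phenotype": r["phenotype"],
                    "test": test,
                    "p_value": p,
                    "neg_log10_p": -np.log10(max(p, 1e-300)),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chromosome", "position", "phenotype", "test",
            "p_value", "neg_log10_p",
        ],
    )
    out.to_csv(path, sep="\t", index=False)
    return out
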