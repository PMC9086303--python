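"""Biallelic genotype container, loaders and quality control.

Genotypes are stored as minor-allele dosages (0/1/2, NaN for missing) in an
individuals x SNPs matrix.  QC applies, in a fixed order: restriction to
autosomes, SNP call rate, minor allele frequency (computed on founders), and
individual call rate.  Thresholds are "keep when >=": a SNP with call rate
exactly at the threshold passes.  No Hardy-Weinberg filter is applied —
with complete-family data the analysis does not rest on HWE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = frozenset(str(i) for i in range(1, 23))


class QcError(ValueError):
    """QC removed every SNP or every individual; carries the report."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        self.report = report


@dataclass
class SnpMeta:
    snp_id: str
    chromosome: str
    position: int
    allele_minor: str = "A"
    allele_major: str = "B"
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        self.chromosome = str(self.chromosome)
        if self.allele_minor == self.allele_major:
            raise ValueError(
                f"{self.snp_id}: minor and major allele are both "
                f"{self.allele_minor!r}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside [0, 0.5]")

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with row (individual) and column (SNP) labels."""

    individuals: list[str]
    snps: list[SnpMeta]
    dosage: np.ndarray  # float array, entries in {0, 1, 2, nan}

    _snp_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosage[~valid].flat[0]
            raise ValueError(f"dosage entry {bad!r} outside {{0, 1, 2, missing}}")
        self._snp_index = {s.snp_id: j for j, s in enumerate(self.snps)}
        if len(self._snp_index) != len(self.snps):
            raise ValueError("duplicate SNP IDs")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self._snp_index[snp_id]]

    def dosage_of(self, individual_ids: Sequence[str], snp_id: str) -> np.ndarray:
        idx = pd.Index(self.individuals).get_indexer(list(individual_ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(individual_ids, idx) if j < 0]
            raise KeyError(f"individuals not in genotype matrix: {missing[:5]}")
        return self.dosage[idx, self._snp_index[snp_id]]

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        snp_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals)
        cols = np.arange(self.n_snps)
        inds = self.individuals
        snps = self.snps
        if individuals is not None:
            pos = {iid: i for i, iid in enumerate(self.individuals)}
            rows = np.array([pos[i] for i in individuals], dtype=int)
            inds = list(individuals)
        if snp_ids is not None:
            cols = np.array([self._snp_index[s] for s in snp_ids], dtype=int)
            snps = [self.snps[j] for j in cols]
        return GenotypeMatrix(inds, snps, self.dosage[np.ix_(rows, cols)])


def snp_call_rate(dosage_column: np.ndarray) -> float:
    """Fraction of non-missing genotypes in one SNP column."""
    col = np.asarray(dosage_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty dosage column")
    return float(np.mean(~np.isnan(col)))


def minor_allele_frequency(
    dosage_column: np.ndarray,
    founder_mask: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Founder-based minor allele frequency.

    Returns (maf, needs_swap): when the counted allele turns out to be the
    major one (frequency > 0.5), the complemented frequency is returned and
    needs_swap is True, meaning dosages should be recoded 2 - d and the
    allele labels exchanged.
    """
    col = np.asarray(dosage_column, dtype=float)
    if founder_mask is not None:
        col = col[np.asarray(founder_mask, dtype=bool)]
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError("no non-missing founder genotypes")
    p = float(col.sum() / (2 * col.size))
    if p > 0.5:
        return 1.0 - p, True
    return p, False


def normalize_minor_allele(
    geno: GenotypeMatrix, founder_ids: Iterable[str] | None = None
) -> GenotypeMatrix:
    """Recode every SNP so the stored dosage counts the minor allele.

    MAF is computed on founders when ``founder_ids`` is given, else on all
    individuals, and recorded in each SnpMeta.
    """
    mask = _founder_mask(geno, founder_ids)
    dosage = geno.dosage.copy()
    snps = []
    for j, snp in enumerate(geno.snps):
        maf, swap = minor_allele_frequency(dosage[:, j], mask)
        if swap:
            dosage[:, j] = 2.0 - dosage[:, j]
            snps.append(
                replace(
                    snp,
                    allele_minor=snp.allele_major,
                    allele_major=snp.allele_minor,
                    maf=maf,
                )
            )
        else:
            snps.append(replace(snp, maf=maf))
    return GenotypeMatrix(list(geno.individuals), snps, dosage)


def _founder_mask(
    geno: GenotypeMatrix, founder_ids: Iterable[str] | None
) -> np.ndarray:
    if founder_ids is None:
        return np.ones(geno.n_individuals, dtype=bool)
    founders = set(founder_ids)
    return np.array([i in founders for i in geno.individuals], dtype=bool)


def apply_qc(
    geno: GenotypeMatrix,
    founder_ids: Iterable[str] | None = None,
    snp_call_min: float = 0.99,
    maf_min: float = 0.01,
    ind_call_min: float = 0.99,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the fixed-order QC filters; return (filtered, report).

    Order: non-autosomal SNPs out; SNP call rate; founder MAF (with
    minor-allele normalization); individual call rate computed on the
    surviving SNPs.  Raises QcError (report attached) if nothing survives.
    """
    for name, thr in (
        ("snp_call_min", snp_call_min),
        ("maf_min", maf_min),
        ("ind_call_min", ind_call_min),
    ):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")

    report_rows = []
    n0 = geno.n_snps

    autosomal = [s.snp_id for s in geno.snps if s.is_autosomal]
    geno = geno.subset(snp_ids=autosomal)
    report_rows.append(("non_autosomal_snps_removed", n0 - geno.n_snps))

    rates = np.mean(~np.isnan(geno.dosage), axis=0)
    keep = rates >= snp_call_min
    report_rows.append(("snp_call_rate_removed", int((~keep).sum())))
    geno = geno.subset(snp_ids=[s.snp_id for s, k in zip(geno.snps, keep) if k])

    if geno.n_snps:
        geno = normalize_minor_allele(geno, founder_ids)
        mafs = np.array([s.maf for s in geno.snps])
        keep = mafs >= maf_min
        report_rows.append(("maf_removed", int((~keep).sum())))
        geno = geno.subset(
            snp_ids=[s.snp_id for s, k in zip(geno.snps, keep) if k]
        )
    else:
        report_rows.append(("maf_removed", 0))

    if geno.n_snps == 0:
        report = _report_frame(report_rows + [("individual_call_rate_removed", 0)])
        raise QcError("QC removed all SNPs", report)

    ind_rates = np.mean(~np.isnan(geno.dosage), axis=1)
    keep_ind = ind_rates >= ind_call_min
    report_rows.append(("individual_call_rate_removed", int((~keep_ind).sum())))
    geno = geno.subset(
        individuals=[i for i, k in zip(geno.individuals, keep_ind) if k]
    )
    report = _report_frame(report_rows)
    if geno.n_individuals == 0:
        raise QcError("QC removed all individuals", report)
    logger.info(
        "QC kept %d SNPs / %d individuals", geno.n_snps, geno.n_individuals
    )
    return geno, report


def _report_frame(rows: list[tuple[str, int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["step", "n_removed"])


# ---------------------------------------------------------------------------
# loaders

def read_dosage_tsv(dosage_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV (rows=individuals, header=SNP IDs, first col=iid)
    plus a PLINK .map-style metadata file (chrom, snp_id, cM, position,
    optionally minor and major allele)."""
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    meta = read_map(map_path)
    meta_by_id = {m.snp_id: m for m in meta}
    try:
        snps = [meta_by_id[c] for c in df.columns]
    except KeyError as exc:
        raise ValueError(f"SNP {exc} in dosage file missing from map") from exc
    return GenotypeMatrix(list(df.index), snps, df.to_numpy(dtype=float))


def read_map(path: str | Path) -> list[SnpMeta]:
    meta = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=4 columns"
                )
            kwargs = {}
            if len(f) >= 6:
                kwargs = {"allele_minor": f[4], "allele_major": f[5]}
            meta.append(
                SnpMeta(
                    snp_id=f[1], chromosome=f[0], position=int(f[3]), **kwargs
                )
            )
    return meta


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK .ped/.map allele-pair text into a dosage matrix.

    The allele counted at each SNP is provisional (the lexicographically
    first observed allele); run :func:`normalize_minor_allele` (or
    :func:`apply_qc`) afterwards so dosages count the true minor allele.
    '0' alleles mark missing genotypes.
    """
    meta = read_map(map_path)
    n_snps = len(meta)
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    allele_pairs: list[list[str]] = [[] for _ in range(n_snps)]
    raw: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_snps} "
                    f"columns, got {len(f)}"
                )
            individuals.append(f[1])
            pairs = [(f[6 + 2 * j], f[7 + 2 * j]) for j in range(n_snps)]
            raw.append(pairs)
            for j, (a, b) in enumerate(pairs):
                for al in (a, b):
                    if al != "0" and al not in allele_pairs[j]:
                        allele_pairs[j].append(al)
    if len(set(individuals)) != len(individuals):
        raise ValueError(f"{ped_path}: duplicate individual IDs")

    snps = []
    for j, m in enumerate(meta):
        alleles = sorted(allele_pairs[j])
        if len(alleles) > 2:
            # treat as biallelic counted-vs-rest: first allele vs pooled rest
            counted, other = alleles[0], ",".join(alleles[1:])
        elif len(alleles) == 2:
            counted, other = alleles
        elif len(alleles) == 1:
            counted, other = alleles[0], "?"
        else:
            counted, other = "A", "B"
        snps.append(
            SnpMeta(m.snp_id, m.chromosome, m.position, counted, other)
        )

    dosage = np.full((len(individuals), n_snps), np.nan)
    for i, pairs in enumerate(raw):
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            counted = snps[j].allele_minor
            dosage[i, j] = (a == counted) + (b == counted)
    return GenotypeMatrix(individuals, snps, dosage)
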