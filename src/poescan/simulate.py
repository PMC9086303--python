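"""Synthetic MCTFR-style family dataset generator.

Generates nuclear families of the three informative types (twin, full
biological sibling, one-biological-offspring), biallelic autosomal SNPs
under Hardy-Weinberg equilibrium with configurable MAF, Mendelian
transmission with the true parental origin of every offspring allele
recorded, and quantitative phenotypes from the parent-of-origin linear
mixed model

    Y = b0 + b1*PD_true + b2*MD_true + g'Z + u + e

with the family random effect u drawn from the same relatedness structure
the analysis uses (MZ co-twins share u fully, sibs at correlation 0.5).
Defaults mirror the published family mix of the MCTFR behavioral-
disinhibition sample after filtering: 621 twin + 377 full-sib + 189
one-offspring families (2,185 offspring), offspring age 17.8 +/- 0.7,
father age 44.6 +/- 5.4, mother age 42.4 +/- 4.9.

Because the truth tables are captured before missingness or genotyping
error is injected, the trio coder and the Mendelian-error handling can be
validated against known answers at any configured error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .families import Family, Individual
from .genotypes import GenotypeMatrix, SnpMeta

DEFAULT_PHENOTYPES = (
    "nicotine",
    "alcohol_consumption",
    "alcohol_dependence",
    "illicit_drugs",
    "BD",
)


@dataclass
class SimConfig:
    """Generative settings; defaults are the study-scale conditions."""

    n_twin: int = 621
    n_fullsib: int = 377
    n_single: int = 189
    mz_fraction: float = 0.5
    n_snps: int = 1
    maf: float | tuple[float, float] = 0.3
    beta0: float = 0.0
    beta1: float = 0.5
    beta2: float = 0.0
    gamma: tuple[float, float, float] = (0.0, 0.0, 0.0)  # sex, age, birth_year
    sigma_b2: float = 0.5
    sigma_e2: float = 1.0
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    causal_snp: int = 0
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    sib_corr: float = 0.5
    mz_corr: float = 1.0
    assessment_year: int = 1995
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_twin", "n_fullsib", "n_single", "n_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mz_fraction", "missing_rate", "mendel_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf {self.maf} outside (0, 0.5]")
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")
        if self.n_snps and not (0 <= self.causal_snp < self.n_snps):
            raise ValueError("causal_snp out of range")

    @property
    def maf_range(self) -> tuple[float, float]:
        if isinstance(self.maf, (tuple, list)):
            return float(self.maf[0]), float(self.maf[1])
        return float(self.maf), float(self.maf)


@dataclass
class SimulatedDataset:
    config: SimConfig
    families: list[Family]
    genotypes: GenotypeMatrix  # after missingness / error injection
    truth_pd: np.ndarray  # offspring x snps, true paternal minor-allele count
    truth_md: np.ndarray
    perturbed: np.ndarray  # offspring x snps bool, genotyping error injected
    offspring_ids: list[str]
    covariates: pd.DataFrame  # per-individual sex/age/birth_year/role table
    phenotypes: pd.DataFrame = field(default=None)

    @property
    def truth_frame(self) -> pd.DataFrame:
        snp_ids = [s.snp_id for s in self.genotypes.snps]
        n_off, n_snp = self.truth_pd.shape
        return pd.DataFrame(
            {
                "offspring_id": np.repeat(self.offspring_ids, n_snp),
                "snp_id": np.tile(snp_ids, n_off),
                "pd": self.truth_pd.ravel(),
                "md": self.truth_md.ravel(),
                "perturbed": self.perturbed.ravel().astype(int),
            }
        )


def _make_families(config: SimConfig, rng: np.random.Generator) -> list[Family]:
    families: list[Family] = []
    counter = 0

    def new_individual(fid, suffix, role, sex, age, birth_year, zygosity="not_twin",
                       adopted=None):
        return Individual(
            id=f"{fid}_{suffix}",
            family_id=fid,
            role=role,
            sex=sex,
            age=round(float(age), 1),
            birth_year=int(birth_year),
            is_adopted=adopted,
            zygosity=zygosity,
        )

    specs = (
        [("twin", 2)] * config.n_twin
        + [("fullsib", 2)] * config.n_fullsib
        + [("single", 1)] * config.n_single
    )
    for kind, n_off in specs:
        counter += 1
        fid = f"F{counter:05d}"
        father_age = rng.normal(44.6, 5.4)
        mother_age = rng.normal(42.4, 4.9)
        father = new_individual(
            fid, "F", "father", "male", father_age,
            config.assessment_year - round(father_age),
        )
        mother = new_individual(
            fid, "M", "mother", "female", mother_age,
            config.assessment_year - round(mother_age),
        )
        offspring = []
        if kind == "twin":
            zyg = "MZ" if rng.random() < config.mz_fraction else "DZ"
            age = rng.normal(17.8, 0.7)
            sex = "male" if rng.random() < 0.5 else "female"
            by = config.assessment_year - round(age)
            for k in range(2):
                o_sex = sex if zyg == "MZ" else (
                    "male" if rng.random() < 0.5 else "female"
                )
                offspring.append(
                    new_individual(
                        fid, f"O{k + 1}", "offspring", o_sex, age, by,
                        zygosity=zyg, adopted=False,
                    )
                )
        else:
            ages = rng.normal(17.8, 0.7, size=n_off)
            for k in range(n_off):
                offspring.append(
                    new_individual(
                        fid, f"O{k + 1}", "offspring",
                        "male" if rng.random() < 0.5 else "female",
                        ages[k], config.assessment_year - round(ages[k]),
                        zygosity="not_twin", adopted=False,
                    )
                )
        families.append(
            Family(family_id=fid, father=father, mother=mother,
                   offspring=offspring)
        )
    return families


def simulate_genotypes(
    config: SimConfig,
    families: Sequence[Family] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Family], GenotypeMatrix, "SimulatedDataset"]:
    """Draw founder genotypes under HWE and transmit alleles Mendelianly.

    Returns (families, genotypes, dataset) where ``dataset`` carries the
    truth tables (recorded before missingness and error injection) and the
    post-injection genotype matrix.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if families is None:
        families = _make_families(config, rng)
    families = list(families)

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps) if lo < hi else np.full(
        config.n_snps, lo
    )

    ind_ids: list[str] = []
    for fam in families:
        ind_ids.extend(m.id for m in fam.members())
    pos = {iid: i for i, iid in enumerate(ind_ids)}
    n_ind, n_snp = len(ind_ids), config.n_snps

    # founder allele pairs: haplotype Bernoulli draws per parent
    allele1 = np.zeros((n_ind, n_snp), dtype=np.int8)
    allele2 = np.zeros((n_ind, n_snp), dtype=np.int8)
    for fam in families:
        for parent in (fam.father, fam.mother):
            i = pos[parent.id]
            allele1[i] = rng.random(n_snp) < mafs
            allele2[i] = rng.random(n_snp) < mafs

    offspring_ids: list[str] = []
    truth_pd_rows: list[np.ndarray] = []
    truth_md_rows: list[np.ndarray] = []
    for fam in families:
        fi, mi = pos[fam.father.id], pos[fam.mother.id]
        is_mz = (
            len(fam.offspring) == 2
            and all(o.zygosity == "MZ" for o in fam.offspring)
        )
        shared_pat = rng.random(n_snp) < 0.5
        shared_mat = rng.random(n_snp) < 0.5
        for off in fam.offspring:
            if is_mz:
                pick_pat, pick_mat = shared_pat, shared_mat
            else:
                pick_pat = rng.random(n_snp) < 0.5
                pick_mat = rng.random(n_snp) < 0.5
            pat_allele = np.where(pick_pat, allele1[fi], allele2[fi])
            mat_allele = np.where(pick_mat, allele1[mi], allele2[mi])
            i = pos[off.id]
            allele1[i] = pat_allele
            allele2[i] = mat_allele
            offspring_ids.append(off.id)
            truth_pd_rows.append(pat_allele.astype(float))
            truth_md_rows.append(mat_allele.astype(float))

    dosage = (allele1 + allele2).astype(float)
    truth_pd = np.array(truth_pd_rows) if truth_pd_rows else np.empty((0, n_snp))
    truth_md = np.array(truth_md_rows) if truth_md_rows else np.empty((0, n_snp))

    # inject genotyping error (offspring only, so every error is a trio
    # inconsistency candidate) and missingness AFTER the truth is recorded
    perturbed = np.zeros((len(offspring_ids), n_snp), dtype=bool)
    if config.mendel_error_rate > 0 and offspring_ids:
        perturbed = rng.random((len(offspring_ids), n_snp)) < config.mendel_error_rate
        off_rows = np.array([pos[i] for i in offspring_ids])
        for r, c in zip(*np.nonzero(perturbed)):
            current = dosage[off_rows[r], c]
            choices = [d for d in (0.0, 1.0, 2.0) if d != current]
            dosage[off_rows[r], c] = choices[rng.integers(2)]
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    snps = [
        SnpMeta(
            snp_id=f"snp{j:05d}",
            chromosome=str(j % 22 + 1),
            position=(j // 22 + 1) * 10_000,
            allele_minor="A",
            allele_major="B",
            maf=float(mafs[j]),
        )
        for j in range(n_snp)
    ]
    geno = GenotypeMatrix(ind_ids, snps, dosage)

    covariates = pd.DataFrame(
        [
            {
                "iid": m.id,
                "fid": fam.family_id,
                "role": m.role,
                "sex": 1 if m.sex == "male" else 0,
                "age": m.age,
                "birth_year": m.birth_year,
                "adopted": int(bool(m.is_adopted)) if m.role == "offspring" else 0,
                "zygosity": m.zygosity,
            }
            for fam in families
            for m in fam.members()
        ]
    )
    dataset = SimulatedDataset(
        config=config,
        families=families,
        genotypes=geno,
        truth_pd=truth_pd,
        truth_md=truth_md,
        perturbed=perturbed,
        offspring_ids=offspring_ids,
        covariates=covariates,
    )
    return families, geno, dataset


def simulate_phenotypes(
    dataset: SimulatedDataset,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate offspring phenotypes from the true PD/MD at the causal SNP.

    Every configured phenotype column shares the same linear predictor
    (genetic + covariate effects) and receives its own family random effect
    and residual draw; the family effect respects the MZ/sib correlation
    structure used by the analysis kinship matrix.
    """
    config = dataset.config
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence([config.seed, 1])
    )
    cov = dataset.covariates.set_index("iid")
    off = cov.loc[dataset.offspring_ids]
    j = config.causal_snp
    g_sex, g_age, g_by = config.gamma
    eta = (
        config.beta0
        + config.beta1 * dataset.truth_pd[:, j]
        + config.beta2 * dataset.truth_md[:, j]
        + g_sex * off["sex"].to_numpy(dtype=float)
        + g_age * off["age"].to_numpy(dtype=float)
        + g_by * off["birth_year"].to_numpy(dtype=float)
    )
    n_off = len(dataset.offspring_ids)
    values: dict[str, np.ndarray] = {}
    row_of = {iid: i for i, iid in enumerate(dataset.offspring_ids)}
    for name in config.phenotypes:
        u = np.zeros(n_off)
        if config.sigma_b2 > 0:
            sd_b = np.sqrt(config.sigma_b2)
            for fam in dataset.families:
                ids = [o.id for o in fam.offspring]
                k = len(ids)
                if k == 0:
                    continue
                is_mz = k == 2 and all(o.zygosity == "MZ" for o in fam.offspring)
                c = config.mz_corr if is_mz else config.sib_corr
                B = np.full((k, k), c)
                np.fill_diagonal(B, 1.0)
                L = np.linalg.cholesky(B + 1e-12 * np.eye(k))
                draw = sd_b * (L @ rng.standard_normal(k))
                for iid, val in zip(ids, draw):
                    u[row_of[iid]] = val
        eps = rng.normal(0.0, np.sqrt(config.sigma_e2), size=n_off)
        values[name] = eta + u + eps

    pheno = pd.DataFrame(values, index=pd.Index(dataset.offspring_ids, name="iid"))
    pheno["sex"] = off["sex"].to_numpy(dtype=float)
    pheno["age"] = off["age"].to_numpy(dtype=float)
    pheno["birth_year"] = off["birth_year"].to_numpy(dtype=float)
    dataset.phenotypes = pheno
    return pheno


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full generative pass: families, genotypes, truth and phenotypes."""
    rng = np.random.default_rng(config.seed)
    _, _, dataset = simulate_genotypes(config, rng=rng)
    simulate_phenotypes(dataset, rng=rng)
    return dataset


def make_mctfr_composition() -> list[Family]:
    """Synthetic pedigree matching the published MCTFR sample composition.

    Reconstructs the pre-filtering family mix of the behavioral-
    disinhibition sample — 621 twin, 377 full-biological-sibling, 174
    one-biological-offspring, 15 mixed (one adoptee each), 16 all-adopted
    and 980 incomplete families; 2,183 families, 6,784 individuals — with
    synthetic IDs.  The incomplete ("other") group is realised as
    one-parent families (794 with one child, 186 with two), which matches
    its published individual count; any split works, since filtering drops
    the whole group.
    """
    families: list[Family] = []
    counter = 0

    def build(n_fams, offspring_spec, father=True, mother=True, zygosity="not_twin"):
        nonlocal counter
        for _ in range(n_fams):
            counter += 1
            fid = f"T{counter:05d}"
            fa = (
                Individual(f"{fid}_F", fid, "father", "male", 45.0, 1950)
                if father
                else None
            )
            mo = (
                Individual(f"{fid}_M", fid, "mother", "female", 43.0, 1952)
                if mother
                else None
            )
            offs = [
                Individual(
                    f"{fid}_O{k + 1}", fid, "offspring",
                    "male" if k % 2 == 0 else "female",
                    18.0, 1977, is_adopted=adopted, zygosity=zygosity,
                )
                for k, adopted in enumerate(offspring_spec)
            ]
            families.append(Family(fid, fa, mo, offs))

    build(621, [False, False], zygosity="DZ")          # twin
    build(377, [False, False])                         # full biological sibling
    build(174, [False])                                # one biological offspring
    build(15, [False, True])                           # mixed (one adoptee)
    build(16, [True, True])                            # all adopted
    build(794, [False], mother=False)                  # incomplete, one child
    build(186, [False, False], mother=False)           # incomplete, two children
    return families


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(dataset: SimulatedDataset, out_prefix: str | Path) -> dict[str, Path]:
    """Write the dataset as text files the pipeline ingests directly.

    Produces ``<prefix>.fam`` (FID IID PAT MAT SEX PHENO),
    ``<prefix>.dosage.tsv`` + ``<prefix>.map`` (minor-allele dosages and SNP
    metadata), ``<prefix>.covar.tsv``, ``<prefix>.pheno.tsv`` and
    ``<prefix>.truth.tsv`` (one row per offspring x SNP).
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fam": prefix.with_suffix(".fam"),
        "dosage": Path(str(prefix) + ".dosage.tsv"),
        "map": prefix.with_suffix(".map"),
        "covar": Path(str(prefix) + ".covar.tsv"),
        "pheno": Path(str(prefix) + ".pheno.tsv"),
        "truth": Path(str(prefix) + ".truth.tsv"),
    }

    with open(paths["fam"], "w") as fh:
        for fam in dataset.families:
            fh.write(f"{fam.family_id} {fam.father.id} 0 0 1 -9\n")
            fh.write(f"{fam.family_id} {fam.mother.id} 0 0 2 -9\n")
            for off in fam.offspring:
                sex_code = 1 if off.sex == "male" else 2
                fh.write(
                    f"{fam.family_id} {off.id} {fam.father.id} "
                    f"{fam.mother.id} {sex_code} -9\n"
                )

    geno = dataset.genotypes
    pd.DataFrame(
        geno.dosage,
        index=pd.Index(geno.individuals, name="iid"),
        columns=[s.snp_id for s in geno.snps],
    ).to_csv(paths["dosage"], sep="\t", na_rep="")

    with open(paths["map"], "w") as fh:
        for s in geno.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\t"
                f"{s.allele_minor}\t{s.allele_major}\n"
            )

    dataset.covariates.to_csv(paths["covar"], sep="\t", index=False)
    if dataset.phenotypes is not None:
        dataset.phenotypes.to_csv(paths["pheno"], sep="\t")
    dataset.truth_frame.to_csv(paths["truth"], sep="\t", index=False)
    return paths
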