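"""Nuclear-family pedigree parsing, classification and filtering.

Family-based parent-of-origin analysis needs complete nuclear families
(both parents genotyped) with biological offspring only: parental origin of
an offspring allele is inferred from the trio, so adopted offspring and
incomplete families carry no information.  This module reads PLINK-style
pedigree text plus an optional covariate table, classifies each family by
its offspring composition (twin / full biological sibling /
one-biological-offspring / mixed / all-adopted / other) and applies the
filtering that keeps only informative families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("father", "mother", "offspring")
SEXES = ("male", "female", "unknown")
ZYGOSITIES = ("MZ", "DZ", "not_twin", "unknown")

#: family-type labels, in the order used for summary tables
FAMILY_TYPES = (
    "twin",
    "full_biological_sibling",
    "one_biological_offspring",
    "mixed_offspring",
    "all_adopted_offspring",
    "other",
)


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree input."""


@dataclass
class Individual:
    id: str
    family_id: str
    role: str
    sex: str = "unknown"
    age: Optional[float] = None
    birth_year: Optional[int] = None
    is_adopted: Optional[bool] = None
    zygosity: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PedigreeError(f"unknown role {self.role!r} for {self.id!r}")
        if self.sex not in SEXES:
            raise PedigreeError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.zygosity not in ZYGOSITIES:
            raise PedigreeError(
                f"unknown zygosity {self.zygosity!r} for {self.id!r}"
            )
        if self.role == "father" and self.sex == "female":
            raise PedigreeError(f"father {self.id!r} recorded as female")
        if self.role == "mother" and self.sex == "male":
            raise PedigreeError(f"mother {self.id!r} recorded as male")
        if self.role != "offspring":
            # adoption status only means something for offspring
            self.is_adopted = None
        elif self.is_adopted is None:
            self.is_adopted = False


@dataclass
class Family:
    family_id: str
    father: Optional[Individual] = None
    mother: Optional[Individual] = None
    offspring: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        for member in self.members():
            if member.family_id != self.family_id:
                raise PedigreeError(
                    f"individual {member.id!r} has family_id "
                    f"{member.family_id!r}, expected {self.family_id!r}"
                )

    def members(self) -> list[Individual]:
        out = [p for p in (self.father, self.mother) if p is not None]
        return out + list(self.offspring)

    @property
    def n_individuals(self) -> int:
        return len(self.members())

    @property
    def is_complete(self) -> bool:
        return self.father is not None and self.mother is not None

    def biological_offspring(self) -> list[Individual]:
        return [o for o in self.offspring if not o.is_adopted]

    def adopted_offspring(self) -> list[Individual]:
        return [o for o in self.offspring if o.is_adopted]


def classify_family(family: Family) -> str:
    """Assign one of the six family-type labels.

    Incomplete families (a missing parent) and childless families are
    "other".  A complete family is "twin" when it has exactly two biological
    offspring, both flagged MZ or DZ, with equal birth years where known;
    two or more non-twin biological offspring give "full_biological_sibling".
    """
    if not family.is_complete or not family.offspring:
        return "other"
    bio = family.biological_offspring()
    adopted = family.adopted_offspring()
    if bio and adopted:
        return "mixed_offspring"
    if not bio:
        return "all_adopted_offspring"
    if len(bio) == 1:
        return "one_biological_offspring"
    if len(bio) == 2 and _is_twin_pair(bio[0], bio[1]):
        return "twin"
    return "full_biological_sibling"


def _is_twin_pair(a: Individual, b: Individual) -> bool:
    if a.zygosity not in ("MZ", "DZ") or b.zygosity not in ("MZ", "DZ"):
        return False
    if a.birth_year is not None and b.birth_year is not None:
        return a.birth_year == b.birth_year
    return True


def filter_families(
    families: Iterable[Family],
) -> tuple[list[Family], pd.DataFrame]:
    """Drop uninformative families; return (kept, Table-1-style summary).

    Adopted offspring are removed from every family first; families are then
    re-classified, and only complete families that still have at least one
    (biological) offspring are kept.  The summary counts families and
    individuals per original type, before and after filtering.
    """
    families = list(families)
    n_fam_before: dict[str, int] = {t: 0 for t in FAMILY_TYPES}
    n_ind_before: dict[str, int] = {t: 0 for t in FAMILY_TYPES}
    n_fam_after: dict[str, int] = {t: 0 for t in FAMILY_TYPES}
    n_ind_after: dict[str, int] = {t: 0 for t in FAMILY_TYPES}

    kept: list[Family] = []
    for fam in families:
        orig_type = classify_family(fam)
        n_fam_before[orig_type] += 1
        n_ind_before[orig_type] += fam.n_individuals

        trimmed = replace(fam, offspring=fam.biological_offspring())
        if not trimmed.is_complete or not trimmed.offspring:
            continue
        new_type = classify_family(trimmed)
        n_fam_after[new_type] += 1
        n_ind_after[new_type] += trimmed.n_individuals
        kept.append(trimmed)

    rows = []
    for t in FAMILY_TYPES:
        rows.append(
            {
                "family_type": t,
                "families_original": n_fam_before[t],
                "individuals_original": n_ind_before[t],
                "families_filtered": n_fam_after[t],
                "individuals_filtered": n_ind_after[t],
            }
        )
    rows.append(
        {
            "family_type": "total",
            "families_original": sum(n_fam_before.values()),
            "individuals_original": sum(n_ind_before.values()),
            "families_filtered": sum(n_fam_after.values()),
            "individuals_filtered": sum(n_ind_after.values()),
        }
    )
    summary = pd.DataFrame(rows)
    logger.info(
        "kept %d of %d families (%d of %d individuals)",
        len(kept),
        len(families),
        summary.iloc[-1]["individuals_filtered"],
        summary.iloc[-1]["individuals_original"],
    )
    return kept, summary


def count_offspring_parents(kept: Iterable[Family]) -> tuple[int, int]:
    """(n_parents, n_offspring) over an already-filtered family list."""
    kept = list(kept)
    n_parents = 2 * len(kept)
    n_offspring = sum(len(f.offspring) for f in kept)
    return n_parents, n_offspring


# ---------------------------------------------------------------------------
# input parsing

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown", "-9": "unknown"}


def read_pedigree(
    path: str | Path,
    dialect: str = "fam",
    covariates: str | Path | pd.DataFrame | None = None,
) -> list[Family]:
    """Parse pedigree text into Family objects.

    dialect "fam": whitespace-separated FID IID PAT MAT SEX PHENO (extra
    columns ignored; this also covers .ped files, whose genotype columns are
    read elsewhere).  dialect "table": a single TSV with header containing at
    least fid, iid, role; optional sex, age, birth_year, adopted, zygosity.
    A separate covariate table (TSV with header iid, and any of fid, role,
    sex, age, birth_year, adopted, zygosity) may accompany the fam dialect.

    Parent IDs of "0" mean an absent parent; a parent ID referenced by an
    offspring but missing from the file is recorded as absent with a warning.
    Individuals that belong to no family (no parents listed and never listed
    as a parent) are dropped with a logged count.
    """
    if dialect in ("fam", "ped"):
        records = _parse_fam_lines(path)
    elif dialect == "table":
        records = _parse_wide_table(path)
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")

    if covariates is not None:
        covar = (
            covariates
            if isinstance(covariates, pd.DataFrame)
            else pd.read_csv(covariates, sep="\t", dtype={"iid": str})
        )
        records = _merge_covariates(records, covar)
    return _assemble_families(records)


def _parse_fam_lines(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected at least 6 columns, "
                    f"got {len(fields)}"
                )
            fid, iid, pat, mat, sex = fields[:5]
            rows.append(
                {
                    "fid": fid,
                    "iid": iid,
                    "pat": pat,
                    "mat": mat,
                    "sex": _SEX_CODES.get(sex, "unknown"),
                    "lineno": lineno,
                }
            )
    df = pd.DataFrame(
        rows, columns=["fid", "iid", "pat", "mat", "sex", "lineno"]
    )
    dup = df["iid"].duplicated()
    if dup.any():
        bad = df.loc[dup, "iid"].iloc[0]
        raise PedigreeError(f"duplicate individual ID {bad!r}")
    return df


def _parse_wide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"fid", "iid", "role"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(
            f"{path}: missing required columns {sorted(missing)}"
        )
    if df["iid"].duplicated().any():
        bad = df.loc[df["iid"].duplicated(), "iid"].iloc[0]
        raise PedigreeError(f"duplicate individual ID {bad!r}")
    # synthesize PAT/MAT from roles within each family
    out_rows = []
    for fid, grp in df.groupby("fid", sort=False):
        fathers = grp.loc[grp["role"] == "father", "iid"].tolist()
        mothers = grp.loc[grp["role"] == "mother", "iid"].tolist()
        if len(fathers) > 1 or len(mothers) > 1:
            raise PedigreeError(f"family {fid!r}: more than one father/mother")
        pat = fathers[0] if fathers else "0"
        mat = mothers[0] if mothers else "0"
        for _, r in grp.iterrows():
            is_off = r["role"] == "offspring"
            out_rows.append(
                {
                    "fid": fid,
                    "iid": r["iid"],
                    "pat": pat if is_off else "0",
                    "mat": mat if is_off else "0",
                    "sex": r.get("sex", "unknown") or "unknown",
                    "role": r["role"],
                    "age": r.get("age"),
                    "birth_year": r.get("birth_year"),
                    "adopted": r.get("adopted"),
                    "zygosity": r.get("zygosity"),
                    "lineno": -1,
                }
            )
    return pd.DataFrame(out_rows)


def _merge_covariates(records: pd.DataFrame, covar: pd.DataFrame) -> pd.DataFrame:
    if "iid" not in covar.columns:
        raise PedigreeError("covariate table must have an 'iid' column")
    covar = covar.copy()
    covar["iid"] = covar["iid"].astype(str)
    extra = [
        c
        for c in ("role", "sex", "age", "birth_year", "adopted", "zygosity")
        if c in covar.columns
    ]
    merged = records.merge(covar[["iid"] + extra], on="iid", how="left",
                           suffixes=("", "_covar"))
    if "sex_covar" in merged.columns:
        # the pedigree file is authoritative for sex; covariates fill gaps
        unknown = merged["sex"].isin(["unknown", None]) | merged["sex"].isna()
        merged.loc[unknown, "sex"] = merged.loc[unknown, "sex_covar"]
        merged = merged.drop(columns=["sex_covar"])
    return merged


def _to_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("1", "1.0", "true", "yes", "y"):
        return True
    if s in ("0", "0.0", "false", "no", "n", ""):
        return False
    raise PedigreeError(f"cannot interpret adoption flag {value!r}")


def _assemble_families(records: pd.DataFrame) -> list[Family]:
    ids = set(records["iid"])
    father_of = dict(zip(records["iid"], records.get("pat", "0")))
    mother_of = dict(zip(records["iid"], records.get("mat", "0")))
    cited_fathers = {p for p in father_of.values() if p != "0"}
    cited_mothers = {m for m in mother_of.values() if m != "0"}
    referenced_parents = cited_fathers | cited_mothers

    families: dict[str, dict] = {}
    n_independent = 0
    for _, r in records.iterrows():
        fid = r["fid"]
        iid = r["iid"]
        role = r.get("role")
        if role is None or (isinstance(role, float) and pd.isna(role)):
            if iid in referenced_parents:
                role = "father" if iid in cited_fathers else "mother"
            elif father_of[iid] != "0" or mother_of[iid] != "0":
                role = "offspring"
            else:
                n_independent += 1
                continue
        entry = families.setdefault(
            fid, {"father": None, "mother": None, "offspring": []}
        )
        ind = Individual(
            id=iid,
            family_id=fid,
            role=role,
            sex=_norm_sex(r.get("sex", "unknown")),
            age=_opt_float(r.get("age")),
            birth_year=_opt_int(r.get("birth_year")),
            is_adopted=_to_bool(r.get("adopted")) if role == "offspring" else None,
            zygosity=_opt_zygosity(r.get("zygosity")),
        )
        if role == "father":
            if entry["father"] is not None:
                raise PedigreeError(f"family {fid!r}: more than one father")
            entry["father"] = ind
        elif role == "mother":
            if entry["mother"] is not None:
                raise PedigreeError(f"family {fid!r}: more than one mother")
            entry["mother"] = ind
        else:
            for parent_key, lookup in (("pat", father_of), ("mat", mother_of)):
                pid = lookup.get(iid, "0")
                if pid != "0" and pid not in ids:
                    logger.warning(
                        "offspring %s cites %s ID %s not present in file; "
                        "parent recorded as absent",
                        iid,
                        "father" if parent_key == "pat" else "mother",
                        pid,
                    )
            entry["offspring"].append(ind)

    if n_independent:
        logger.info("dropped %d independent individuals", n_independent)
    return [
        Family(family_id=fid, father=e["father"], mother=e["mother"],
               offspring=e["offspring"])
        for fid, e in families.items()
    ]


def _norm_sex(value) -> str:
    """Accept male/female names, PLINK 1/2 codes and M/F abbreviations."""
    if value is None:
        return "unknown"
    s = str(value).strip().lower()
    if s in ("male", "m", "1", "1.0"):
        return "male"
    if s in ("female", "f", "2", "2.0"):
        return "female"
    return "unknown"


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    try:
        if pd.isna(value):
            return None
    except (TypeError, ValueError):
        pass
    return float(value)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(round(f))


def _opt_zygosity(value) -> str:
    if value is None:
        return "unknown"
    try:
        if pd.isna(value):
            return "unknown"
    except (TypeError, ValueError):
        pass
    s = str(value).strip()
    return s if s in ZYGOSITIES else "unknown"
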