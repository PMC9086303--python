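import numpy as np
import pandas as pd
import pytest

import poescan as ps

COVARS = ["sex", "age", "birth_year"]


def poe_design_matrix(ds, snp_id="snp00000", phenotype="nicotine"):
    """Assemble (y, X, sample_ids, rows) for one SNP-phenotype fit: X columns
    are (PD, MD, sex, centered age, centered birth_year)."""
    design, _ = ps.build_design(
        ds.genotypes, ds.families, snp_id, ds.phenotypes[COVARS]
    )
    rows = design.join(ds.phenotypes[phenotype].rename("_y"), how="inner")
    rows = rows.dropna(subset=["_y"])
    y = rows["_y"].to_numpy(dtype=float)
    Z = rows[COVARS].to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    Z[:, 0] = rows["sex"].to_numpy(dtype=float)
    X = np.column_stack([rows["pd"], rows["md"], Z])
    return y, X, list(rows.index), rows


def fit_poe(ds, snp_id="snp00000", phenotype="nicotine", kinship=None):
    y, X, ids, _ = poe_design_matrix(ds, snp_id, phenotype)
    if kinship is None:
        kinship = ps.build_kinship(ds.families)
    return ps.fit_lmm(y, X, kinship, sample_ids=ids, model="poe")


@pytest.fixture(scope="session")
def small_dataset():
    """Modest simulated dataset shared by read-only tests."""
    cfg = ps.SimConfig(
        n_twin=60, n_fullsib=40, n_single=20, n_snps=4, seed=11
    )
    return ps.simulate_dataset(cfg)


@pytest.fixture()
def trio_family():
    def make(fid="F1", n_offspring=2, adopted=(), zygosity="not_twin",
             father=True, mother=True, birth_years=None):
        fa = ps.Individual(f"{fid}_F", fid, "father", "male", 45.0, 1950) if father else None
        mo = ps.Individual(f"{fid}_M", fid, "mother", "female", 43.0, 1952) if mother else None
        offs = []
        for k in range(n_offspring):
            by = birth_years[k] if birth_years else 1977
            offs.append(
                ps.Individual(
                    f"{fid}_O{k+1}", fid, "offspring",
                    "male" if k % 2 == 0 else "female",
                    18.0, by, is_adopted=k in adopted, zygosity=zygosity,
                )
            )
        return ps.Family(fid, fa, mo, offs)

    return make
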