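import numpy as np
import pandas as pd
import pytest

from epimdr import Cohort, biallelic_locus, default_loci, reconstructed_cohort


def make_cohort(genotypes: dict[str, list[str]], phenotype: list[int],
                loci=None, **covariates) -> Cohort:
    """Small-cohort builder for hand-traceable tests."""
    n = len(phenotype)
    if loci is None:
        loci = []
        for name in genotypes:
            alleles = sorted({ch for g in genotypes[name] if g != "NA" for ch in g})
            if len(alleles) == 1:  # monomorphic toy data still needs 3 categories
                alleles.append("B" if alleles[0] != "B" else "C")
            loci.append(biallelic_locus(name, alleles[0], alleles[1]))
    df = pd.DataFrame({"id": [f"i{j}" for j in range(n)],
                       "phenotype": phenotype,
                       "subtype": ["LAA" if p == 1 else "control" for p in phenotype],
                       **genotypes, **covariates})
    return Cohort(df, loci)


def random_small_cohort(rng: np.random.Generator, n_loci: int, n: int) -> Cohort:
    """Random cohort of <=30 individuals on 2-3 triallelic-category loci."""
    loci = [biallelic_locus(f"L{j}", "A", "B") for j in range(n_loci)]
    data = {"id": [f"i{j}" for j in range(n)]}
    # both classes guaranteed, at least 3 of each so 3-fold CV is legal
    phen = np.array([0, 0, 0, 1, 1, 1] + list(rng.integers(0, 2, n - 6)))
    data["phenotype"] = phen
    data["subtype"] = ["LAA" if p else "control" for p in phen]
    for loc in loci:
        data[loc.name] = rng.choice(loc.categories, size=n)
    return Cohort(pd.DataFrame(data), loci)


@pytest.fixture(scope="session")
def reconstruction() -> Cohort:
    return reconstructed_cohort(seed=0)


@pytest.fixture(scope="session")
def six_loci():
    return default_loci()
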