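import numpy as np
import pandas as pd
import pytest

from ssgblup.pedigree import PedigreeTable
from ssgblup.genomic import GenotypeMatrix


def random_pedigree(n: int, n_founders: int, seed: int) -> PedigreeTable:
    """Random valid pedigree: founders first, each later animal's parents
    drawn from earlier animals."""
    rng = np.random.default_rng(seed)
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    for i in range(n_founders, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire.append(int(s))
        dam.append(int(d))
    return PedigreeTable(ids=[f"a{i}" for i in range(n)],
                         sire=np.array(sire), dam=np.array(dam))


def hwe_genotypes(n: int, m: int, seed: int, p_range=(0.1, 0.5)) -> GenotypeMatrix:
    """Unrelated animals with genotypes in Hardy–Weinberg proportions."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    dos = ((rng.random((n, m)) < p).astype(float)
           + (rng.random((n, m)) < p).astype(float))
    mm = pd.DataFrame({"snp_id": [f"s{j}" for j in range(m)],
                       "chrom": 1, "bp": np.arange(1, m + 1) * 1000})
    return GenotypeMatrix(dosages=dos, marker_map=mm,
                          animal_ids=[f"a{i}" for i in range(n)])


@pytest.fixture(scope="session")
def ped50():
    return random_pedigree(50, 10, seed=42)
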