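import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass

from ldacc.data import Pedigree
from ldacc.simulate import (
    gene_drop,
    sample_architecture,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from ldacc.data import genotype_data_from_haplotypes


@pytest.fixture()
def toy_pedigree() -> Pedigree:
    """Five individuals: founders S, D; full sibs X, Y; Z from the full-sib
    mating X x Y (inbred, diagonal 1.25)."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["S", "D", "X", "Y", "Z"],
                "sire": ["0", "0", "S", "S", "X"],
                "dam": ["0", "0", "D", "D", "Y"],
                "sex": ["M", "F", "M", "F", "M"],
                "birth_year": [0, 0, 1, 1, 2],
            }
        )
    )


@pytest.fixture(scope="session")
def small_population():
    """A small simulated population shared by predictor/evaluation tests:
    3 generations, ~150 genotyped bulls, 300 markers + 100 hidden QTL
    candidates on 2 chromosomes."""
    ped = simulate_pedigree(3, 60, 20, 5.0, seed=2)
    founders = simulate_founder_haplotypes(
        len(ped.founders), 2, 150, 9_600_000, n_reserve_per_chrom=50, seed=4
    )
    haps = gene_drop(ped, founders, 1e-8, seed=5)
    arch = sample_architecture(founders, 20, 1.0, 0.53, seed=6)
    bulls = [i for i in ped.males if ped.birth_year_of(i) >= 1]
    phenotypes = simulate_phenotypes(haps, arch, bulls, seed=7)
    genotypes = genotype_data_from_haplotypes(haps, ids=bulls)
    return {
        "pedigree": ped,
        "founders": founders,
        "haplotypes": haps,
        "architecture": arch,
        "bulls": bulls,
        "phenotypes": phenotypes,
        "genotypes": genotypes,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929 % 2**16)
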