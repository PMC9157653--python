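"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from solgs import genotypes as gt
from solgs import simdata


@pytest.fixture(scope="session")
def small_pop() -> gt.GenotypeMatrix:
    """Cultivated + 7 wild groups, 84 accessions x 600 SNPs, with missing."""
    spec = simdata.PopulationSpec(
        n_cultivated=60,
        wild_group_sizes=(6, 5, 4, 3, 2, 2, 2),
        n_snps=600,
        n_chromosomes=6,
        ld_rho=0.9,
        fst_wild=0.3,
        missing_rate=0.05,
        seed=42,
    )
    return simdata.simulate_genotypes(spec)


@pytest.fixture(scope="session")
def qc_pop(small_pop) -> gt.GenotypeMatrix:
    """The small panel after the full QC chain (complete, polymorphic)."""
    G = gt.filter_missingness(small_pop, 0.5)
    G = gt.impute_missing(G)
    G = gt.filter_maf(G, 0.05)
    return gt.prune_redundant(G, 0.999)


@pytest.fixture(scope="session")
def cultivated_panel() -> gt.GenotypeMatrix:
    """A complete 200 x 800 cultivated-only panel for prediction tests."""
    spec = simdata.PopulationSpec(
        n_cultivated=200,
        wild_group_sizes=(1,),
        n_snps=800,
        n_chromosomes=8,
        ld_rho=0.7,
        missing_rate=0.0,
        seed=7,
    )
    return simdata.simulate_genotypes(spec).take_accessions(np.arange(200))
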