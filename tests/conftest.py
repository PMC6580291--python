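import numpy as np
import pytest

import hybridscape as hs
from hybridscape.genotypes import MISSING


@pytest.fixture(scope="session")
def four_taxon_data():
    """Small four-taxon dataset from the default study-design generator."""
    comp = hs.four_taxon_complex()
    gm, truth = hs.gen_species_complex(comp, n_ind=10, n_loci=300, missing_rate=0.05, seed=42)
    return gm, truth


@pytest.fixture
def toy_matrix():
    """4-species, 10-locus matrix with 2 SNPs sharing one tag, for filter tests.

    Layout (2 diploid individuals per species):
      - loci L0/L1 share tagA (one must be dropped by the one-per-tag rule)
      - locus L2 is genotyped in only 2 of 4 species (tag presence rule)
      - loci L3 and L4 are monomorphic (MAF 0, below the 1% rule)
      - locus L5 is missing in >60% of individuals (sample-fraction rule)
      - loci L6-L9 are clean polymorphic sites
    """
    n_ind, n_loci = 8, 10
    g = np.ones((n_ind, n_loci), dtype=np.int8)
    g[::2, :] = 0  # alternate 0/1 rows: every locus polymorphic, MAF 0.25
    g[:, 2] = [0, 1, 0, 1, MISSING, MISSING, MISSING, MISSING]  # only sp1, sp2
    g[:, 3] = 0  # monomorphic reference
    g[:, 4] = 2  # monomorphic alternate
    g[:, 5] = [0, MISSING, 1, MISSING, 1, MISSING, MISSING, MISSING]  # 3 species, 3/8 called
    g[0, 1] = MISSING  # L1 has more missing than L0 -> L0 wins the tag
    species = ["sp1", "sp1", "sp2", "sp2", "sp3", "sp3", "sp4", "sp4"]
    tags = ["tagA", "tagA"] + [f"tag{j}" for j in range(2, n_loci)]
    return hs.GenotypeMatrix(
        g,
        [f"i{k}" for k in range(n_ind)],
        species,
        [f"L{j}" for j in range(n_loci)],
        tag_ids=tags,
    )


@pytest.fixture(scope="session")
def single_deme_schedule():
    """One constant-size deme; the textbook neutral coalescent."""
    return hs.EventSchedule(
        1, np.array([0.0, 1e30]), np.array([[1.0]]), np.zeros((1, 1, 1))
    )
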