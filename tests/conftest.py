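import numpy as np
import pytest

import poefam as pf

TRIO_FAM = "F1 dad 0 0 1\nF1 mom 0 0 2\nF1 kid dad mom 1\n"

# 4 samples x 2 variants; variant 1 alleles {A:6, G:2} -> minor G,
# variant 2 has one missing pair
PED_4x2 = (
    "F1 s1 0 0 1 0 A A C C\n"
    "F1 s2 0 0 2 0 A G C T\n"
    "F1 s3 0 0 1 0 A A 0 0\n"
    "F1 s4 0 0 2 0 A G T T\n"
)
MAP_2 = "16 rs1 0 53700100\n16 rs2 0 53700200\n"


@pytest.fixture
def small_matrix():
    g, ped = pf.read_genotypes(PED_4x2, MAP_2)
    return g, ped


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-sized three-generation cohort with a paternal effect."""
    cfg = pf.SimConfig(
        seed=20_260_920,
        n_families=120,
        family_shape="three_generation",
        n_snps=5,
        maf=0.3,
        beta_pat=0.05,
        beta_mat=0.0,
        sigma=0.15,
    )
    ped, g, truth = pf.simulate_pedigree_genotypes(cfg)
    pheno = pf.simulate_poe_phenotype(cfg, truth, ped)
    return cfg, ped, g, truth, pheno
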