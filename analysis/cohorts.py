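"""Shared study configurations for the numbered analysis scripts.

Two synthetic cohorts mirror the structure of the two study arms:

* a quantitative family cohort — 141 three-generation families (~1100
  individuals), 22 candidate SNPs at MAF 0.3, ln(BMI) with a pure paternal
  effect of 0.04 at one SNP, residual sd 0.15, age/sex/T2D covariates and a
  1.3% genotype missing rate;
* a case-parent trio cohort — 705 trios ascertained on an affected
  offspring, with a maternal relative risk of 1.6 per risk allele and no
  paternal risk, the asymmetry the PAT is designed to detect.
"""

import poefam as pf

SEED = 20_260_920

QUANT_CFG = pf.SimConfig(
    seed=SEED,
    n_families=141,
    family_shape="three_generation",
    n_children=2,
    n_snps=22,
    maf=0.3,
    causal_snp=0,
    beta_pat=0.04,
    beta_mat=0.0,
    sigma=0.15,
    genotype_missing_rate=0.013,
)

TRIO_CFG = pf.TrioSimConfig(
    seed=SEED + 1,
    n_trios=705,
    maf=0.3,
    rr_pat=1.0,
    rr_mat=1.6,
    baseline_risk=0.05,
    n_snps=3,
)


def quant_cohort():
    ped, g, truth = pf.simulate_pedigree_genotypes(QUANT_CFG)
    pheno = pf.simulate_poe_phenotype(QUANT_CFG, truth, ped)
    return ped, g, truth, pheno


def trio_cohort():
    return pf.simulate_ascertained_trios(TRIO_CFG)
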