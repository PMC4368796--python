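"""Published summary statistics bundled as package inputs.

Individual-level data from the two source cohorts — the Sorbs family cohort
(quantitative BMI analysis) and the 705 German childhood-obesity
case-parent trios (PAT analysis) — are not publicly deposited. What the
publications do print are summary quantities, and those are sufficient
inputs for two computations this package performs:

* exact PAT p-values recomputed from the printed per-SNP transmission
  counts of the major allele to heterozygous affected offspring;
* the paternal-vs-maternal effect-size comparison reconstructed from the
  printed per-allele regression estimates and 95% confidence intervals.

Values are transcribed as printed: betas keep their reported effect allele
(paternal and maternal rows of the same SNP may be oriented to different
alleles), and confidence-interval bounds keep their printed order; the
reconstruction helpers normalise bound order but take the printed
orientation at face value, which is how the published comparison was run.
"""

from __future__ import annotations

import pandas as pd

#: Reported transmissions of the major allele to heterozygous affected
#: offspring in 705 German childhood-obesity case-parent trios, for the ten
#: FTO SNPs carried forward from the family cohort.
FTO_TRIO_TRANSMISSIONS = pd.DataFrame(
    [
        # intron, snp_id, minor, major, n_paternal, n_maternal
        ("intron1", "rs1861869", "C", "G", 134, 119),
        ("intron1", "rs1861868", "T", "C", 129, 128),
        ("intron1", "rs1121980", "A", "G", 140, 123),
        ("intron1", "rs9939973", "A", "G", 139, 123),
        ("intron2", "rs10852522", "A", "T", 111, 152),
        ("intron3", "rs17818920", "C", "A", 85, 114),
        ("intron3", "rs17818902", "G", "T", 85, 114),
        ("intron3", "rs7203051", "C", "G", 122, 151),
        ("intron3", "rs8053740", "C", "G", 122, 151),
        ("intron3", "rs7205009", "T", "C", 122, 151),
    ],
    columns=["intron", "snp_id", "minor", "major", "n_paternal", "n_maternal"],
)

#: Reported parental-origin regression summaries for the same ten FTO SNPs
#: in the Sorbs family cohort: per-allele effect on ln(BMI), with the
#: reported effect allele and 95% CI for the paternal-allele and
#: maternal-allele tests (CIs as printed, bounds sometimes in reversed
#: order).
FTO_SORBS_POE_ESTIMATES = pd.DataFrame(
    [
        (
            "intron1", "rs1861869",
            0.003, "G", (-0.003, 0.010),
            0.010, "G", (0.003, 0.016),
        ),
        (
            "intron1", "rs1861868",
            0.003, "T", (-0.003, 0.010),
            -0.010, "C", (-0.003, -0.017),
        ),
        (
            "intron1", "rs1121980",
            -0.010, "G", (-0.003, -0.016),
            0.001, "G", (-0.006, 0.007),
        ),
        (
            "intron1", "rs9939973",
            -0.009, "G", (-0.002, -0.015),
            0.001, "G", (-0.006, 0.007),
        ),
        (
            "intron2", "rs10852522",
            0.003, "T", (-0.004, 0.010),
            0.011, "T", (0.004, 0.017),
        ),
        (
            "intron3", "rs17818920",
            0.009, "A", (0.0001, 0.017),
            0.013, "A", (0.005, 0.022),
        ),
        (
            "intron3", "rs17818902",
            0.009, "T", (0.0004, 0.017),
            0.014, "T", (0.005, 0.022),
        ),
        (
            "intron3", "rs7203051",
            0.005, "G", (-0.002, 0.012),
            0.011, "G", (0.004, 0.017),
        ),
        (
            "intron3", "rs8053740",
            0.005, "G", (-0.002, 0.012),
            0.011, "G", (0.004, 0.017),
        ),
        (
            "intron3", "rs7205009",
            0.005, "C", (-0.002, 0.011),
            0.010, "C", (0.004, 0.017),
        ),
    ],
    columns=[
        "intron", "snp_id",
        "beta_pat", "allele_pat", "ci_pat",
        "beta_mat", "allele_mat", "ci_mat",
    ],
)
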