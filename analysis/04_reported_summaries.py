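#!/usr/bin/env python
"""Recompute what the published summary statistics allow.

Individual-level data from the two source cohorts are not public, but two
published tables are themselves sufficient inputs: the per-SNP transmission
counts from the 705 childhood-obesity trios (exact PAT p-values follow
directly), and the per-allele regression estimates with 95% CIs from the
Sorbs family cohort (the paternal-vs-maternal comparison follows after
recovering SEs from the interval widths).
"""

from pathlib import Path

import pandas as pd

from poefam.assoc import compare_reported_estimates
from poefam.datasets import FTO_SORBS_POE_ESTIMATES, FTO_TRIO_TRANSMISSIONS
from poefam.pat import TransmissionCounts, pat_binomial

RESULTS = Path(__file__).resolve().parent.parent / "results" / "reported"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)

    pat_rows = []
    for r in FTO_TRIO_TRANSMISSIONS.itertuples(index=False):
        res = pat_binomial(
            TransmissionCounts(r.snp_id, r.major, r.n_paternal, r.n_maternal)
        )
        pat_rows.append(
            {
                "intron": r.intron,
                "snp_id": r.snp_id,
                "allele_counted": r.major,
                "n_paternal": r.n_paternal,
                "n_maternal": r.n_maternal,
                "p": res.p,
                "p_2dp": round(res.p, 2),
            }
        )
    pat_tab = pd.DataFrame(pat_rows)
    pat_tab.to_csv(RESULTS / "pat_from_reported_counts.tsv", sep="\t",
                   index=False, float_format="%.6g")
    print("PAT from the reported trio transmission counts:")
    print(pat_tab.to_string(index=False))

    cmp_rows = []
    for r in FTO_SORBS_POE_ESTIMATES.itertuples(index=False):
        c = compare_reported_estimates(
            r.snp_id, r.beta_pat, r.ci_pat, r.beta_mat, r.ci_mat
        )
        cmp_rows.append(
            {"intron": r.intron, "snp_id": r.snp_id, "delta": c.delta,
             "t": c.t, "p": c.p}
        )
    cmp_tab = pd.DataFrame(cmp_rows)
    cmp_tab.to_csv(RESULTS / "beta_compare_from_reported_cis.tsv", sep="\t",
                   index=False, float_format="%.6g")
    print("\npaternal-vs-maternal comparison reconstructed from the "
          "reported estimates and CIs (betas taken at their reported "
          "effect alleles, as published):")
    print(cmp_tab.to_string(index=False))
    print(f"\ntables written to {RESULTS}")


if __name__ == "__main__":
    main()
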