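#!/usr/bin/env python
"""Quantitative parent-of-origin analysis of the synthetic family cohort.

Runs QC -> Mendelian phasing -> unphased-rate filter -> the three allelic
regressions on ln(BMI) -> paternal-vs-maternal comparison, and reports how
the injected pure paternal effect (0.04 at snp0001) surfaces in each test.
"""

from pathlib import Path

import poefam as pf
from cohorts import QUANT_CFG, SEED, quant_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results" / "quant"


def main() -> None:
    ped, g, truth, pheno = quant_cohort()
    res = pf.run_quantitative_pipeline(ped, g, pheno, out_dir=RESULTS, seed=SEED)

    n_pass = int(res["qc_report"]["pass"].sum())
    print(f"QC: {n_pass}/{g.n_variants} SNPs passed "
          f"(missing<5%, HWE p>1e-4, MAF>1%)")
    print(f"phasing: mean per-SNP phasing rate "
          f"{res['mean_phasing_rate']:.2%} among non-founders; "
          f"{len(res['phasing_report'])} SNPs kept under the >=30% rule")

    assoc = res["assoc"]
    causal = "snp0001"
    rows = assoc[assoc["snp_id"] == causal].set_index("mode")
    print(f"\ncausal SNP {causal} (true paternal effect 0.04, maternal 0):")
    for mode in ("standard", "paternal", "maternal"):
        r = rows.loc[mode]
        print(f"  {mode:9s} beta={r['beta']:+.4f} "
              f"(95% CI {r['ci_low']:+.4f},{r['ci_high']:+.4f}) "
              f"p={r['p']:.2e} n={int(r['n'])}")
    cmp_row = res["beta_compare"].set_index("snp_id").loc[causal]
    print(f"  paternal-vs-maternal: delta={cmp_row['delta']:+.4f} "
          f"t={cmp_row['t']:.2f} p={cmp_row['p']:.3g}")
    print(f"\nBonferroni threshold 0.05/({len(res['beta_compare'])}*3) = "
          f"{res['threshold']:.3g}")
    n_sig = int(assoc["significant"].sum())
    print(f"{n_sig} association rows below the corrected threshold")
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
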