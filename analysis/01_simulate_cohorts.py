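#!/usr/bin/env python
"""Generate the two synthetic study cohorts and write them to disk.

The bulky PLINK-dialect files go under scratch/ (inputs for external tools
or re-runs); small summaries of what was generated go to results/.
"""

from pathlib import Path

import numpy as np

import poefam as pf
from cohorts import QUANT_CFG, TRIO_CFG, quant_cohort, trio_cohort

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    ped, g, truth, pheno = quant_cohort()
    ped_text, map_text = pf.write_genotypes(g, ped)
    (SCRATCH / "cohort.ped").write_text(ped_text)
    (SCRATCH / "cohort.map").write_text(map_text)
    (SCRATCH / "cohort.fam").write_text(pf.write_pedigree(ped))
    (SCRATCH / "pheno.tsv").write_text(pf.write_phenotypes(pheno))
    (SCRATCH / "truth.tsv").write_text(truth.to_tsv())

    tped, tg, ttruth = trio_cohort()
    tped_text, tmap_text = pf.write_genotypes(tg, tped)
    (SCRATCH / "trios.ped").write_text(tped_text)
    (SCRATCH / "trios.map").write_text(tmap_text)
    (SCRATCH / "trios.fam").write_text(pf.write_pedigree(tped))

    lines = [
        "cohort\tn_individuals\tn_families\tn_snps\tmean_maf\tmissing_rate",
        "\t".join(
            [
                "quantitative",
                str(g.n_samples),
                str(QUANT_CFG.n_families),
                str(g.n_variants),
                f"{np.mean([pf.maf(g, j) for j in range(g.n_variants)]):.3f}",
                f"{np.isnan(g.dosage).mean():.4f}",
            ]
        ),
        "\t".join(
            [
                "trios",
                str(tg.n_samples),
                str(TRIO_CFG.n_trios),
                str(tg.n_variants),
                f"{np.mean([pf.maf(tg, j) for j in range(tg.n_variants)]):.3f}",
                f"{np.isnan(tg.dosage).mean():.4f}",
            ]
        ),
    ]
    (RESULTS / "cohort_summary.tsv").write_text("\n".join(lines) + "\n")
    print(f"quantitative cohort: {g.n_samples} individuals, "
          f"{g.n_variants} SNPs -> {SCRATCH}")
    print(f"trio cohort: {TRIO_CFG.n_trios} affected-offspring trios -> {SCRATCH}")
    print(f"summary written to {RESULTS / 'cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
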