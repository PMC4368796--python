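"""Per-SNP quality control: missing rate, MAF and exact Hardy-Weinberg test.

The filter thresholds use strict inequalities: a variant passes when its
missing rate is < ``max_missing``, its Hardy-Weinberg exact p-value is
> ``min_hwe_p`` and its minor allele frequency is > ``min_maf``. Defaults
are the conventional GWAS candidate-region settings (5% missingness,
HWE p 1e-4, MAF 1%).

The Hardy-Weinberg test is the conditional exact test: holding the allele
counts fixed, the p-value sums the probabilities of every heterozygote count
whose conditional probability under random mating does not exceed that of
the observed count (a two-sided minimum-likelihood rule). It is computed by
direct enumeration in log space, which is exact and cheap at candidate-SNP
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GenotypeMatrix, Pedigree


@dataclass(frozen=True)
class QCThresholds:
    max_missing: float = 0.05
    min_hwe_p: float = 0.0001
    min_maf: float = 0.01

    def __post_init__(self):
        for name in ("max_missing", "min_hwe_p", "min_maf"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class QCReport:
    """Per-variant QC metrics and pass/fail decisions."""

    table: pd.DataFrame  # snp_id, missing_rate, maf, hwe_p, pass, fail_reasons

    def to_tsv(self) -> str:
        df = self.table.copy()
        df["fail_reasons"] = df["fail_reasons"].apply(
            lambda rs: ";".join(rs) if rs else "."
        )
        return df.to_csv(sep="\t", index=False, float_format="%.6g")


def snp_missing_rate(g: GenotypeMatrix, v: int) -> float:
    """Fraction of samples with missing dosage at variant index ``v``."""
    if g.n_samples == 0:
        raise ValueError("missing rate undefined on an empty sample set")
    return float(np.isnan(g.dosage[:, v]).mean())


def maf(g: GenotypeMatrix, v: int) -> float:
    """Minor allele frequency at variant ``v`` among non-missing chromosomes."""
    d = g.dosage[:, v]
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError(f"variant index {v}: all genotypes missing")
    p = d.sum() / (2 * d.size)
    return float(min(p, 1 - p))


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Conditional exact Hardy-Weinberg test p-value.

    Parameters are the genotype counts (homozygote, heterozygote, other
    homozygote). Symmetric under swapping the two homozygote classes.
    """
    for c in (n_hom1, n_het, n_hom2):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_hom1 + n_het  # allele-1 count
    if n_a == 0 or n_a == 2 * n:
        return 1.0  # monomorphic: a single configuration exists

    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    # P(het = h | allele counts) ∝ n! 2^h / ((nA-h)/2)! h! ((2n-nA-h)/2)!
    logw = (
        hets * np.log(2)
        - gammaln((n_a - hets) // 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (n_a + hets) // 2 + 1)
    )
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_het} incompatible with allele count {n_a}"
        )
    # 1+1e-12 guards against float round-off excluding ties
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def genotype_counts(g: GenotypeMatrix, v: int) -> tuple[int, int, int]:
    """(hom-minor, het, hom-major) counts at variant ``v``."""
    d = g.dosage[:, v]
    d = d[~np.isnan(d)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def apply_qc(
    g: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    pedigree: Pedigree | None = None,
    hwe_founders_only: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants failing any QC rule; return the filtered matrix + report.

    By default the HWE test uses all genotyped individuals, relatives
    included; ``hwe_founders_only=True`` restricts it to pedigree founders
    (requires ``pedigree``), which removes the dependence among related
    genotypes at the cost of sample size.
    """
    if hwe_founders_only and pedigree is None:
        raise ValueError("hwe_founders_only requires a pedigree")

    g_hwe = g
    if hwe_founders_only:
        founder_ids = {r.individual_id for r in pedigree.founders()}
        keep = [i for i, s in enumerate(g.sample_ids) if s in founder_ids]
        g_hwe = GenotypeMatrix(
            sample_ids=[g.sample_ids[i] for i in keep],
            variants=g.variants,
            dosage=g.dosage[keep, :],
            sample_families=[g.sample_families[i] for i in keep],
        )

    rows = []
    keep_idx = []
    for j, var in enumerate(g.variants):
        miss = snp_missing_rate(g, j)
        reasons = []
        if not miss < thresholds.max_missing:
            reasons.append(f"missing_rate {miss:.4g} >= {thresholds.max_missing}")
        all_missing = np.isnan(g.dosage[:, j]).all()
        if all_missing:
            freq, hp = np.nan, np.nan
            reasons.append("all genotypes missing")
        else:
            freq = maf(g, j)
            if not freq > thresholds.min_maf:
                reasons.append(f"maf {freq:.4g} <= {thresholds.min_maf}")
            hp = hwe_exact_p(*genotype_counts(g_hwe, j))
            if not hp > thresholds.min_hwe_p:
                reasons.append(f"hwe_p {hp:.4g} <= {thresholds.min_hwe_p}")
        ok = not reasons
        rows.append(
            {
                "snp_id": var.snp_id,
                "missing_rate": miss,
                "maf": freq,
                "hwe_p": hp,
                "pass": ok,
                "fail_reasons": reasons,
            }
        )
        if ok:
            keep_idx.append(j)

    report = QCReport(table=pd.DataFrame(rows))
    return g.subset_variants(keep_idx), report
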