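"""Pairwise linkage disequilibrium (r^2) from phased haplotypes.

Because phase is known (from the pedigree phaser or a pre-phased VCF), r^2
is computed by direct haplotype counting — no EM over ambiguous double
heterozygotes is needed. For a variant pair, every haplotype (one paternal
and one maternal per individual) with both sites resolved contributes one
observation; r^2 = D^2 / (pA pa pB pb) with D = pAB - pA pB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phasing import PhasedGenotypes


class MonomorphicVariantError(ValueError):
    """r^2 is undefined when a variant is monomorphic among shared haplotypes."""


@dataclass
class LDMatrix:
    variant_ids: list[str]
    r2: np.ndarray  # symmetric, unit diagonal; NaN where undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids)
        return df.to_csv(sep="\t", na_rep="NA", float_format="%.6g")

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variant_ids):
            for j in range(i + 1, len(self.variant_ids)):
                rows.append(
                    {"id1": a, "id2": self.variant_ids[j], "r2": self.r2[i, j]}
                )
        return pd.DataFrame(rows, columns=["id1", "id2", "r2"])


def _haplotypes(ph: PhasedGenotypes, v1: int, v2: int) -> np.ndarray:
    """(n_hap, 2) array of allele pairs with both sites resolved."""
    cols = []
    for mat in (ph.paternal, ph.maternal):
        pair = np.column_stack([mat[:, v1], mat[:, v2]])
        cols.append(pair[~np.isnan(pair).any(axis=1)])
    return np.vstack(cols)


def haplotype_r2(ph: PhasedGenotypes, v1: int, v2: int) -> float:
    """Squared allelic correlation between variants ``v1`` and ``v2``.

    Computed over haplotypes with both sites resolved; invariant under
    allele relabelling at either site. Raises
    :class:`MonomorphicVariantError` when either site is monomorphic among
    the shared haplotypes (undefined, deliberately not 0).
    """
    hap = _haplotypes(ph, v1, v2)
    if hap.shape[0] == 0:
        raise MonomorphicVariantError("no jointly resolved haplotypes")
    pA = hap[:, 0].mean()
    pB = hap[:, 1].mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicVariantError(
            "variant monomorphic among jointly resolved haplotypes"
        )
    pAB = (hap[:, 0] * hap[:, 1]).mean()
    d = pAB - pA * pB
    return float(d * d / (pA * (1 - pA) * pB * (1 - pB)))


def ld_matrix(ph: PhasedGenotypes) -> LDMatrix:
    """All-pairs r^2; undefined pairs are NaN and listed, not zeroed."""
    ids = [v.snp_id for v in ph.variants]
    m = len(ids)
    r2 = np.full((m, m), np.nan)
    undefined = []
    for i in range(m):
        try:
            haplotype_r2(ph, i, i)
            r2[i, i] = 1.0
        except MonomorphicVariantError:
            undefined.append((ids[i], ids[i]))
        for j in range(i + 1, m):
            try:
                r2[i, j] = r2[j, i] = haplotype_r2(ph, i, j)
            except MonomorphicVariantError:
                undefined.append((ids[i], ids[j]))
    return LDMatrix(variant_ids=ids, r2=r2, undefined_pairs=undefined)
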