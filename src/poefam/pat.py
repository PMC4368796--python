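"""Parental asymmetry test (PAT) for case-parent trios.

For each SNP, trios with a heterozygous affected offspring are classified by
which parent transmitted a designated allele (by default the major allele).
A trio is informative only when the transmitting parent is unambiguous:
when both parents are heterozygous either parent could have transmitted
either allele, so such trios are excluded. Under the null of no
parent-of-origin asymmetry the paternal count is Binomial(n, 1/2) given the
informative total n; the reported p-value is the exact two-sided binomial
probability, computed by doubling the smaller tail and capping at 1.

The test is robust to population stratification because it conditions on
parental genotypes, and the p-value is invariant to which of the two
alleles is designated (the counts swap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass
class TransmissionCounts:
    snp_id: str
    allele_counted: str
    n_paternal: int
    n_maternal: int
    n_ambiguous: int = 0
    n_mendel_errors: int = 0

    def __post_init__(self):
        if self.n_paternal < 0 or self.n_maternal < 0:
            raise ValueError("transmission counts must be non-negative")

    @property
    def n_informative(self) -> int:
        return self.n_paternal + self.n_maternal


@dataclass
class PATResult:
    snp_id: str
    n_informative: int
    p: float


def count_transmissions(
    trio_dosages: Iterable[Sequence[float | None]],
    snp_id: str = "",
    allele: str = "",
) -> TransmissionCounts:
    """Tally parental transmissions of the designated allele.

    ``trio_dosages`` yields (father, mother, child) genotypes for affected
    offspring, each expressed as the dosage (0/1/2) of the designated
    allele, with ``None``/NaN for missing; any trio with a missing genotype
    is skipped. Only heterozygous children are considered; both-parents-
    heterozygous trios are ambiguous and excluded; Mendelian-impossible
    parent combinations are excluded and counted.
    """
    n_pat = n_mat = n_amb = n_err = 0
    for row in trio_dosages:
        df, dm, dc = row
        if any(x is None or (isinstance(x, float) and np.isnan(x)) for x in row):
            continue
        df, dm, dc = int(df), int(dm), int(dc)
        for name, d in (("father", df), ("mother", dm), ("child", dc)):
            if d not in (0, 1, 2):
                raise ValueError(f"{snp_id}: {name} dosage {d} not in 0/1/2")
        if dc != 1:
            continue  # only heterozygous offspring are informative
        father_can_give = df >= 1  # father carries the designated allele
        father_can_other = df <= 1
        mother_can_give = dm >= 1
        mother_can_other = dm <= 1
        paternal_ok = father_can_give and mother_can_other
        maternal_ok = mother_can_give and father_can_other
        if paternal_ok and maternal_ok:
            n_amb += 1  # both parents heterozygous: origin undefined
        elif paternal_ok:
            n_pat += 1
        elif maternal_ok:
            n_mat += 1
        else:
            n_err += 1  # e.g. both parents homozygous for the same allele
    if n_err:
        logger.warning(
            "%s: %d trio(s) with Mendelian-impossible genotypes excluded",
            snp_id or "<snp>",
            n_err,
        )
    return TransmissionCounts(
        snp_id=snp_id,
        allele_counted=allele,
        n_paternal=n_pat,
        n_maternal=n_mat,
        n_ambiguous=n_amb,
        n_mendel_errors=n_err,
    )


def count_transmissions_from_pedigree(
    ped: Pedigree,
    g: GenotypeMatrix,
    v: int,
    count_minor: bool = False,
    affected: dict[str, int] | None = None,
) -> TransmissionCounts:
    """Extract trio genotypes from a pedigree and tally transmissions.

    Families are used when they contain a child with both parents recorded
    and genotyped (a case-parent trio). All offspring are assumed affected
    unless ``affected`` marks them otherwise, matching an
    affected-ascertained trio design. By default the major allele is
    counted; ``count_minor=True`` counts the minor allele instead (the
    p-value is invariant, the counts swap).
    """
    var = g.variants[v]
    allele = (var.minor_allele if count_minor else var.major_allele) or "?"
    pos = {s: i for i, s in enumerate(g.sample_ids)}
    rows = []
    for rec in ped:
        if rec.father_id is None or rec.mother_id is None:
            continue
        if affected is not None and affected.get(rec.individual_id, 1) != 1:
            continue
        ids = (rec.father_id, rec.mother_id, rec.individual_id)
        if any(i not in pos for i in ids):
            continue
        d = [g.dosage[pos[i], v] for i in ids]
        if not count_minor:
            d = [np.nan if np.isnan(x) else 2 - x for x in d]
        rows.append(tuple(d))
    return count_transmissions(rows, snp_id=var.snp_id, allele=allele)


def pat_binomial(tc: TransmissionCounts) -> PATResult:
    """Exact two-sided binomial PAT p-value at null probability 1/2.

    Doubles the smaller tail of Binomial(n_informative, 0.5) at the observed
    paternal count, capped at 1.
    """
    n = tc.n_informative
    if n < 1:
        raise ValueError(f"{tc.snp_id}: no informative trios")
    k = min(tc.n_paternal, tc.n_maternal)
    p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
    return PATResult(snp_id=tc.snp_id, n_informative=n, p=p)
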