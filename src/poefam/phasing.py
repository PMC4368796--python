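"""Parental-origin phasing by Mendelian constraint propagation.

Each individual's genotype at a SNP is split into a paternal and a maternal
allele. The phaser is a deterministic single-marker constraint solver: for
every family and variant it maintains, per individual, the set of ordered
(paternal, maternal) allele pairs compatible with that individual's genotype,
and repeatedly prunes these sets with the transmission constraint — a
child's paternal allele must be one of the father's two alleles, and
symmetrically for the mother — until a fixpoint. Deductions therefore
include the classic trio rules (homozygous child; homozygous parent forces
the transmitted allele; a heterozygous child with one side resolved forces
the other) as well as multi-generation chains in which grandparental or
offspring genotypes resolve an individual's own phase.

The solver is sound but deliberately incomplete: it never guesses. A site it
cannot force (canonically a fully heterozygous parent-offspring trio with no
outside information) is marked unresolved and stays missing downstream,
which is exactly how failed phasing is treated in the association stage.
This is a stand-in for haplotype-library long-range phasing: it produces the
same kind of output (origin-labelled alleles with missingness) and is exact
wherever it resolves, but it resolves fewer sites than a population-scale
phaser would, because it uses no linkage information across markers.

Mendelian-inconsistent sites abstain rather than abort: the whole family is
set unresolved at that variant and the event is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, Pedigree, Variant

logger = logging.getLogger(__name__)

SOURCE_UNRESOLVED = 0
SOURCE_HOMOZYGOTE = 1
SOURCE_TRIO_FORCED = 2
SOURCE_PROPAGATED = 3
SOURCE_PREPHASED = 4

SOURCE_LABELS = {
    SOURCE_UNRESOLVED: "unresolved",
    SOURCE_HOMOZYGOTE: "homozygote",
    SOURCE_TRIO_FORCED: "trio-forced",
    SOURCE_PROPAGATED: "propagated",
    SOURCE_PREPHASED: "pre-phased",
}

_ALL_PAIRS = frozenset({(0, 0), (0, 1), (1, 0), (1, 1)})
_MAX_SWEEPS = 64


class MendelianInconsistency(Exception):
    """Internal signal: a family/variant admits no consistent assignment."""


@dataclass
class PhasedGenotypes:
    """Origin-labelled allele matrices.

    ``paternal[i, j]`` / ``maternal[i, j]`` hold the allele (0/1 copies of
    the variant's minor allele) individual ``i`` inherited from each parent,
    NaN where unresolved. Wherever both are present their sum equals the
    genotype dosage. Founders (``founder_mask``) receive origin labels only
    at homozygous sites, where the labelling is vacuous.
    """

    sample_ids: list[str]
    variants: list[Variant]
    paternal: np.ndarray
    maternal: np.ndarray
    phase_source: np.ndarray  # int8 codes, see SOURCE_LABELS
    founder_mask: np.ndarray
    mendelian_errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def resolved(self) -> np.ndarray:
        """Boolean mask of cells with both alleles assigned."""
        return ~(np.isnan(self.paternal) | np.isnan(self.maternal))

    def variant_index(self, snp_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.snp_id == snp_id:
                return j
        raise KeyError(snp_id)

    def subset_variants(self, keep: list[int]) -> "PhasedGenotypes":
        kept_ids = {self.variants[j].snp_id for j in keep}
        return PhasedGenotypes(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[j] for j in keep],
            paternal=self.paternal[:, keep].copy(),
            maternal=self.maternal[:, keep].copy(),
            phase_source=self.phase_source[:, keep].copy(),
            founder_mask=self.founder_mask.copy(),
            mendelian_errors=[e for e in self.mendelian_errors if e[1] in kept_ids],
        )

    def validate_against(self, g: GenotypeMatrix) -> None:
        """Assert paternal + maternal == dosage at every doubly-resolved,
        genotyped cell. Raises AssertionError on violation."""
        both = self.resolved() & ~np.isnan(g.dosage)
        if not np.allclose(
            (self.paternal + self.maternal)[both], g.dosage[both]
        ):
            raise AssertionError("phased alleles inconsistent with dosages")


@dataclass
class PhasingReport:
    """Per-variant unphased rates and exclusion decisions."""

    table: pd.DataFrame  # snp_id, unphased_rate, excluded
    mean_phasing_rate: float

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.6g")


def _init_domain(dosage: float) -> frozenset:
    if np.isnan(dosage):
        return _ALL_PAIRS
    d = int(dosage)
    if d == 0:
        return frozenset({(0, 0)})
    if d == 2:
        return frozenset({(1, 1)})
    return frozenset({(0, 1), (1, 0)})


def _solve_family_variant(
    members: list[str],
    parents: dict[str, tuple[str | None, str | None]],
    dosages: dict[str, float],
) -> tuple[dict[str, frozenset], dict[str, int]]:
    """Constraint propagation to fixpoint for one family at one variant.

    Returns the final domains and, per individual, the sweep number at which
    its domain became fully resolved (0 = from own genotype).
    """
    doms = {iid: _init_domain(dosages.get(iid, np.nan)) for iid in members}
    resolved_sweep: dict[str, int] = {}

    def fully_resolved(dom: frozenset) -> bool:
        return len({p[0] for p in dom}) == 1 and len({p[1] for p in dom}) == 1

    for iid in members:
        if fully_resolved(doms[iid]):
            resolved_sweep[iid] = 0

    edges = []  # (parent, child, component): 0 = paternal, 1 = maternal
    for iid in members:
        fa, mo = parents[iid]
        if fa is not None:
            edges.append((fa, iid, 0))
        if mo is not None:
            edges.append((mo, iid, 1))
    edges.sort()

    for sweep in range(1, _MAX_SWEEPS + 1):
        snapshot = dict(doms)
        new = {iid: set(doms[iid]) for iid in members}
        for parent, child, comp in edges:
            transmissible = set()
            for x, y in snapshot[parent]:
                transmissible.add(x)
                transmissible.add(y)
            new[child] = {p for p in new[child] if p[comp] in transmissible}
            child_comp = {p[comp] for p in snapshot[child]}
            new[parent] = {
                p for p in new[parent] if p[0] in child_comp or p[1] in child_comp
            }
        changed = False
        for iid in members:
            nd = frozenset(new[iid])
            if not nd:
                raise MendelianInconsistency(iid)
            if nd != doms[iid]:
                doms[iid] = nd
                changed = True
                if iid not in resolved_sweep and fully_resolved(nd):
                    resolved_sweep[iid] = sweep
        if not changed:
            break

    return doms, resolved_sweep


def phase_pedigree(ped: Pedigree, g: GenotypeMatrix) -> PhasedGenotypes:
    """Assign parental origin to every allele the pedigree can force.

    Every genotyped sample must appear in the pedigree; pedigree members
    without genotypes still participate in propagation (their genotypes are
    treated as missing, and constraints can flow through them).
    """
    ped_ids = {r.individual_id for r in ped}
    for s in g.sample_ids:
        if s not in ped_ids:
            raise ValueError(f"genotyped individual {s!r} absent from pedigree")

    n, m = g.n_samples, g.n_variants
    paternal = np.full((n, m), np.nan)
    maternal = np.full((n, m), np.nan)
    source = np.zeros((n, m), dtype=np.int8)

    sample_pos = {s: i for i, s in enumerate(g.sample_ids)}
    rec_by_id = {r.individual_id: r for r in ped}
    founder_mask = np.array(
        [rec_by_id[s].is_founder for s in g.sample_ids], dtype=bool
    )
    mendelian_errors: list[tuple[str, str]] = []

    for fam_id, members_recs in sorted(ped.families().items()):
        members = sorted(r.individual_id for r in members_recs)
        parents = {
            r.individual_id: (r.father_id, r.mother_id) for r in members_recs
        }
        for j in range(m):
            dosages = {
                iid: g.dosage[sample_pos[iid], j]
                for iid in members
                if iid in sample_pos
            }
            try:
                doms, resolved_sweep = _solve_family_variant(
                    members, parents, dosages
                )
            except MendelianInconsistency:
                mendelian_errors.append((fam_id, g.variants[j].snp_id))
                logger.warning(
                    "Mendelian inconsistency in family %s at %s; "
                    "site left unresolved",
                    fam_id,
                    g.variants[j].snp_id,
                )
                continue
            for iid in members:
                i = sample_pos.get(iid)
                if i is None:
                    continue
                dom = doms[iid]
                pats = {p[0] for p in dom}
                mats = {p[1] for p in dom}
                if len(pats) == 1 and len(mats) == 1:
                    paternal[i, j] = next(iter(pats))
                    maternal[i, j] = next(iter(mats))
                    sweep = resolved_sweep.get(iid, 0)
                    if sweep == 0:
                        source[i, j] = SOURCE_HOMOZYGOTE
                    elif sweep == 1:
                        source[i, j] = SOURCE_TRIO_FORCED
                    else:
                        source[i, j] = SOURCE_PROPAGATED

    if mendelian_errors:
        logger.info(
            "%d family-variant sites abstained due to Mendelian inconsistency",
            len(mendelian_errors),
        )

    return PhasedGenotypes(
        sample_ids=list(g.sample_ids),
        variants=[v for v in g.variants],
        paternal=paternal,
        maternal=maternal,
        phase_source=source,
        founder_mask=founder_mask,
        mendelian_errors=mendelian_errors,
    )


def phasing_missing_rate(ph: PhasedGenotypes, v: int) -> float:
    """Fraction of phase-eligible (non-founder) samples unresolved at ``v``.

    Founders are excluded: they have no recorded parents, so parental-origin
    labels are undefined for them and they contribute transmissions only.
    """
    eligible = ~ph.founder_mask
    if eligible.sum() == 0:
        raise ValueError("no phase-eligible (non-founder) samples")
    unres = np.isnan(ph.paternal[eligible, v]) | np.isnan(ph.maternal[eligible, v])
    return float(unres.mean())


def filter_unphased(
    ph: PhasedGenotypes, threshold: float = 0.30
) -> tuple[PhasedGenotypes, PhasingReport]:
    """Drop variants whose unphased rate is >= ``threshold`` (note: >=)."""
    rows = []
    keep = []
    for j, var in enumerate(ph.variants):
        rate = phasing_missing_rate(ph, j)
        excluded = rate >= threshold
        rows.append(
            {"snp_id": var.snp_id, "unphased_rate": rate, "excluded": excluded}
        )
        if not excluded:
            keep.append(j)
    table = pd.DataFrame(rows)
    mean_rate = float(1.0 - table["unphased_rate"].mean()) if len(table) else float("nan")
    return ph.subset_variants(keep), PhasingReport(
        table=table, mean_phasing_rate=mean_rate
    )


def write_allele_matrices(ph: PhasedGenotypes) -> tuple[str, str]:
    """Serialize paternal and maternal allele matrices as TSV text."""
    ids = [v.snp_id for v in ph.variants]

    def fmt(mat):
        df = pd.DataFrame(mat, index=ph.sample_ids, columns=ids)
        return df.to_csv(sep="\t", na_rep="NA", float_format="%g")

    return fmt(ph.paternal), fmt(ph.maternal)
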