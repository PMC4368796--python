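"""Synthetic pedigrees, gene-dropped genotypes and parent-of-origin traits.

This module generates the statistical structure the rest of the package is
tested against, with the generating truth stored alongside:

* extended pedigrees (trio / nuclear / three-generation) whose founders are
  drawn at Hardy-Weinberg proportions at a configurable MAF and whose
  descendants receive one uniformly random allele from each parent (gene
  dropping), with the true transmitted alleles recorded before missingness
  is applied;
* a quantitative trait generated on the log scale,
  ``ln(BMI) = mu + b_pat X_pat + b_mat X_mat + b_age age + b_sex sex
  + b_t2d t2d + N(0, sigma)``, so paternal and maternal per-allele effects
  are separately controllable;
* case-parent trios ascertained on an affected offspring, where affection
  probability is multiplicative in the paternally and maternally inherited
  risk-allele counts (``baseline * rr_pat^X_pat * rr_mat^X_mat``, capped at
  1) — the origin-specific risk that the parental asymmetry test detects.

Determinism: every entry point takes its seed from the config; independent
sub-streams are derived from the one integer seed via ``SeedSequence`` spawn
keys, so the same seed always reproduces the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, Individual, Pedigree, PhenotypeTable, Variant
from .phasing import PhasedGenotypes, SOURCE_PREPHASED

import pandas as pd

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass
class SimConfig:
    """Generating parameters for the quantitative family cohort.

    Defaults emulate an adult family cohort: 141 extended families, 22
    candidate SNPs at MAF 0.3, ln-scale trait with residual sd 0.15 around
    an intercept of 3.25 (BMI ~ 26 kg/m^2), small age/sex/diabetes covariate
    effects, and a 1.3% genotype missing rate (98.7% call rate).
    """

    seed: int
    n_families: int = 141
    family_shape: str = "three_generation"  # trio | nuclear | three_generation
    n_children: int = 2
    n_snps: int = 22
    maf: float | list[float] = 0.3
    causal_snp: int = 0
    beta_pat: float = 0.0
    beta_mat: float = 0.0
    mu: float = 3.25
    beta_age: float = 0.003
    beta_sex: float = -0.02
    beta_t2d: float = 0.06
    sigma: float = 0.15
    t2d_prevalence: float = 0.12
    genotype_missing_rate: float = 0.013

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.family_shape not in ("trio", "nuclear", "three_generation"):
            raise ValueError(f"unknown family_shape {self.family_shape!r}")
        for r in np.atleast_1d(self.maf):
            if not (0 <= r <= 0.5):
                raise ValueError(f"maf {r} outside [0, 0.5]")
        if not (0 <= self.genotype_missing_rate <= 1):
            raise ValueError("genotype_missing_rate outside [0, 1]")

    def maf_vector(self) -> np.ndarray:
        m = np.atleast_1d(np.asarray(self.maf, dtype=float))
        if m.size == 1:
            m = np.repeat(m, self.n_snps)
        if m.size != self.n_snps:
            raise ValueError("maf list length must match n_snps")
        return m


@dataclass
class TrioSimConfig:
    """Generating parameters for affected-offspring-ascertained trios."""

    seed: int
    n_trios: int = 705
    maf: float = 0.3
    rr_pat: float = 1.0
    rr_mat: float = 1.0
    baseline_risk: float = 0.05
    n_snps: int = 1
    genotype_missing_rate: float = 0.0
    max_candidates: int = 5_000_000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.rr_pat <= 0 or self.rr_mat <= 0:
            raise ValueError("relative risks must be > 0")
        if not (0 < self.baseline_risk <= 1):
            raise ValueError("baseline_risk must lie in (0, 1]")
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")


@dataclass
class SimTruth:
    """True transmitted alleles per individual and SNP, pre-missingness.

    ``paternal``/``maternal`` are aligned with ``sample_ids`` x SNPs; for
    founders the two drawn alleles are labelled arbitrarily (they are
    exchangeable). ``paternal + maternal`` always equals the pre-missingness
    dosage.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    paternal: np.ndarray
    maternal: np.ndarray
    params: dict = field(default_factory=dict)

    def dosage(self) -> np.ndarray:
        return self.paternal + self.maternal

    def to_tsv(self) -> str:
        cols = {}
        for j, sid in enumerate(self.snp_ids):
            cols[f"{sid}_pat"] = self.paternal[:, j]
            cols[f"{sid}_mat"] = self.maternal[:, j]
        df = pd.DataFrame(cols, index=self.sample_ids)
        df.index.name = "iid"
        return df.to_csv(sep="\t", float_format="%g")


def _make_variants(n_snps: int, mafs: np.ndarray) -> list[Variant]:
    variants = []
    for j in range(n_snps):
        minor, major = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            Variant(
                snp_id=f"snp{j + 1:04d}",
                chrom="16",
                pos=53_700_000 + 1000 * j,
                allele1=minor,
                allele2=major,
                minor_allele=minor,
                notes=f"simulated maf={mafs[j]:g}",
            )
        )
    return variants


def _family_members(shape: str, n_children: int, fam: str):
    """(records, parent_links) for one family; ids are family-scoped."""
    recs: list[Individual] = []

    def add(iid, father, mother, sex):
        recs.append(
            Individual(
                family_id=fam,
                individual_id=f"{fam}_{iid}",
                father_id=f"{fam}_{father}" if father else None,
                mother_id=f"{fam}_{mother}" if mother else None,
                sex=sex,
            )
        )

    if shape == "three_generation":
        add("gf1", None, None, "male")
        add("gm1", None, None, "female")
        add("gf2", None, None, "male")
        add("gm2", None, None, "female")
        add("fa", "gf1", "gm1", "male")
        add("mo", "gf2", "gm2", "female")
        for k in range(n_children):
            add(f"c{k + 1}", "fa", "mo", "male" if k % 2 == 0 else "female")
    else:
        add("fa", None, None, "male")
        add("mo", None, None, "female")
        kids = 1 if shape == "trio" else n_children
        for k in range(kids):
            add(f"c{k + 1}", "fa", "mo", "male" if k % 2 == 0 else "female")
    return recs


def simulate_pedigree_genotypes(
    cfg: SimConfig,
) -> tuple[Pedigree, GenotypeMatrix, SimTruth]:
    """Gene-drop genotypes through simulated pedigrees.

    Founder allele pairs are iid Bernoulli(maf) (Hardy-Weinberg), each
    descendant inherits one uniformly chosen allele from each parent, truth
    is stored, then genotype missingness is applied to the emitted dosages.
    """
    rng = _rng(cfg.seed, 0)
    mafs = cfg.maf_vector()
    variants = _make_variants(cfg.n_snps, mafs)

    records: list[Individual] = []
    for f in range(cfg.n_families):
        records.extend(
            _family_members(cfg.family_shape, cfg.n_children, f"F{f + 1:04d}")
        )
    ped = Pedigree(records)

    n = len(records)
    pat = np.zeros((n, cfg.n_snps))
    mat = np.zeros((n, cfg.n_snps))
    pos = {r.individual_id: i for i, r in enumerate(records)}
    # records are emitted parents-before-children within each family
    for rec in records:
        i = pos[rec.individual_id]
        if rec.father_id is None:
            pat[i] = rng.random(cfg.n_snps) < mafs
            mat[i] = rng.random(cfg.n_snps) < mafs
        else:
            fi, mi = pos[rec.father_id], pos[rec.mother_id]
            from_f = rng.integers(0, 2, cfg.n_snps)
            from_m = rng.integers(0, 2, cfg.n_snps)
            pat[i] = np.where(from_f == 0, pat[fi], mat[fi])
            mat[i] = np.where(from_m == 0, pat[mi], mat[mi])

    truth = SimTruth(
        sample_ids=[r.individual_id for r in records],
        snp_ids=[v.snp_id for v in variants],
        paternal=pat,
        maternal=mat,
        params={
            "seed": cfg.seed,
            "n_families": cfg.n_families,
            "family_shape": cfg.family_shape,
            "beta_pat": cfg.beta_pat,
            "beta_mat": cfg.beta_mat,
            "sigma": cfg.sigma,
        },
    )

    dosage = pat + mat
    if cfg.genotype_missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.genotype_missing_rate
        dosage = np.where(mask, np.nan, dosage)

    g = GenotypeMatrix(
        sample_ids=[r.individual_id for r in records],
        variants=variants,
        dosage=dosage,
        sample_families=[r.family_id for r in records],
    )
    return ped, g, truth


_GENERATION_AGES = {  # mean, sd, lower bound by pedigree depth
    0: (68.0, 7.0, 40.0),
    1: (47.0, 7.0, 25.0),
    2: (22.0, 4.0, 18.0),
}


def _generation_depth(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def walk(rec) -> int:
        iid = rec.individual_id
        if iid in depth:
            return depth[iid]
        if rec.father_id is None and rec.mother_id is None:
            depth[iid] = 0
        else:
            par = [
                walk(ped.get(rec.family_id, p))
                for p in (rec.father_id, rec.mother_id)
                if p is not None
            ]
            depth[iid] = max(par) + 1
        return depth[iid]

    for rec in ped:
        walk(rec)
    return depth


def simulate_poe_phenotype(
    cfg: SimConfig, truth: SimTruth, ped: Pedigree
) -> PhenotypeTable:
    """Generate BMI/age/sex/T2D with origin-specific allelic effects.

    ln(BMI) follows the additive model in the module docstring with the
    paternal and maternal allele counts taken from the stored truth at
    ``cfg.causal_snp``; BMI is emitted on the natural scale as exp(ln BMI).
    Ages are drawn per pedigree generation (grandparents, parents,
    offspring) so covariate structure resembles an adult family cohort.
    """
    rng = _rng(cfg.seed, 1)
    ids = truth.sample_ids
    idx = {iid: i for i, iid in enumerate(ids)}
    depth = _generation_depth(ped)
    recs = {r.individual_id: r for r in ped}

    n = len(ids)
    age = np.empty(n)
    sex = np.empty(n)
    for iid in ids:
        i = idx[iid]
        mean, sd, lo = _GENERATION_AGES.get(min(depth[iid], 2), (47.0, 7.0, 25.0))
        age[i] = max(lo, rng.normal(mean, sd))
        sex[i] = 1.0 if recs[iid].sex == "female" else 0.0
    t2d = (rng.random(n) < cfg.t2d_prevalence).astype(float)

    x_pat = truth.paternal[:, cfg.causal_snp]
    x_mat = truth.maternal[:, cfg.causal_snp]
    ln_bmi = (
        cfg.mu
        + cfg.beta_pat * x_pat
        + cfg.beta_mat * x_mat
        + cfg.beta_age * age
        + cfg.beta_sex * sex
        + cfg.beta_t2d * t2d
        + rng.normal(0.0, cfg.sigma, n)
    )
    df = pd.DataFrame(
        {"bmi": np.exp(ln_bmi), "age": age, "sex": sex, "t2d": t2d},
        index=pd.Index(ids, name="iid"),
    )
    return PhenotypeTable(data=df)


def simulate_ascertained_trios(
    cfg: TrioSimConfig,
) -> tuple[Pedigree, GenotypeMatrix, SimTruth]:
    """Case-parent trios retained only when the offspring is affected.

    Parent genotypes are at Hardy-Weinberg proportions, offspring alleles
    are gene-dropped, and the offspring is affected with probability
    ``baseline_risk * rr_pat^X_pat * rr_mat^X_mat`` (capped at 1), where X
    counts minor (risk) alleles at the first SNP. Candidate trios are drawn
    in vectorised batches until ``n_trios`` affected offspring are
    collected; generation aborts if ``max_candidates`` is exhausted.
    """
    rng = _rng(cfg.seed, 2)
    kept_f: list[np.ndarray] = []
    kept_m: list[np.ndarray] = []
    kept_cp: list[np.ndarray] = []
    kept_cm: list[np.ndarray] = []
    n_kept = 0
    drawn = 0
    accept_guess = min(1.0, cfg.baseline_risk * max(cfg.rr_pat, cfg.rr_mat, 1.0))
    while n_kept < cfg.n_trios:
        need = cfg.n_trios - n_kept
        batch = int(min(200_000, max(1024, 2 * need / max(accept_guess, 1e-4))))
        if drawn + batch > cfg.max_candidates:
            batch = cfg.max_candidates - drawn
            if batch <= 0:
                raise RuntimeError(
                    "affection too rare: candidate budget exhausted before "
                    f"{cfg.n_trios} affected trios were collected"
                )
        drawn += batch
        fa = (rng.random((batch, 2, cfg.n_snps)) < cfg.maf).astype(float)
        mo = (rng.random((batch, 2, cfg.n_snps)) < cfg.maf).astype(float)
        pick_f = rng.integers(0, 2, (batch, cfg.n_snps))
        pick_m = rng.integers(0, 2, (batch, cfg.n_snps))
        child_p = np.take_along_axis(fa, pick_f[:, None, :], axis=1)[:, 0, :]
        child_m = np.take_along_axis(mo, pick_m[:, None, :], axis=1)[:, 0, :]
        risk = np.minimum(
            1.0,
            cfg.baseline_risk
            * cfg.rr_pat ** child_p[:, 0]
            * cfg.rr_mat ** child_m[:, 0],
        )
        aff = rng.random(batch) < risk
        take = np.flatnonzero(aff)[: cfg.n_trios - n_kept]
        kept_f.append(fa[take])
        kept_m.append(mo[take])
        kept_cp.append(child_p[take])
        kept_cm.append(child_m[take])
        n_kept += take.size

    fa = np.vstack(kept_f)
    mo = np.vstack(kept_m)
    cp = np.vstack(kept_cp)
    cm = np.vstack(kept_cm)

    records: list[Individual] = []
    sample_ids: list[str] = []
    fams: list[str] = []
    rows_pat: list[np.ndarray] = []
    rows_mat: list[np.ndarray] = []
    for t in range(cfg.n_trios):
        fam = f"T{t + 1:05d}"
        fid, mid, cid = f"{fam}_fa", f"{fam}_mo", f"{fam}_c1"
        records += [
            Individual(fam, fid, None, None, "male"),
            Individual(fam, mid, None, None, "female"),
            Individual(fam, cid, fid, mid, "unknown"),
        ]
        sample_ids += [fid, mid, cid]
        fams += [fam] * 3
        rows_pat += [fa[t, 0], mo[t, 0], cp[t]]
        rows_mat += [fa[t, 1], mo[t, 1], cm[t]]

    pat = np.vstack(rows_pat)
    mat = np.vstack(rows_mat)
    mafs = np.full(cfg.n_snps, cfg.maf)
    variants = _make_variants(cfg.n_snps, mafs)
    truth = SimTruth(
        sample_ids=sample_ids,
        snp_ids=[v.snp_id for v in variants],
        paternal=pat,
        maternal=mat,
        params={
            "seed": cfg.seed,
            "n_trios": cfg.n_trios,
            "rr_pat": cfg.rr_pat,
            "rr_mat": cfg.rr_mat,
            "baseline_risk": cfg.baseline_risk,
            "candidates_drawn": drawn,
        },
    )
    dosage = pat + mat
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.genotype_missing_rate
        dosage = np.where(miss, np.nan, dosage)
    g = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=dosage,
        sample_families=fams,
    )
    return Pedigree(records), g, truth


def simulate_phased_haplotypes(
    n_individuals: int,
    p1: float,
    p2: float,
    r2: float,
    seed: int,
) -> PhasedGenotypes:
    """Two-locus phased haplotypes at a target allelic correlation.

    Draws 2n haplotypes from the four-class haplotype distribution with
    allele-1 frequencies ``p1``/``p2`` and positive-D squared correlation
    ``r2`` — a direct way to exercise the LD computation without going
    through a pedigree. Raises if the requested (p1, p2, r2) combination is
    infeasible.
    """
    if not (0 < p1 < 1 and 0 < p2 < 1 and 0 <= r2 <= 1):
        raise ValueError("need 0 < p1, p2 < 1 and r2 in [0, 1]")
    d = np.sqrt(r2 * p1 * (1 - p1) * p2 * (1 - p2))
    freqs = np.array(
        [
            p1 * p2 + d,  # 11
            p1 * (1 - p2) - d,  # 10
            (1 - p1) * p2 - d,  # 01
            (1 - p1) * (1 - p2) + d,  # 00
        ]
    )
    if (freqs < -1e-12).any():
        raise ValueError(f"infeasible haplotype frequencies for r2={r2}")
    freqs = np.clip(freqs, 0, None)
    freqs /= freqs.sum()
    rng = _rng(seed, 3)
    draws = rng.choice(4, size=(n_individuals, 2), p=freqs)
    hap_alleles = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=float)
    paternal = hap_alleles[draws[:, 0]]
    maternal = hap_alleles[draws[:, 1]]
    variants = _make_variants(2, np.array([p1, p2]))
    return PhasedGenotypes(
        sample_ids=[f"I{i + 1:05d}" for i in range(n_individuals)],
        variants=variants,
        paternal=paternal,
        maternal=maternal,
        phase_source=np.full((n_individuals, 2), SOURCE_PREPHASED, dtype=np.int8),
        founder_mask=np.zeros(n_individuals, dtype=bool),
    )
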