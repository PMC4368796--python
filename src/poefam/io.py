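"""Readers and writers for PLINK-dialect pedigree/genotype text files.

The containers defined here are shared by every downstream stage:

* :class:`Pedigree` — family structure (FAM columns) with founder status.
* :class:`GenotypeMatrix` — samples x variants minor-allele dosages with
  missingness, plus per-variant allele metadata.
* :class:`PhenotypeTable` — per-individual BMI (kg/m^2), age (years), sex,
  type-2-diabetes status and an optional affection flag for trio designs.

Conventions: missing code ``"0"`` for alleles and parent ids; ``NA`` or
``-9`` for phenotypes; coordinates are 1-based as in MAP files; alleles are
taken as given on the forward strand (no strand flipping is attempted).
Dosage counts copies of the observed minor allele; frequency ties at 0.5
are broken by lexicographic order of the allele symbol and recorded in the
variant notes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_CODE = "0"
SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_CODES_INV = {"male": "1", "female": "2", "unknown": "0"}
_VALID_ALLELES = frozenset("ACGT")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


class GenotypeParseError(ValueError):
    """Raised for malformed PED/MAP input."""


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # 'male' | 'female' | 'unknown'

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A validated collection of individuals with parent links.

    Invariants enforced at construction: individual ids unique within a
    family; parent references resolve within the same family; the parent
    graph is acyclic.
    """

    def __init__(self, records: list[Individual]):
        self.records = list(records)
        self._by_key: dict[tuple[str, str], Individual] = {}
        for rec in self.records:
            key = (rec.family_id, rec.individual_id)
            if key in self._by_key:
                raise PedigreeError(
                    f"duplicate individual id {rec.individual_id!r} in family "
                    f"{rec.family_id!r}"
                )
            self._by_key[key] = rec
        for rec in self.records:
            for pid in (rec.father_id, rec.mother_id):
                if pid is not None and (rec.family_id, pid) not in self._by_key:
                    raise PedigreeError(
                        f"parent {pid!r} of {rec.individual_id!r} not found in "
                        f"family {rec.family_id!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {key: WHITE for key in self._by_key}
        for start in self._by_key:
            if color[start] != WHITE:
                continue
            stack = [(start, iter(self._parent_keys(start)))]
            color[start] = GRAY
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if color[p] == GRAY:
                        raise PedigreeError(
                            f"pedigree cycle involving individual {p[1]!r} "
                            f"in family {p[0]!r}"
                        )
                    if color[p] == WHITE:
                        color[p] = GRAY
                        stack.append((p, iter(self._parent_keys(p))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def _parent_keys(self, key: tuple[str, str]):
        rec = self._by_key[key]
        for pid in (rec.father_id, rec.mother_id):
            if pid is not None:
                yield (rec.family_id, pid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, family_id: str, individual_id: str) -> Individual:
        return self._by_key[(family_id, individual_id)]

    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for rec in self.records:
            fams.setdefault(rec.family_id, []).append(rec)
        return fams

    def founders(self) -> list[Individual]:
        return [r for r in self.records if r.is_founder]

    def individual_ids(self) -> list[str]:
        return [r.individual_id for r in self.records]


@dataclass
class Variant:
    """A biallelic SNP with observed allele metadata."""

    snp_id: str
    chrom: str
    pos: int
    allele1: str | None  # minor allele symbol (dosage-counted), None if unseen
    allele2: str | None  # major allele symbol
    minor_allele: str | None = None
    notes: str = ""
    build: str = "GRCh37"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.snp_id}: position must be >= 1")
        if (
            self.allele1 is not None
            and self.allele2 is not None
            and self.allele1 == self.allele2
        ):
            raise ValueError(f"variant {self.snp_id}: alleles must differ")
        if self.minor_allele is None:
            self.minor_allele = self.allele1

    @property
    def major_allele(self) -> str | None:
        return self.allele2


@dataclass
class GenotypeMatrix:
    """Samples x variants minor-allele dosage matrix.

    ``dosage[i, j]`` counts copies of ``variants[j].minor_allele`` carried by
    ``sample_ids[i]``; missing genotypes are NaN. ``sample_families`` keeps
    the family each sample belongs to so pedigree-aware stages can join back.
    """

    sample_ids: list[str]
    variants: list[Variant]
    dosage: np.ndarray  # float array, NaN = missing
    sample_families: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique across the matrix")
        if not self.sample_families:
            self.sample_families = ["F0"] * len(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, snp_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.snp_id == snp_id:
                return j
        raise KeyError(snp_id)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_variants(self, keep: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=[replace(self.variants[j]) for j in keep],
            dosage=self.dosage[:, keep].copy(),
            sample_families=list(self.sample_families),
        )


@dataclass
class PhenotypeTable:
    """Typed per-individual phenotype/covariate table.

    ``data`` holds the validated rows indexed by individual id with columns
    ``bmi`` (kg/m^2, strictly positive), ``age`` (years), ``sex`` (0 = male,
    1 = female), ``t2d`` (0/1) and optionally ``affected`` (0/1). Rows that
    fail validation are kept in ``flagged`` as (row number, line, reason) —
    flagged, never silently dropped.
    """

    data: pd.DataFrame
    flagged: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# pedigree I/O


def read_pedigree(text: str) -> Pedigree:
    """Parse FAM-dialect lines (family, individual, father, mother, sex, ...)."""
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) < 5:
            raise PedigreeError(
                f"line {lineno}: expected >= 5 whitespace-delimited columns"
            )
        fid, iid, father, mother, sex = fields[:5]
        if iid == MISSING_CODE:
            raise PedigreeError(f"line {lineno}: individual id may not be '0'")
        if father == iid or mother == iid:
            raise PedigreeError(
                f"line {lineno}: individual {iid!r} listed as its own parent"
            )
        records.append(
            Individual(
                family_id=fid,
                individual_id=iid,
                father_id=None if father == MISSING_CODE else father,
                mother_id=None if mother == MISSING_CODE else mother,
                sex=SEX_CODES.get(sex, "unknown"),
            )
        )
    return Pedigree(records)


def write_pedigree(ped: Pedigree) -> str:
    lines = []
    for rec in ped:
        lines.append(
            " ".join(
                [
                    rec.family_id,
                    rec.individual_id,
                    rec.father_id or MISSING_CODE,
                    rec.mother_id or MISSING_CODE,
                    SEX_CODES_INV[rec.sex],
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# genotype I/O


def _parse_map(map_text: str) -> list[tuple[str, str, int]]:
    out = []
    for lineno, line in enumerate(map_text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) == 4:
            chrom, snp_id, _cm, pos = fields
        elif len(fields) == 3:
            chrom, snp_id, pos = fields
        else:
            raise GenotypeParseError(
                f"MAP line {lineno}: expected 3 or 4 columns, got {len(fields)}"
            )
        out.append((chrom, snp_id, int(pos)))
    return out


def read_genotypes(ped_text: str, map_text: str) -> tuple[GenotypeMatrix, Pedigree]:
    """Parse PED + MAP text into a dosage matrix and the embedded pedigree.

    Allele pairs are re-coded as dosages of the minor allele, determined from
    the observed allele counts over all non-missing chromosomes. PED rows may
    carry 5 or 6 leading columns (the optional 6th is the PLINK phenotype
    column, ignored here).
    """
    variants_meta = _parse_map(map_text)
    m = len(variants_meta)

    sample_ids: list[str] = []
    fam_lines: list[str] = []
    sample_families: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(ped_text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        lead = len(fields) - 2 * m
        if lead not in (5, 6):
            raise GenotypeParseError(
                f"PED line {lineno}: {len(fields)} columns inconsistent with "
                f"{m} variants (expected {5 + 2 * m} or {6 + 2 * m})"
            )
        fid, iid = fields[0], fields[1]
        fam_lines.append(" ".join(fields[:5]))
        sample_ids.append(iid)
        sample_families.append(fid)
        alleles = fields[lead:]
        for a in alleles:
            if a != MISSING_CODE and a not in _VALID_ALLELES:
                raise GenotypeParseError(
                    f"PED line {lineno}: invalid allele symbol {a!r}"
                )
        allele_rows.append(alleles)

    if len(set(sample_ids)) != len(sample_ids):
        raise GenotypeParseError("individual ids must be unique across PED rows")

    pedigree = read_pedigree("\n".join(fam_lines))

    n = len(sample_ids)
    dosage = np.full((n, m), np.nan)
    variants: list[Variant] = []
    for j, (chrom, snp_id, pos) in enumerate(variants_meta):
        counts: dict[str, int] = {}
        pairs = []
        for i in range(n):
            a, b = allele_rows[i][2 * j], allele_rows[i][2 * j + 1]
            pairs.append((a, b))
            if a != MISSING_CODE and b != MISSING_CODE:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
        minor, major, notes = _polarize(counts)
        variants.append(
            Variant(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                allele1=minor,
                allele2=major,
                minor_allele=minor,
                notes=notes,
            )
        )
        for i, (a, b) in enumerate(pairs):
            if a == MISSING_CODE or b == MISSING_CODE:
                continue
            dosage[i, j] = (a == minor) + (b == minor)

    return GenotypeMatrix(sample_ids, variants, dosage, sample_families), pedigree


def _polarize(counts: dict[str, int]) -> tuple[str | None, str | None, str]:
    """Pick (minor, major) from observed allele counts; ties break lexically."""
    if not counts:
        return None, None, "all-missing"
    if len(counts) > 2:
        raise GenotypeParseError(
            f"more than two alleles observed: {sorted(counts)}"
        )
    if len(counts) == 1:
        only = next(iter(counts))
        return None, only, "monomorphic"
    a, b = sorted(counts)  # lexicographic
    if counts[a] == counts[b]:
        return a, b, "maf-tie broken lexicographically"
    minor = a if counts[a] < counts[b] else b
    major = b if minor == a else a
    return minor, major, ""


def write_genotypes(g: GenotypeMatrix, ped: Pedigree | None = None) -> tuple[str, str]:
    """Serialize to (ped_text, map_text). Inverse of :func:`read_genotypes`."""
    map_lines = [
        f"{v.chrom} {v.snp_id} 0 {v.pos}" for v in g.variants
    ]
    recs = {r.individual_id: r for r in ped} if ped is not None else {}
    ped_lines = []
    for i, iid in enumerate(g.sample_ids):
        rec = recs.get(iid)
        fid = g.sample_families[i]
        lead = [
            fid,
            iid,
            (rec.father_id if rec else None) or MISSING_CODE,
            (rec.mother_id if rec else None) or MISSING_CODE,
            SEX_CODES_INV[rec.sex] if rec else "0",
        ]
        alleles = []
        for j, v in enumerate(g.variants):
            d = g.dosage[i, j]
            if np.isnan(d):
                alleles += [MISSING_CODE, MISSING_CODE]
            else:
                d = int(d)
                minor = v.minor_allele or "N"
                major = v.major_allele or "N"
                alleles += [minor] * d + [major] * (2 - d)
        ped_lines.append(" ".join(lead + alleles))
    return "\n".join(ped_lines) + "\n", "\n".join(map_lines) + "\n"


# ---------------------------------------------------------------------------
# phenotype I/O

_PHENO_MISSING = {"NA", "-9", ""}


def read_phenotypes(tsv_text: str) -> PhenotypeTable:
    """Parse a phenotype/covariate table.

    Expects a header whose first column is the individual key followed by
    ``bmi``, ``age``, ``sex``, ``t2d`` and optionally ``affected`` (any
    order). Malformed rows are flagged with a reason, not dropped silently.
    """
    lines = [ln for ln in tsv_text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty phenotype table")
    header = lines[0].split()
    key_col = header[0]
    required = {"bmi", "age", "sex", "t2d"}
    missing_cols = required - set(header[1:])
    if missing_cols:
        raise ValueError(f"phenotype header missing columns: {sorted(missing_cols)}")
    has_affected = "affected" in header

    rows = []
    flagged: list[tuple[int, str, str]] = []
    for rowno, line in enumerate(lines[1:], start=2):
        fields = line.split()
        if len(fields) != len(header):
            flagged.append((rowno, line, "column count mismatch"))
            continue
        rec = dict(zip(header, fields))
        try:
            parsed = _parse_pheno_row(rec, has_affected)
        except ValueError as exc:
            flagged.append((rowno, line, str(exc)))
            continue
        parsed[key_col] = rec[key_col]
        rows.append(parsed)

    cols = ["bmi", "age", "sex", "t2d"] + (["affected"] if has_affected else [])
    df = pd.DataFrame(rows, columns=[key_col] + cols)
    if len(df) and df[key_col].duplicated().any():
        dups = df.loc[df[key_col].duplicated(), key_col].tolist()
        raise ValueError(f"duplicate phenotype keys: {dups}")
    df = df.set_index(key_col) if len(df) else df.set_index(key_col, drop=True)
    return PhenotypeTable(data=df, flagged=flagged)


def _parse_pheno_row(rec: dict[str, str], has_affected: bool) -> dict:
    def num(col):
        v = rec[col]
        if v in _PHENO_MISSING:
            return np.nan
        return float(v)

    bmi = num("bmi")
    if not np.isnan(bmi) and bmi <= 0:
        raise ValueError(f"bmi must be > 0, got {bmi}")
    age = num("age")
    if not np.isnan(age) and age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    sex_raw = rec["sex"].lower()
    sex_map = {"1": 0.0, "m": 0.0, "male": 0.0, "2": 1.0, "f": 1.0, "female": 1.0}
    if sex_raw in _PHENO_MISSING or sex_raw == "0":
        sex = np.nan
    elif sex_raw in sex_map:
        sex = sex_map[sex_raw]
    else:
        raise ValueError(f"unknown sex code {rec['sex']!r}")
    t2d = num("t2d")
    if not np.isnan(t2d) and t2d not in (0.0, 1.0):
        raise ValueError(f"t2d must be 0/1, got {rec['t2d']}")
    out = {"bmi": bmi, "age": age, "sex": sex, "t2d": t2d}
    if has_affected:
        aff = num("affected")
        if not np.isnan(aff) and aff not in (0.0, 1.0):
            raise ValueError(f"affected must be 0/1, got {rec['affected']}")
        out["affected"] = aff
    return out


def write_phenotypes(ph: PhenotypeTable, key_col: str = "iid") -> str:
    df = ph.data.reset_index()
    df.columns = [key_col] + list(df.columns[1:])
    # emit sex in the 1=male / 2=female dialect the reader accepts
    df["sex"] = df["sex"].map({0.0: 1, 1.0: 2})
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%g")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# phased VCF (optional pre-phased input path)


def write_phased_vcf(ph, path: str) -> None:
    """Write phased genotypes as a VCF with GT ordered paternal|maternal.

    Unresolved alleles are written as ``.``. Accepts the
    :class:`~poefam.phasing.PhasedGenotypes` container.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ph.sample_ids)
            + "\n"
        )
        for j, v in enumerate(ph.variants):
            ref = v.major_allele or "N"
            alt = v.minor_allele or "."
            cells = []
            for i in range(len(ph.sample_ids)):
                p, m = ph.paternal[i, j], ph.maternal[i, j]
                ps = "." if np.isnan(p) else str(int(p))
                ms = "." if np.isnan(m) else str(int(m))
                cells.append(f"{ps}|{ms}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def read_phased_vcf(path: str):
    """Read a phased VCF (``|``-separated GT, paternal first) produced by
    :func:`write_phased_vcf` or an external phaser. Returns a
    :class:`~poefam.phasing.PhasedGenotypes` with allele 1 = ALT (minor).
    """
    from .phasing import PhasedGenotypes, SOURCE_UNRESOLVED, SOURCE_PREPHASED

    sample_ids: list[str] = []
    variants: list[Variant] = []
    pat_cols: list[np.ndarray] = []
    mat_cols: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, snp_id, ref, alt = fields[:5]
            variants.append(
                Variant(
                    snp_id=snp_id,
                    chrom=chrom,
                    pos=int(pos),
                    allele1=None if alt == "." else alt,
                    allele2=ref,
                )
            )
            pat = np.full(len(sample_ids), np.nan)
            mat = np.full(len(sample_ids), np.nan)
            for i, cell in enumerate(fields[9:]):
                gt = cell.split(":")[0]
                if "|" not in gt:
                    continue  # unphased cell stays missing
                ps, ms = gt.split("|")
                if ps != ".":
                    pat[i] = float(ps)
                if ms != ".":
                    mat[i] = float(ms)
            pat_cols.append(pat)
            mat_cols.append(mat)

    paternal = np.column_stack(pat_cols) if pat_cols else np.empty((len(sample_ids), 0))
    maternal = np.column_stack(mat_cols) if mat_cols else np.empty((len(sample_ids), 0))
    source = np.where(
        np.isnan(paternal) | np.isnan(maternal), SOURCE_UNRESOLVED, SOURCE_PREPHASED
    )
    return PhasedGenotypes(
        sample_ids=sample_ids,
        variants=variants,
        paternal=paternal,
        maternal=maternal,
        phase_source=source,
        founder_mask=np.zeros(len(sample_ids), dtype=bool),
    )
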