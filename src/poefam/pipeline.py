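"""End-to-end orchestration of the two study designs.

``run_quantitative_pipeline`` chains the family-cohort analysis:
QC -> pedigree phasing -> unphased-rate filter -> the three association
tests (standard / paternal / maternal) -> paternal-vs-maternal effect
comparison -> Bonferroni threshold.

``run_trio_pipeline`` runs the case-parent trio analysis: transmission
counting and the exact binomial parental asymmetry test per SNP.

Both emit TSV tables with a provenance header (tool version, seed, config
hash) when given an output directory, and return the tables in memory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    AssociationError,
    bonferroni_threshold,
    compare_betas,
    fit_allelic_regression,
    ln_transform,
)
from .io import GenotypeMatrix, Pedigree, PhenotypeTable
from .pat import count_transmissions_from_pedigree, pat_binomial
from .phasing import filter_unphased, phase_pedigree
from .qc import QCThresholds, apply_qc

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage could not produce usable output (e.g. nothing passed QC)."""


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def run_quantitative_pipeline(
    ped: Pedigree,
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    thresholds: QCThresholds = QCThresholds(),
    alpha: float = 0.05,
    snp_ids: list[str] | None = None,
    phase_threshold: float = 0.30,
    df_override: int | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Full quantitative-trait parent-of-origin analysis.

    Returns a dict with ``qc_report``, ``phasing_report``, ``assoc``
    (one row per SNP x mode), ``beta_compare`` (one row per SNP) and the
    Bonferroni ``threshold`` = alpha / (retained SNPs x 3 tests).
    """
    if snp_ids is not None:
        keep = [g.variant_index(s) for s in snp_ids]
        g = g.subset_variants(keep)

    g_qc, qc_report = apply_qc(g, thresholds)
    if g_qc.n_variants == 0:
        raise PipelineError("no variants remain after QC")
    logger.info("QC: %d of %d variants retained", g_qc.n_variants, g.n_variants)

    ph = phase_pedigree(ped, g_qc)
    ph.validate_against(g_qc)
    ph, phasing_report = filter_unphased(ph, threshold=phase_threshold)
    if ph.n_variants == 0:
        raise PipelineError("no variants remain after the unphased-rate filter")
    logger.info(
        "phasing: %d variants retained, mean phasing rate %.3f",
        ph.n_variants,
        phasing_report.mean_phasing_rate,
    )

    y = ln_transform(pheno)
    covars = pheno.data[["age", "sex", "t2d"]]

    # founders carry origin labels only where homozygous (vacuously), so the
    # parental-mode tests run on phase-eligible non-founders only
    nonfounder = ~ph.founder_mask

    assoc_rows = []
    cmp_rows = []
    m = ph.n_variants
    threshold = bonferroni_threshold(alpha, m, 3)
    for j, var in enumerate(ph.variants):
        jg = g_qc.variant_index(var.snp_id)
        pat_pred = np.where(nonfounder, ph.paternal[:, j], np.nan)
        mat_pred = np.where(nonfounder, ph.maternal[:, j], np.nan)
        predictors = {
            "standard": pd.Series(g_qc.dosage[:, jg], index=g_qc.sample_ids),
            "paternal": pd.Series(pat_pred, index=ph.sample_ids),
            "maternal": pd.Series(mat_pred, index=ph.sample_ids),
        }
        results = {}
        for mode, x in predictors.items():
            try:
                res = fit_allelic_regression(
                    y, x, covars, mode, snp_id=var.snp_id,
                    effect_allele=var.minor_allele or "?",
                )
            except AssociationError as exc:
                logger.warning("%s", exc)
                assoc_rows.append(
                    {
                        "snp_id": var.snp_id,
                        "mode": mode,
                        "effect_allele": var.minor_allele or "?",
                        "beta": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "p": np.nan,
                        "n": 0,
                        "beta_doubled_coding": np.nan,
                        "significant": False,
                        "nominal": False,
                    }
                )
                continue
            results[mode] = res
            assoc_rows.append(
                {
                    "snp_id": res.snp_id,
                    "mode": mode,
                    "effect_allele": res.effect_allele,
                    "beta": res.beta,
                    "se": res.se,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p": res.p,
                    "n": res.n,
                    # slope on the 0/2 doubled-predictor coding some diploid-
                    # only tools force for haploid parental alleles
                    "beta_doubled_coding": (
                        res.beta / 2 if mode != "standard" else res.beta
                    ),
                    "significant": res.p < threshold,
                    "nominal": threshold <= res.p <= 0.05,
                }
            )
        if "paternal" in results and "maternal" in results:
            cmp_res = compare_betas(
                results["paternal"], results["maternal"], df_override=df_override
            )
            cmp_rows.append(
                {
                    "snp_id": cmp_res.snp_id,
                    "delta": cmp_res.delta,
                    "t": cmp_res.t,
                    "p": cmp_res.p,
                }
            )

    out = {
        "qc_report": qc_report.table,
        "phasing_report": phasing_report.table,
        "mean_phasing_rate": phasing_report.mean_phasing_rate,
        "assoc": pd.DataFrame(assoc_rows),
        "beta_compare": pd.DataFrame(cmp_rows, columns=["snp_id", "delta", "t", "p"]),
        "threshold": threshold,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "tool": f"poefam {__version__}",
            "seed": seed if seed is not None else "NA",
            "config_hash": _config_hash(
                {
                    "thresholds": thresholds.__dict__,
                    "alpha": alpha,
                    "snp_ids": snp_ids,
                    "phase_threshold": phase_threshold,
                    "df_override": df_override,
                }
            ),
            "bonferroni_threshold": f"{threshold:.6g}",
        }
        qc_tab = qc_report.table.copy()
        qc_tab["fail_reasons"] = qc_tab["fail_reasons"].apply(
            lambda rs: ";".join(rs) if rs else "."
        )
        _write_tsv(out_dir / "qc_report.tsv", qc_tab, meta)
        _write_tsv(out_dir / "phasing_report.tsv", phasing_report.table, meta)
        _write_tsv(out_dir / "assoc.tsv", out["assoc"], meta)
        _write_tsv(out_dir / "beta_compare.tsv", out["beta_compare"], meta)
    return out


def run_trio_pipeline(
    ped: Pedigree,
    g: GenotypeMatrix,
    affected: dict[str, int] | None = None,
    count_minor: bool = False,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Per-SNP parental asymmetry test over case-parent trios.

    Families that are not usable trios (missing parents or genotypes) are
    skipped with a log note. SNPs with zero informative trios are flagged
    with a missing p-value rather than dropped.
    """
    n_trio_children = sum(
        1 for r in ped if r.father_id is not None and r.mother_id is not None
    )
    if n_trio_children == 0:
        raise PipelineError("no case-parent trios found in the pedigree")
    n_skipped = len(ped) - 3 * n_trio_children
    if n_skipped > 0:
        logger.warning(
            "%d pedigree members are not part of a parent-parent-child trio",
            n_skipped,
        )

    rows = []
    for v in range(g.n_variants):
        tc = count_transmissions_from_pedigree(
            ped, g, v, count_minor=count_minor, affected=affected
        )
        row = {
            "snp_id": tc.snp_id,
            "allele_counted": tc.allele_counted,
            "n_paternal": tc.n_paternal,
            "n_maternal": tc.n_maternal,
            "n_informative": tc.n_informative,
            "n_ambiguous": tc.n_ambiguous,
            "n_mendel_errors": tc.n_mendel_errors,
        }
        if tc.n_informative == 0:
            row["p"] = np.nan
            row["note"] = "no informative trios"
        else:
            row["p"] = pat_binomial(tc).p
            row["note"] = ""
        rows.append(row)
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "tool": f"poefam {__version__}",
            "seed": seed if seed is not None else "NA",
            "config_hash": _config_hash({"count_minor": count_minor}),
        }
        _write_tsv(out_dir / "pat.tsv", table, meta)
    return {"pat": table}
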