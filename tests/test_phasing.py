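import numpy as np
import pytest

import poefam as pf
from poefam.phasing import (
    SOURCE_HOMOZYGOTE,
    SOURCE_PROPAGATED,
    SOURCE_TRIO_FORCED,
    SOURCE_UNRESOLVED,
    PhasedGenotypes,
    phasing_missing_rate,
)


def build_matrix(sample_defs, dosages):
    """sample_defs: list of (iid, father, mother); one variant."""
    fam_lines = []
    for iid, fa, mo in sample_defs:
        fam_lines.append(f"F1 {iid} {fa or '0'} {mo or '0'} 1")
    ped = pf.read_pedigree("\n".join(fam_lines) + "\n")
    g = pf.GenotypeMatrix(
        sample_ids=[s[0] for s in sample_defs],
        variants=[pf.Variant("rs", "16", 100, "A", "G")],
        dosage=np.array(dosages, dtype=float).reshape(-1, 1),
        sample_families=["F1"] * len(sample_defs),
    )
    return ped, g


class TestTrioRules:
    def test_forced_transmission(self):
        ped, g = build_matrix(
            [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")],
            [2, 0, 1],
        )
        ph = pf.phase_pedigree(ped, g)
        k = ph.sample_ids.index("kid")
        assert ph.paternal[k, 0] == 1 and ph.maternal[k, 0] == 0
        assert ph.phase_source[k, 0] == SOURCE_TRIO_FORCED

    def test_all_heterozygous_trio_unresolved(self):
        ped, g = build_matrix(
            [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")],
            [1, 1, 1],
        )
        ph = pf.phase_pedigree(ped, g)
        k = ph.sample_ids.index("kid")
        assert np.isnan(ph.paternal[k, 0]) and np.isnan(ph.maternal[k, 0])
        assert ph.phase_source[k, 0] == SOURCE_UNRESOLVED

    def test_homozygous_child_regardless_of_parents(self):
        ped, g = build_matrix(
            [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")],
            [1, 1, 0],
        )
        ph = pf.phase_pedigree(ped, g)
        k = ph.sample_ids.index("kid")
        assert ph.paternal[k, 0] == 0 and ph.maternal[k, 0] == 0
        assert ph.phase_source[k, 0] == SOURCE_HOMOZYGOTE

    def test_one_resolved_side_forces_the_other(self):
        # mother homozygous minor, child heterozygous: maternal=1, paternal=0
        ped, g = build_matrix(
            [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")],
            [1, 2, 1],
        )
        ph = pf.phase_pedigree(ped, g)
        k = ph.sample_ids.index("kid")
        assert ph.paternal[k, 0] == 0 and ph.maternal[k, 0] == 1


class TestPropagation:
    def test_grandparents_resolve_missing_parent_genotype(self):
        # father ungenotyped but both his parents are hom-major -> father is
        # hom-major -> child's heterozygous minor allele must be maternal
        ped, g = build_matrix(
            [
                ("gf", None, None),
                ("gm", None, None),
                ("dad", "gf", "gm"),
                ("mom", None, None),
                ("kid", "dad", "mom"),
            ],
            [0, 0, np.nan, 1, 1],
        )
        ph = pf.phase_pedigree(ped, g)
        k = ph.sample_ids.index("kid")
        assert ph.paternal[k, 0] == 0 and ph.maternal[k, 0] == 1
        assert ph.phase_source[k, 0] == SOURCE_PROPAGATED

    def test_offspring_feed_back_into_parent_phase(self):
        # X is ungenotyped; spouse hom-major and child carries the minor
        # allele, so X carries it; X's own father is hom-major, pinning X's
        # paternal allele to 0 -> X resolves to an origin-labelled het
        ped, g = build_matrix(
            [
                ("gf", None, None),
                ("x", "gf", None),
                ("spouse", None, None),
                ("kid", "x", "spouse"),
            ],
            [0, np.nan, 0, 1],
        )
        ph = pf.phase_pedigree(ped, g)
        i = ph.sample_ids.index("x")
        assert ph.paternal[i, 0] == 0 and ph.maternal[i, 0] == 1

    def test_soundness_against_simulated_truth(self, sim_cohort):
        """Every allele the solver resolves equals the gene-dropping truth;
        propagation never guesses."""
        _, ped, g, truth, _ = sim_cohort
        ph = pf.phase_pedigree(ped, g)
        res = ph.resolved() & ~np.isnan(g.dosage)
        assert np.array_equal(ph.paternal[res], truth.paternal[res])
        assert np.array_equal(ph.maternal[res], truth.maternal[res])

    def test_sum_invariant_globally(self, sim_cohort):
        _, ped, g, _, _ = sim_cohort
        ph = pf.phase_pedigree(ped, g)
        ph.validate_against(g)

    def test_order_independence(self, sim_cohort):
        _, ped, g, _, _ = sim_cohort
        order = np.random.default_rng(3).permutation(g.n_samples)
        g2 = pf.GenotypeMatrix(
            sample_ids=[g.sample_ids[i] for i in order],
            variants=g.variants,
            dosage=g.dosage[order, :],
            sample_families=[g.sample_families[i] for i in order],
        )
        ped2 = pf.Pedigree(list(reversed(list(ped))))
        ph1 = pf.phase_pedigree(ped, g)
        ph2 = pf.phase_pedigree(ped2, g2)
        back = np.argsort(order)
        np.testing.assert_array_equal(ph1.paternal, ph2.paternal[back, :])
        np.testing.assert_array_equal(ph1.maternal, ph2.maternal[back, :])

    def test_mendelian_inconsistency_abstains(self):
        ped, g = build_matrix(
            [("dad", None, None), ("mom", None, None), ("kid", "dad", "mom")],
            [0, 0, 2],
        )
        ph = pf.phase_pedigree(ped, g)
        assert ("F1", "rs") in ph.mendelian_errors
        k = ph.sample_ids.index("kid")
        assert np.isnan(ph.paternal[k, 0])


def synthetic_phased(unphased_rates, n_samples=100):
    """PhasedGenotypes with prescribed per-variant unphased rates among
    non-founders (founder mask all False)."""
    m = len(unphased_rates)
    pat = np.zeros((n_samples, m))
    mat = np.ones((n_samples, m))
    src = np.full((n_samples, m), 2, dtype=np.int8)
    for j, rate in enumerate(unphased_rates):
        k = int(round(rate * n_samples))
        pat[:k, j] = np.nan
        src[:k, j] = SOURCE_UNRESOLVED
    return PhasedGenotypes(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        variants=[
            pf.Variant(f"snp{j}", "16", 100 + j, "A", "G") for j in range(m)
        ],
        paternal=pat,
        maternal=mat,
        phase_source=src,
        founder_mask=np.zeros(n_samples, dtype=bool),
    )


class TestUnphasedFilter:
    def test_rate_trivials(self):
        ph = synthetic_phased([0.0, 0.3], n_samples=10)
        assert phasing_missing_rate(ph, 0) == 0.0
        assert phasing_missing_rate(ph, 1) == pytest.approx(0.3)

    def test_boundary_is_inclusive(self):
        ph = synthetic_phased([0.30, 0.29])
        filtered, rep = pf.filter_unphased(ph, threshold=0.30)
        assert [v.snp_id for v in filtered.variants] == ["snp1"]
        assert rep.table["excluded"].tolist() == [True, False]

    def test_27_to_22_bookkeeping(self):
        rates = [0.05] * 20 + [0.29, 0.1] + [0.30, 0.35, 0.5, 0.95, 0.31]
        ph = synthetic_phased(rates)
        filtered, rep = pf.filter_unphased(ph)
        assert ph.n_variants == 27
        assert filtered.n_variants == 22
        assert int(rep.table["excluded"].sum()) == 5

    def test_founders_excluded_from_rate(self):
        ph = synthetic_phased([0.0], n_samples=10)
        ph.founder_mask[:5] = True
        ph.paternal[:5, 0] = np.nan  # unresolved founders don't count
        assert phasing_missing_rate(ph, 0) == 0.0
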