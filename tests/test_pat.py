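from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poefam as pf
from poefam.pat import TransmissionCounts, count_transmissions, pat_binomial


def binomial_two_sided_oracle(k, n):
    """Doubled smaller exact tail of Binomial(n, 1/2), in exact rationals."""
    lo = min(k, n - k)
    tail = sum(Fraction(comb(n, i), 2**n) for i in range(lo + 1))
    return float(min(Fraction(1), 2 * tail))


class TestCounting:
    def test_forced_paternal(self):
        # father AA, mother GG, child AG, counting A (dosages of A: 2, 0, 1)
        tc = count_transmissions([(2, 0, 1)], "rs", "A")
        assert (tc.n_paternal, tc.n_maternal) == (1, 0)

    def test_both_parents_het_ambiguous(self):
        tc = count_transmissions([(1, 1, 1)], "rs", "A")
        assert tc.n_informative == 0 and tc.n_ambiguous == 1

    def test_homozygous_child_uninformative(self):
        tc = count_transmissions([(2, 0, 2), (0, 0, 0)], "rs", "A")
        assert tc.n_informative == 0 and tc.n_ambiguous == 0

    def test_hand_built_fixture_counts_3_2(self):
        trios = [
            (2, 0, 1),  # paternal
            (2, 1, 1),  # father must give A (mother could give other)
            (1, 0, 1),  # only father carries A -> paternal
            (0, 2, 1),  # maternal
            (1, 2, 1),  # only mother can give... both? father het, mother AA
            (1, 1, 1),  # ambiguous
        ]
        tc = count_transmissions(trios, "rs", "A")
        assert (tc.n_paternal, tc.n_maternal) == (3, 2)
        assert tc.n_ambiguous == 1

    def test_missing_genotype_skipped(self):
        tc = count_transmissions([(np.nan, 0, 1), (2, 0, 1)], "rs", "A")
        assert tc.n_informative == 1

    def test_mendelian_impossible_logged(self):
        # both parents hom-other, child het carrying the allele: impossible
        tc = count_transmissions([(0, 0, 1)], "rs", "A")
        assert tc.n_informative == 0 and tc.n_mendel_errors == 1

    def test_bad_dosage_errors(self):
        with pytest.raises(ValueError, match="dosage"):
            count_transmissions([(3, 0, 1)], "rs", "A")


class TestBinomialPAT:
    @pytest.mark.parametrize(
        "k,n_other,expected",
        [
            (111, 152, 0.01),
            (129, 128, 1.00),
            (85, 114, 0.05),
            (134, 119, 0.38),
            (139, 123, 0.35),
            (140, 123, 0.32),
            (122, 151, 0.09),
        ],
    )
    def test_reported_transmission_counts_two_dp(self, k, n_other, expected):
        res = pat_binomial(TransmissionCounts("rs", "X", k, n_other))
        assert round(res.p, 2) == expected

    def test_closed_form_7_0(self):
        res = pat_binomial(TransmissionCounts("rs", "X", 7, 0))
        assert res.p == pytest.approx(2 * 0.5**7)
        assert res.p == pytest.approx(0.015625)

    def test_no_informative_trios_errors(self):
        with pytest.raises(ValueError, match="no informative"):
            pat_binomial(TransmissionCounts("rs", "X", 0, 0))

    @settings(derandomize=True, max_examples=80)
    @given(st.integers(0, 400), st.integers(0, 400))
    def test_matches_fraction_oracle_and_symmetry(self, a, b):
        if a + b == 0:
            return
        p_ab = pat_binomial(TransmissionCounts("rs", "X", a, b)).p
        p_ba = pat_binomial(TransmissionCounts("rs", "X", b, a)).p
        assert p_ab == pytest.approx(p_ba, rel=1e-12)
        assert p_ab == pytest.approx(
            binomial_two_sided_oracle(a, a + b), rel=1e-9
        )
        assert 0 < p_ab <= 1

    def test_close_to_minlike_rule_at_study_scale(self):
        """At the study's count sizes the doubled-tail rule and scipy's
        minimum-likelihood two-sided rule agree to 2 d.p."""
        from scipy.stats import binomtest

        for k, other in [(111, 152), (129, 128), (85, 114), (122, 151)]:
            ours = pat_binomial(TransmissionCounts("rs", "X", k, other)).p
            ref = binomtest(k, k + other, 0.5).pvalue
            assert round(ours, 2) == round(ref, 2)

    def test_power_monotone_in_asymmetry(self):
        """At fixed n, the p-value at the expected counts shrinks as the
        maternal:paternal transmission asymmetry grows."""
        n = 200
        ps = [
            pat_binomial(TransmissionCounts("rs", "X", n // 2 - d, n // 2 + d)).p
            for d in (0, 10, 20, 30, 40)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestPedigreeCounting:
    def make_trios(self, geno_triples):
        """geno_triples: minor-allele dosages (father, mother, child)."""
        recs, ids, fams, rows = [], [], [], []
        for t, (df, dm, dc) in enumerate(geno_triples):
            fam = f"T{t}"
            f, m, c = f"{fam}_f", f"{fam}_m", f"{fam}_c"
            recs += [
                pf.io.Individual(fam, f, None, None, "male"),
                pf.io.Individual(fam, m, None, None, "female"),
                pf.io.Individual(fam, c, f, m, "unknown"),
            ]
            ids += [f, m, c]
            fams += [fam] * 3
            rows += [df, dm, dc]
        ped = pf.Pedigree(recs)
        g = pf.GenotypeMatrix(
            sample_ids=ids,
            variants=[pf.Variant("rs", "16", 1, "A", "G")],
            dosage=np.array(rows, dtype=float).reshape(-1, 1),
            sample_families=fams,
        )
        return ped, g

    def test_major_allele_default_and_minor_flag_swap(self):
        # minor dosages: father 0 (GG), mother 2 (AA), child 1 (AG)
        # counting major G: father transmitted G -> paternal
        ped, g = self.make_trios([(0, 2, 1), (2, 0, 1)])
        tc_major = pf.count_transmissions_from_pedigree(ped, g, 0)
        assert tc_major.allele_counted == "G"
        assert (tc_major.n_paternal, tc_major.n_maternal) == (1, 1)
        tc_minor = pf.count_transmissions_from_pedigree(ped, g, 0, count_minor=True)
        assert (tc_minor.n_paternal, tc_minor.n_maternal) == (1, 1)
        assert (
            pat_binomial(tc_major).p == pat_binomial(tc_minor).p
        )

    def test_affected_filter(self):
        ped, g = self.make_trios([(0, 2, 1), (0, 2, 1)])
        aff = {"T0_c": 1, "T1_c": 0}
        tc = pf.count_transmissions_from_pedigree(ped, g, 0, affected=aff)
        assert tc.n_informative == 1
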