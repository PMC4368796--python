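import numpy as np
import pandas as pd
import pytest
from scipy import stats

import poefam as pf
from poefam.assoc import (
    AssocResult,
    AssociationError,
    compare_reported_estimates,
)


def fit(y, x, cov=None, mode="standard", **kw):
    idx = y.index
    cov = pd.DataFrame(index=idx) if cov is None else cov
    return pf.fit_allelic_regression(y, x, cov, mode, **kw)


class TestLnTransform:
    def test_values(self):
        tab = pf.PhenotypeTable(
            data=pd.DataFrame(
                {"bmi": [np.e**2, 1.0, 26.1], "age": 0, "sex": 0, "t2d": 0},
                index=["a", "b", "c"],
            )
        )
        y = pf.ln_transform(tab)
        assert y["a"] == pytest.approx(2.0)
        assert y["b"] == pytest.approx(0.0)
        assert y["c"] == pytest.approx(np.log(26.1))


class TestAllelicRegression:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(0)
        n = 80
        x = pd.Series(rng.integers(0, 3, n).astype(float))
        age = pd.Series(rng.uniform(20, 70, n))
        y = 0.5 * x + 0.1 * age + 1.0
        res = fit(y, x, pd.DataFrame({"age": age}), "standard", snp_id="rs")
        assert res.beta == pytest.approx(0.5, abs=1e-10)
        assert res.p < 1e-30
        assert res.n == n
        lo, hi = res.ci95
        assert (lo, hi) == pytest.approx(
            (res.beta - 1.959964 * res.se, res.beta + 1.959964 * res.se)
        )

    def test_monomorphic_predictor_errors(self):
        y = pd.Series(np.random.default_rng(1).normal(size=30))
        x = pd.Series(np.zeros(30))
        with pytest.raises(AssociationError, match="monomorphic"):
            fit(y, x)

    def test_too_few_rows_errors(self):
        y = pd.Series([1.0, 2.0])
        x = pd.Series([0.0, 1.0])
        with pytest.raises(AssociationError, match="complete cases"):
            fit(y, x)

    def test_complete_case_drops_missing(self):
        rng = np.random.default_rng(2)
        n = 50
        x = pd.Series(rng.integers(0, 3, n).astype(float))
        y = pd.Series(0.3 * x + rng.normal(0, 0.1, n))
        x_miss = x.copy()
        x_miss.iloc[:10] = np.nan
        res = fit(y, x_miss)
        assert res.n == 40

    def test_orientation_equivariance(self):
        """Flipping the effect allele negates beta and keeps p, all modes."""
        rng = np.random.default_rng(3)
        n = 200
        cov = pd.DataFrame({"age": rng.uniform(20, 70, n)})
        for mode, levels in [("standard", 3), ("paternal", 2), ("maternal", 2)]:
            x = pd.Series(rng.integers(0, levels, n).astype(float))
            y = pd.Series(0.2 * x + 0.01 * cov["age"] + rng.normal(0, 0.3, n))
            a = fit(y, x, cov, mode)
            b = fit(y, (levels - 1) - x, cov, mode)
            assert b.beta == pytest.approx(-a.beta)
            assert b.p == pytest.approx(a.p)

    def test_paternal_ci_covers_truth(self):
        """Nominal CI coverage of the paternal-mode estimate under the
        generating model (small replicate study)."""
        rng = np.random.default_rng(4)
        n, beta_pat, reps = 300, 0.02, 200
        hits = 0
        for _ in range(reps):
            xp = pd.Series((rng.random(n) < 0.3).astype(float))
            y = pd.Series(beta_pat * xp + rng.normal(0, 0.1, n))
            res = fit(y, xp, mode="paternal")
            hits += res.ci95[0] <= beta_pat <= res.ci95[1]
        assert hits / reps >= 0.90


class TestCompareBetas:
    def mk(self, beta, se, mode, allele="G", snp="rs1"):
        return AssocResult(
            snp_id=snp, mode=mode, effect_allele=allele, beta=beta, se=se,
            ci95=(beta - 1.959964 * se, beta + 1.959964 * se), p=0.5, n=100,
        )

    def test_equal_betas_give_p_one(self):
        c = pf.compare_betas(
            self.mk(0.1, 0.02, "paternal"), self.mk(0.1, 0.03, "maternal")
        )
        assert c.t == 0.0 and c.p == 1.0

    def test_normal_reference_oracle(self):
        c = pf.compare_betas(
            self.mk(0.2, 0.1, "paternal"), self.mk(-0.1, 0.1, "maternal")
        )
        assert c.t == pytest.approx(0.3 / np.sqrt(0.02), abs=1e-4)
        assert c.t == pytest.approx(2.1213, abs=1e-4)
        assert c.p == pytest.approx(2 * stats.norm.sf(2.1213203), abs=1e-6)
        assert c.p == pytest.approx(0.0339, abs=2e-4)

    def test_df_override_uses_t_reference(self):
        a = self.mk(0.2, 0.1, "paternal")
        b = self.mk(-0.1, 0.1, "maternal")
        p_norm = pf.compare_betas(a, b).p
        p_t = pf.compare_betas(a, b, df_override=10).p
        assert p_t > p_norm  # heavier tails
        assert pf.compare_betas(a, b, df_override=100000).p == pytest.approx(
            p_norm, rel=1e-3
        )

    def test_orientation_mismatch_errors(self):
        with pytest.raises(ValueError, match="orientation"):
            pf.compare_betas(
                self.mk(0.2, 0.1, "paternal", allele="G"),
                self.mk(0.1, 0.1, "maternal", allele="T"),
            )

    def test_zero_se_errors(self):
        with pytest.raises(ValueError, match="positive"):
            pf.compare_betas(
                self.mk(0.2, 0.0, "paternal"), self.mk(0.1, 0.1, "maternal")
            )

    def test_type_i_error_under_equal_effects(self):
        """With identical nonzero paternal and maternal effects, the
        comparison rejects at ~5%."""
        rng = np.random.default_rng(5)
        n, reps, beta = 250, 2000, 0.05
        rej = 0
        for _ in range(reps):
            xp = (rng.random(n) < 0.3).astype(float)
            xm = (rng.random(n) < 0.3).astype(float)
            noise = rng.normal(0, 0.15, n)
            y = pd.Series(beta * xp + beta * xm + noise)
            a = fit(y, pd.Series(xp), mode="paternal", snp_id="rs")
            b = fit(y, pd.Series(xm), mode="maternal", snp_id="rs")
            rej += pf.compare_betas(a, b).p < 0.05
        assert rej / reps == pytest.approx(0.05, abs=0.02)

    def test_dilution_of_pure_maternal_effect(self):
        """A maternal-only effect yields stronger maternal-mode tests and a
        standard-mode slope near half the maternal effect."""
        rng = np.random.default_rng(6)
        n, reps, beta_mat = 500, 200, 0.04
        p_pat, p_mat, std_betas = [], [], []
        for _ in range(reps):
            xp = (rng.random(n) < 0.3).astype(float)
            xm = (rng.random(n) < 0.3).astype(float)
            y = pd.Series(beta_mat * xm + rng.normal(0, 0.15, n))
            p_pat.append(fit(y, pd.Series(xp), mode="paternal").p)
            p_mat.append(fit(y, pd.Series(xm), mode="maternal").p)
            std_betas.append(fit(y, pd.Series(xp + xm), mode="standard").beta)
        assert np.median(p_mat) < np.median(p_pat)
        assert np.mean(std_betas) == pytest.approx(beta_mat / 2, abs=0.005)


class TestReportedEstimates:
    def test_se_from_ci_arithmetic(self):
        se = pf.se_from_ci((-0.003, 0.010), 0.003)
        assert se == pytest.approx(0.0033164, abs=1e-6)

    def test_se_from_ci_inverse_identity(self):
        beta, s = 0.12, 0.034
        ci = (beta - 1.959964 * s, beta + 1.959964 * s)
        assert pf.se_from_ci(ci, beta) == pytest.approx(s, rel=1e-9)

    def test_degenerate_interval_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            pf.se_from_ci((0.0, 0.0), 0.0)

    def test_reversed_bounds_normalised(self):
        # printed maternal interval arrives high-to-low
        assert pf.se_from_ci((-0.003, -0.017), -0.010) == pytest.approx(
            0.014 / (2 * 1.959964), rel=1e-6
        )

    def test_published_style_comparison(self):
        c = compare_reported_estimates(
            "rs1861868", 0.003, (-0.003, 0.010), -0.010, (-0.003, -0.017)
        )
        assert c.t == pytest.approx(2.667, abs=0.01)
        assert c.p <= 0.05


class TestBonferroni:
    def test_values(self):
        assert pf.bonferroni_threshold(0.05, 22, 3) == pytest.approx(
            0.05 / 66
        )
        assert pf.bonferroni_threshold(0.05, 1, 1) == 0.05
        assert pf.bonferroni_threshold(0.06, 2, 3) == pytest.approx(0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pf.bonferroni_threshold(0.05, 0, 3)
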