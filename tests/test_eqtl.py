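"""Per-cohort mapping: QC, robust adjustment, association, FDR, calls."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from lungeqtl import eqtl


def hwe_exact_oracle(n0: int, n1: int, n2: int) -> float:
    """Brute-force exact HWE P: enumerate every heterozygote count directly
    from the conditional multinomial probabilities (independent of the
    recurrence used in the implementation)."""
    n = n0 + n1 + n2
    n_rare = 2 * min(n0, n2) + n1
    n_common = 2 * n - n_rare

    def prob(h: int) -> float:
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        # P(config | allele counts) = n! 2^h / (hr! h! hc!) / (2n)!/(nr! nc!)
        num = (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2)
        )
        den = (
            math.lgamma(2 * n + 1)
            - math.lgamma(n_rare + 1)
            - math.lgamma(n_common + 1)
        )
        return math.exp(num - den)

    hs = range(n_rare % 2, min(n_rare, n) + 1, 2)
    probs = {h: prob(h) for h in hs}
    obs = probs[n1]
    return min(1.0, sum(p for p in probs.values() if p <= obs * (1 + 1e-12)))


class TestHweExact:
    def test_perfect_hwe_is_retained(self):
        assert eqtl.hwe_exact_test(25, 50, 25) > 1e-6

    def test_no_heterozygotes_is_removed(self):
        assert eqtl.hwe_exact_test(50, 0, 50) < 1e-6

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (50, 0, 50), (10, 5, 1), (0, 0, 30), (3, 9, 8), (1, 1, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert eqtl.hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), rel=1e-10
        )

    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
    )
    def test_matches_oracle_property(self, n0, n1, n2):
        if n0 + n1 + n2 == 0:
            return
        assert eqtl.hwe_exact_test(n0, n1, n2) == pytest.approx(
            hwe_exact_oracle(n0, n1, n2), rel=1e-9
        )


class TestQc:
    def test_low_call_rate_snp_removed(self):
        G = pd.DataFrame(
            {
                "s1": [0, np.nan],
                "s2": [1, np.nan],
                "s3": [1, 0],
                "s4": [2, 1],
            },
            index=["ok", "halfmissing"],
            dtype=float,
        )
        kept, report = eqtl.qc_genotypes(G)
        assert list(kept.index) == ["ok"]
        assert report.n_removed_call_rate == 1
        assert report.n_removed_hwe == 0

    def test_hwe_failure_removed(self):
        n = 100
        g_bad = np.array([0] * 50 + [2] * 50, dtype=float)
        g_ok = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)
        G = pd.DataFrame([g_ok, g_bad], index=["ok", "bad"],
                         columns=[f"s{i}" for i in range(n)])
        kept, report = eqtl.qc_genotypes(G)
        assert list(kept.index) == ["ok"]
        assert report.n_removed_hwe == 1

    def test_everything_removed_raises(self):
        G = pd.DataFrame([[np.nan] * 4], index=["snp"], columns=list("abcd"))
        with pytest.raises(ValueError):
            eqtl.qc_genotypes(G)


def _cov_table(n: int, rng) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.uniform(40, 80, n),
            "sex": rng.integers(0, 2, n),
            "smoking": rng.choice(["never", "ex", "current"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestAdjustExpression:
    def test_no_covariate_effect_returns_centered_expression(self):
        rng = np.random.default_rng(0)
        cov = _cov_table(200, rng)
        y = rng.normal(size=(3, 200))
        E = pd.DataFrame(y, index=list("abc"), columns=cov.index)
        resid = eqtl.adjust_expression(E, cov)
        centered = y - y.mean(axis=1, keepdims=True)
        # no planted covariate signal: residuals track centered input closely
        assert np.abs(resid.to_numpy() - centered).max() < 0.15
        assert np.allclose(resid.to_numpy().mean(axis=1), 0.0, atol=1e-12)

    def test_planted_age_effect_is_removed(self):
        rng = np.random.default_rng(1)
        cov = _cov_table(300, rng)
        y = 0.05 * cov["age"].to_numpy() + rng.normal(size=300)
        E = pd.DataFrame([y], index=["a"], columns=cov.index)
        resid = eqtl.adjust_expression(E, cov).to_numpy()[0]
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 0.05

    def test_huber_resists_outlier_more_than_ols(self):
        rng = np.random.default_rng(2)
        cov = _cov_table(100, rng)
        age = cov["age"].to_numpy()
        y = 0.02 * age + rng.normal(scale=0.5, size=100)
        y_out = y.copy()
        y_out[0] += 20 * 0.5  # +20 SD outlier
        X = np.column_stack([np.ones(100), age])
        ols_clean = np.linalg.lstsq(X, y, rcond=None)[0][1]
        ols_out = np.linalg.lstsq(X, y_out, rcond=None)[0][1]
        rlm_out = (
            sm.RLM(y_out, X, M=sm.robust.norms.HuberT(t=1.345)).fit().params[1]
        )
        assert abs(rlm_out - ols_clean) < abs(ols_out - ols_clean)

    def test_constant_row_warns_and_zeroes(self):
        rng = np.random.default_rng(3)
        cov = _cov_table(60, rng)
        E = pd.DataFrame([[1.0] * 60], index=["const"], columns=cov.index)
        with pytest.warns(UserWarning):
            resid = eqtl.adjust_expression(E, cov)
        assert (resid.to_numpy() == 0).all()

    def test_non_numeric_covariates_raise(self):
        rng = np.random.default_rng(4)
        cov = _cov_table(10, rng)
        cov["age"] = "old"
        E = pd.DataFrame([np.arange(10.0)], index=["a"], columns=cov.index)
        with pytest.raises(Exception):
            eqtl.adjust_expression(E, cov)


class TestClassifyPair:
    WINDOW = 1_000_000

    @pytest.mark.parametrize(
        "snp_pos,expected",
        [
            (5_000_000 - 1_000_000, "cis"),  # exactly at the upstream boundary
            (5_000_000 - 1_000_001, "trans"),
            (5_010_000 + 1_000_000, "cis"),  # downstream boundary, inclusive
            (5_010_000 + 1_000_001, "trans"),
            (5_005_000, "cis"),  # inside the probeset
        ],
    )
    def test_window_boundaries(self, snp_pos, expected):
        assert (
            eqtl.classify_pair("chr1", snp_pos, "chr1", 5_000_000, 5_010_000, self.WINDOW)
            == expected
        )

    def test_different_chromosome_is_trans(self):
        assert eqtl.classify_pair("chr2", 5_000_000, "chr1", 5_000_000, 5_010_000) == "trans"

    def test_missing_position_raises(self):
        with pytest.raises(ValueError):
            eqtl.classify_pair("chr1", np.nan, "chr1", 1, 2)


class TestAssociation:
    def test_worked_example(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = np.array([0.1, 0.6, 1.1, -0.1, 0.4, 0.9])
        res = eqtl.test_association(g, y, min_samples=2)
        assert res["beta"] == pytest.approx(0.5, abs=1e-12)
        assert res["r2"] == pytest.approx(4 / 4.24, abs=1e-12)

    def test_perfect_fit(self):
        g = np.array([0.0, 1, 2, 1, 0, 2])
        res = eqtl.test_association(g, g, min_samples=2)
        assert res["beta"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError):
            eqtl.test_association(np.ones(40), np.random.default_rng(0).normal(size=40))

    def test_min_samples_enforced(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            eqtl.test_association(rng.integers(0, 3, 10), rng.normal(size=10))

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 120).astype(float)
        y = 0.4 * g + rng.normal(size=120)
        res = eqtl.test_association(g, y)
        fit = sm.OLS(y, sm.add_constant(g)).fit()
        assert res["beta"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res["se"] == pytest.approx(fit.bse[1], abs=1e-10)
        assert res["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)
        assert res["r2"] == pytest.approx(fit.rsquared, abs=1e-10)

    def test_pairwise_missing_dropped(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, 100).astype(float)
        y = 0.5 * g + rng.normal(size=100)
        g_miss = g.copy()
        g_miss[:5] = np.nan
        res = eqtl.test_association(g_miss, y)
        ref = eqtl.test_association(g[5:], y[5:])
        assert res == ref


class TestScan:
    def test_cardinality_and_class_partition(self, small_dataset):
        ds = small_dataset
        c = ds.cohorts["cohort1"]
        G = c.genotypes.iloc[:40]
        resid = eqtl.adjust_expression(c.expression.iloc[:10], c.covariates)
        table = eqtl.scan(G, resid, ds.snps, ds.probesets, cohort="cohort1")
        assert len(table) == 40 * 10  # no monomorphic SNPs at these MAFs
        assert set(table["class"]) <= {"cis", "trans"}
        assert (table["cis"] == (table["class"] == "cis")).all()

    def test_matrix_scan_matches_single_pair_tests(self, small_dataset):
        ds = small_dataset
        c = ds.cohorts["cohort1"]
        G = c.genotypes.iloc[:15]
        resid = eqtl.adjust_expression(c.expression.iloc[:5], c.covariates)
        table = eqtl.scan(G, resid, ds.snps, ds.probesets, cohort="cohort1")
        rng = np.random.default_rng(0)
        for _ in range(10):
            row = table.iloc[rng.integers(0, len(table))]
            ref = eqtl.test_association(
                G.loc[row["snp_id"]].to_numpy(), resid.loc[row["probeset_id"]].to_numpy()
            )
            for key in ("beta", "se", "p", "r2"):
                assert row[key] == pytest.approx(ref[key], rel=1e-9), key


class TestFdrThreshold:
    def test_worked_example(self):
        thr = eqtl.estimate_fdr_threshold(
            np.array([0.001, 0.01, 0.02, 0.5]),
            [np.array([0.03, 0.2, 0.6, 0.9])],
            target_fdr=0.10,
        )
        assert thr.p_cutoff == pytest.approx(0.02)
        assert thr.n_discoveries == 3

    def test_observed_equals_null_gives_no_discoveries(self):
        x = np.array([0.05, 0.2, 0.4, 0.8])
        thr = eqtl.estimate_fdr_threshold(x, [x], target_fdr=0.10)
        assert thr.p_cutoff == 0.0
        assert thr.n_discoveries == 0

    def test_target_one_keeps_everything(self):
        x = np.array([0.01, 0.3, 0.77])
        thr = eqtl.estimate_fdr_threshold(x, [np.array([0.5, 0.6, 0.9])], target_fdr=1.0)
        assert thr.p_cutoff == pytest.approx(0.77)
        assert thr.n_discoveries == 3


class TestCalls:
    def _results(self):
        return pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3", "rs4"],
                "probeset_id": ["p1", "p1", "p2", "p2"],
                "cohort": "c",
                "beta": [0.5, 0.4, 0.3, 0.3],
                "se": 0.1,
                "p": [1e-8, 1e-5, 1e-3, 1e-3],
                "r2": 0.2,
                "n": 100,
                "cis": [True, True, True, True],
            }
        )

    def _snps(self):
        return pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3", "rs4"],
                "chrom": "chr1",
                "pos": [100, 200, 400, 300],
            }
        )

    def test_lowest_p_snp_is_the_esnp(self):
        calls = eqtl.call_eqtls(self._results(), {"cis": 1e-4}, self._snps())
        assert len(calls) == 1
        assert calls.iloc[0]["snp_id"] == "rs1"

    def test_no_subcutoff_snp_no_call(self):
        res = self._results()
        calls = eqtl.call_eqtls(res[res["probeset_id"] == "p2"], {"cis": 1e-4}, self._snps())
        assert calls.empty

    def test_tie_broken_by_position(self):
        calls = eqtl.call_eqtls(self._results(), {"cis": 1e-2}, self._snps())
        p2 = calls[calls["probeset_id"] == "p2"]
        assert p2.iloc[0]["snp_id"] == "rs4"  # pos 300 < 400

    def test_at_most_one_cis_call_per_probeset(self, small_results):
        cis = small_results.calls[small_results.calls["class"] == "cis"]
        grouped = cis.groupby(["cohort", "probeset_id"]).size()
        assert (grouped == 1).all()
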