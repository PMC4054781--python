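"""Unit tests for the differential-methylation stage."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ocmeth import diffmeth
from ocmeth.diffmeth import (
    BETA_EPS,
    annotate_dmps,
    beta_to_m,
    bh_fdr,
    call_dmps,
    concordance,
    iqr_filter,
    m_to_beta,
    paired_moderated_t,
    quantile_normalize,
    set_enrichment,
)

from ._oracles import ebayes_oracle, ols_oracle


class TestBetaToM:
    @pytest.mark.parametrize(
        "beta,expected",
        [
            (0.5, 0.0),
            (0.8, 2.0),  # log2(0.8/0.2) = log2(4)
            (1.0, np.log2(0.999 / 0.001)),  # clamped at 1 - eps
            (0.0, np.log2(0.001 / 0.999)),
        ],
    )
    def test_known_values(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            beta_to_m(-0.1)
        with pytest.raises(ValueError):
            beta_to_m(1.2)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=BETA_EPS, max_value=1 - BETA_EPS))
    def test_roundtrip_identity_on_clamped_interval(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, rel=1e-12)

    def test_monotone(self, rng):
        b = np.sort(rng.uniform(0.001, 0.999, 100))
        m = beta_to_m(b)
        assert np.all(np.diff(m) >= 0)


class TestQuantileNormalize:
    def test_two_column_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_tie_rule_mean_of_reference(self):
        # column [1,1,2] ties at ranks 1,2: each gets (r1+r2)/2
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [10.0, 20.0, 30.0]})
        ref = (np.sort(df["a"]) + np.sort(df["b"])) / 2  # [5.5, 10.5, 16.0]
        out = quantile_normalize(df)
        tied = (ref[0] + ref[1]) / 2
        assert out["a"].tolist() == [tied, tied, ref[2]]

    def test_sorted_columns_identical_property(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_rejects_missing(self):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(df)

    def test_single_row(self):
        df = pd.DataFrame({"a": [1.0], "b": [3.0]})
        out = quantile_normalize(df)
        assert out.iloc[0].tolist() == [2.0, 2.0]


class TestIqrFilter:
    def test_median_threshold_keeps_upper_half(self):
        # IQRs 0.1 .. 0.4; median (linear interpolation) = 0.25; keep >=
        rows = []
        for iqr in (0.1, 0.2, 0.3, 0.4):
            rows.append([0.0, iqr / 2, iqr, 3 * iqr / 2, 2 * iqr])
        df = pd.DataFrame(rows, index=list("wxyz"), columns=list("abcde"))
        kept = iqr_filter(df, 0.5)
        assert list(kept) == ["y", "z"]

    def test_threshold_zero_keeps_all(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        assert len(iqr_filter(df, 0.0)) == 10

    def test_equal_iqrs_all_kept(self):
        df = pd.DataFrame([[0.0, 1.0, 2.0]] * 5)
        assert len(iqr_filter(df, 0.9)) == 5

    def test_threshold_out_of_range(self):
        df = pd.DataFrame([[0.0, 1.0]])
        with pytest.raises(ValueError):
            iqr_filter(df, 1.5)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03]).tolist() == [0.03]

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _paired_matrix(diffs, design):
    """Build an M matrix whose paired OC-MO differences equal `diffs`."""
    n_pairs = diffs.shape[1]
    cols = {}
    for i in range(n_pairs):
        cols[f"MO_D{i+1}"] = np.zeros(diffs.shape[0])
        cols[f"OC_D{i+1}"] = diffs[:, i]
    return pd.DataFrame(cols, index=[f"p{i}" for i in range(diffs.shape[0])])


class TestPairedModeratedT:
    def test_prior_df_zero_equals_classical_paired_t(self, rng, paired_design):
        diffs = rng.normal(0.2, 1.0, size=(50, 4))
        m = _paired_matrix(diffs, None)
        res = paired_moderated_t(m, paired_design(4), prior_df=0)
        t_cl, p_cl = sps.ttest_rel(
            m[[f"OC_D{i+1}" for i in range(4)]], m[[f"MO_D{i+1}" for i in range(4)]],
            axis=1,
        )
        np.testing.assert_allclose(res.t, t_cl, rtol=1e-9)
        np.testing.assert_allclose(res.p, p_cl, rtol=1e-9)

    def test_zero_variance_probe_gets_finite_positive_t(self, paired_design):
        diffs = np.vstack(
            [np.array([[1.0, 1.0, 1.0]]), np.random.default_rng(5).normal(size=(30, 3))]
        )
        m = _paired_matrix(diffs, None)
        res = paired_moderated_t(m, paired_design(3))
        assert np.isfinite(res.t[0]) and res.t[0] > 0

    def test_matches_formula_oracle(self, rng, paired_design):
        diffs = rng.normal(0.0, 1.0, size=(50, 5)) + rng.normal(
            0, 0.5, size=(50, 1)
        )
        m = _paired_matrix(diffs, None)
        res = paired_moderated_t(m, paired_design(5))
        oracle = ebayes_oracle(diffs)
        assert res.prior_df == pytest.approx(oracle["d0"], rel=1e-8)
        assert res.prior_var == pytest.approx(oracle["s0"], rel=1e-8)
        np.testing.assert_allclose(res.t, oracle["t"], rtol=1e-8)
        np.testing.assert_allclose(res.p, oracle["p"], rtol=1e-8)

    def test_posterior_variance_identity(self, rng, paired_design):
        diffs = rng.normal(size=(40, 4))
        res = paired_moderated_t(_paired_matrix(diffs, None), paired_design(4))
        d0, d = res.prior_df, res.df_residual
        expected = (d0 * res.prior_var + d * res.s2) / (d0 + d)
        np.testing.assert_allclose(res.post_var, expected, rtol=1e-12)

    def test_requires_two_pairs(self, paired_design):
        m = _paired_matrix(np.ones((5, 1)), None)
        with pytest.raises(ValueError):
            paired_moderated_t(m, paired_design(1))

    def test_all_zero_variances_error(self, paired_design):
        m = _paired_matrix(np.ones((5, 3)), None)
        with pytest.raises(ValueError, match="variance"):
            paired_moderated_t(m, paired_design(3))

    def test_matches_limma_reference(self, rng, paired_design, tmp_path):
        """Cross-check d0, s0^2, t and p against Bioconductor limma."""
        diffs = rng.normal(0.1, 1.2, size=(40, 4))
        m = _paired_matrix(diffs, None)
        res = paired_moderated_t(m, paired_design(4))
        data = tmp_path / "diffs.tsv"
        np.savetxt(data, diffs, delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(limma))
                args <- commandArgs(trailingOnly=TRUE)
                x <- as.matrix(read.table(args[1], sep="\\t"))
                fit <- eBayes(lmFit(x, matrix(1, ncol(x), 1)))
                out <- cbind(fit$t[,1], fit$p.value[,1])
                cat(fit$df.prior, fit$s2.prior, "\\n")
                write.table(out, args[2], sep="\\t", row.names=FALSE, col.names=FALSE)
                """
            )
        )
        out = tmp_path / "out.tsv"
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(data), str(out)],
            capture_output=True, text=True, timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        d0, s0 = map(float, proc.stdout.split())
        ref = np.loadtxt(out, delimiter="\t")
        assert res.prior_df == pytest.approx(d0, rel=1e-6)
        assert res.prior_var == pytest.approx(s0, rel=1e-6)
        np.testing.assert_allclose(res.t, ref[:, 0], rtol=1e-6)
        np.testing.assert_allclose(res.p, ref[:, 1], rtol=1e-6)


class TestCallDmps:
    def _stats(self, probes, p, q):
        n = len(probes)
        return diffmeth.ModeratedStats(
            probe_ids=pd.Index(probes), mean_diff=np.zeros(n), s2=np.ones(n),
            df_residual=2, prior_df=2.0, prior_var=1.0, post_var=np.ones(n),
            t=np.zeros(n), p=np.asarray(p, float), q=np.asarray(q, float),
        )

    def _beta(self, probes, mo, oc, design):
        cols = {}
        for _, row in design.iterrows():
            cols[row["sample"]] = mo if row["condition"] == "MO" else oc
        return pd.DataFrame(cols, index=pd.Index(probes))

    def test_hyper_call_with_fc3(self, paired_design):
        design = paired_design(3)
        beta = self._beta(["p1"], np.array([0.2]), np.array([0.6]), design)
        out = call_dmps(beta, design, self._stats(["p1"], [0.001], [0.01]))
        assert len(out) == 1
        assert out.loc[0, "direction"] == "hyper"
        assert out.loc[0, "FC"] == pytest.approx(3.0)

    def test_small_fc_not_called(self, paired_design):
        design = paired_design(3)
        beta = self._beta(["p1"], np.array([0.4]), np.array([0.5]), design)
        out = call_dmps(beta, design, self._stats(["p1"], [1e-6], [1e-6]))
        assert len(out) == 0

    def test_fc_boundary_inclusive(self, paired_design):
        design = paired_design(3)
        beta = self._beta(["p1"], np.array([0.6]), np.array([0.3]), design)
        out = call_dmps(beta, design, self._stats(["p1"], [0.001], [0.01]))
        assert out.loc[0, "direction"] == "hypo"
        assert out.loc[0, "FC"] == pytest.approx(0.5)
        strict = call_dmps(
            beta, design, self._stats(["p1"], [0.001], [0.01]), inclusive=False
        )
        assert len(strict) == 0

    def test_requires_both_p_and_q(self, paired_design):
        design = paired_design(3)
        beta = self._beta(["p1"], np.array([0.2]), np.array([0.6]), design)
        out = call_dmps(beta, design, self._stats(["p1"], [0.001], [0.2]))
        assert len(out) == 0

    def test_order_invariance(self, small_meth):
        from ocmeth.diffmeth import dmp_workflow

        beta = small_meth.beta
        dmps1, _, _ = dmp_workflow(beta, small_meth.design)
        perm = np.random.default_rng(3).permutation(len(beta))
        dmps2, _, _ = dmp_workflow(beta.iloc[perm], small_meth.design)
        pd.testing.assert_frame_equal(dmps1, dmps2)


class TestAnnotate:
    MANIFEST = pd.DataFrame(
        {
            "probe": ["p1", "p2", "p3"],
            "chrom": ["chr1"] * 3,
            "pos": [100, 200, 300],
            "gene": ["GENEA", "", "GENEA;GENEB"],
            "region": ["TSS200", "", "Body;TSS200"],
        }
    )

    def _dmps(self, probes, directions):
        return pd.DataFrame(
            {
                "probe": probes,
                "direction": directions,
                "delta_beta": [0.2] * len(probes),
            }
        )

    def test_tss200_is_promoter(self):
        annotated, fractions, _ = annotate_dmps(self._dmps(["p1"], ["hypo"]), self.MANIFEST)
        assert annotated.loc[0, "category"] == "promoter"
        assert fractions.loc["hypo", "promoter"] == 1.0

    def test_no_gene_is_intergenic(self):
        annotated, _, gene_sets = annotate_dmps(self._dmps(["p2"], ["hyper"]), self.MANIFEST)
        assert annotated.loc[0, "category"] == "intergenic"
        assert gene_sets["hyper"] == set()

    def test_promoter_precedence_and_both_genes_recorded(self):
        annotated, _, gene_sets = annotate_dmps(self._dmps(["p3"], ["hypo"]), self.MANIFEST)
        assert annotated.loc[0, "category"] == "promoter"
        assert gene_sets["hypo"] == {"GENEA", "GENEB"}

    def test_unknown_probe_errors(self):
        with pytest.raises(KeyError):
            annotate_dmps(self._dmps(["nope"], ["hypo"]), self.MANIFEST)


class TestSetEnrichment:
    def test_query_equals_set_is_significant(self):
        universe = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(10)}
        res = set_enrichment(target, {"T": target}, universe)
        assert res.loc[0, "p"] < 1e-6

    def test_disjoint_query_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        res = set_enrichment({"g0", "g1"}, {"T": {"g10", "g11"}}, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_tail(self):
        # 2x2: 5 in both, 5 query-only, 5 set-only, 85 neither
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(10)}
        members = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        res = set_enrichment(query, {"T": members}, universe)
        expected = sum(
            sps.hypergeom.pmf(k, 100, 10, 10) for k in range(5, 11)
        )
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            set_enrichment(set(), {"T": set()}, set())


class TestConcordance:
    def test_perfect_agreement(self):
        beta = np.array([0.1, 0.5, 0.9, 0.3])
        r2, slope, intercept = concordance(beta, 100 * beta)
        assert (r2, slope) == pytest.approx((1.0, 1.0))
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_anticorrelation(self):
        beta = np.array([0.1, 0.5, 0.9])
        r2, slope, _ = concordance(beta, 100 * (1 - beta))
        assert (r2, slope) == pytest.approx((1.0, -1.0))

    def test_matches_closed_form_ols(self, rng):
        beta = rng.uniform(0, 1, 20)
        pyro = 100 * (0.9 * beta + 0.05) + rng.normal(0, 2, 20)
        r2, slope, intercept = concordance(beta, pyro)
        o_slope, o_intercept, o_r2 = ols_oracle(100 * beta, pyro)
        assert slope == pytest.approx(o_slope, abs=1e-10)
        assert intercept == pytest.approx(o_intercept, abs=1e-10)
        assert r2 == pytest.approx(o_r2, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            concordance([0.5, 0.5, 0.5], [50.0, 51.0, 52.0])
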