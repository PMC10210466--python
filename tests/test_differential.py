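"""Variance-prior estimation, moderated t-tests and BH control."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from evflux import (AbundanceMatrix, SyntheticProteomeSpec, VariancePrior,
                    bh_adjust, fit_variance_prior, generate_abundance_matrix,
                    log2_normalize, moderated_ttest, summarize_calls,
                    volcano_table)
from evflux.differential import ModeratedTTest, trigamma_inverse


def _log2_matrix(values, conditions):
    values = np.asarray(values, dtype=float)
    samples = [f"{c}_{i}" for i, c in enumerate(conditions)]
    ids = [f"P{i}" for i in range(values.shape[0])]
    return AbundanceMatrix(
        intensities=pd.DataFrame(values, index=ids, columns=samples),
        peptide_counts=pd.Series(2, index=ids),
        design=pd.Series(list(conditions), index=samples),
        control="CTR", scale="log2")


def test_trigamma_inverse_round_trip():
    for y in (0.05, 0.5, 2.0, 10.0, 200.0):
        x = float(special.polygamma(1, y))
        assert trigamma_inverse(x) == pytest.approx(y, rel=1e-8)


class TestVariancePriorFit:
    def test_identical_variances_give_infinite_prior(self, rng):
        base = rng.normal(20, 2, 40)
        noise = np.array([0.5, -0.5])
        vals = np.column_stack([base + noise[0], base + noise[1],
                                base + 2 + noise[0], base + 2 + noise[1]])
        m = _log2_matrix(vals, ("CTR", "CTR", "T1", "T1"))
        prior = fit_variance_prior(m)
        assert np.isinf(prior.df)
        # every protein's pooled variance is exactly 0.5 here
        assert prior.var == pytest.approx(0.5, rel=1e-10)

    def test_parameter_recovery_from_generator(self):
        spec = SyntheticProteomeSpec(n_proteins=2000, prior_df=4.0,
                                     prior_var=0.0625, de_fraction=0.0,
                                     missing_midpoint=None, seed=11)
        matrix, _ = generate_abundance_matrix(spec)
        prior = fit_variance_prior(log2_normalize(matrix))
        assert 2.8 <= prior.df <= 5.2
        assert prior.var == pytest.approx(0.0625, rel=0.20)

    def test_heterogeneous_variances_give_finite_positive_df(self, rng):
        scales = 10.0 ** rng.uniform(-3, 3, 10)
        vals = rng.normal(0, 1, (10, 6)) * scales[:, None] + 20
        m = _log2_matrix(vals, ("CTR",) * 3 + ("T1",) * 3)
        prior = fit_variance_prior(m)
        assert np.isfinite(prior.df)
        assert prior.df > 0 and prior.var > 0

    def test_too_few_proteins_rejected(self, rng):
        m = _log2_matrix(rng.normal(20, 1, (5, 4)), ("CTR", "CTR", "T1", "T1"))
        with pytest.raises(ValueError):
            fit_variance_prior(m)


class TestModeratedTTest:
    def _fixed_data(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(20, 1, (60, 6))
        vals[:10, 3:] += 2.0
        return _log2_matrix(vals, ("CTR",) * 3 + ("T1",) * 3)

    def test_equal_group_means_give_zero_t_unit_p(self):
        vals = np.array([[10.0, 11.0, 10.0, 11.0]])
        m = _log2_matrix(vals, ("CTR", "CTR", "T1", "T1"))
        res = moderated_ttest(m, prior=VariancePrior(df=4.0, var=0.25))
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "pvalue"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_prior_df_equals_classical_pooled_ttest(self):
        m = self._fixed_data()
        est = ModeratedTTest(control="CTR", prior=None, prior_df=0.0)
        est.fit(m)
        res = est.results_
        vals = m.intensities.to_numpy()
        for g in range(vals.shape[0]):
            t, p = stats.ttest_ind(vals[g, 3:], vals[g, :3], equal_var=True)
            assert res.loc[g, "t"] == pytest.approx(t, rel=1e-10)
            assert res.loc[g, "pvalue"] == pytest.approx(p, rel=1e-10)

    def test_infinite_prior_df_equals_fixed_variance_z_form(self):
        m = self._fixed_data()
        s0sq = 0.8
        res = moderated_ttest(m, prior=VariancePrior(df=np.inf, var=s0sq))
        vals = m.intensities.to_numpy()
        delta = vals[:, 3:].mean(axis=1) - vals[:, :3].mean(axis=1)
        z = delta / np.sqrt(s0sq * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res["t"].to_numpy(), z, rtol=1e-12)
        np.testing.assert_allclose(res["pvalue"].to_numpy(),
                                   2 * stats.norm.sf(np.abs(z)), rtol=1e-10)

    def test_continuity_in_prior_df_at_both_limits(self):
        m = self._fixed_data()
        lo = moderated_ttest(m, prior=VariancePrior(df=1e-9, var=0.5))
        classical = ModeratedTTest(control="CTR", prior=None, prior_df=0.0)
        classical.fit(m)
        np.testing.assert_allclose(lo["t"], classical.results_["t"], rtol=1e-6)
        hi = moderated_ttest(m, prior=VariancePrior(df=1e12, var=0.5))
        z = moderated_ttest(m, prior=VariancePrior(df=np.inf, var=0.5))
        np.testing.assert_allclose(hi["t"], z["t"], rtol=1e-6)

    def test_matches_limma_on_fixed_data(self, tmp_path):
        """Independent oracle: the reference R implementation of the
        empirical-Bayes moderated t-test, run on the same matrix."""
        spec = SyntheticProteomeSpec(n_proteins=120, missing_midpoint=None,
                                     seed=7)
        matrix, _ = generate_abundance_matrix(spec)
        m = log2_normalize(matrix)
        m.intensities.to_csv(tmp_path / "mat.tsv", sep="\t")
        res = moderated_ttest(m)
        script = textwrap.dedent("""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("mat.tsv", row.names=1, check.names=FALSE))
            group <- factor(sub("_[0-9]+$", "", colnames(x)), levels=c("CTR","T1"))
            design <- model.matrix(~0+group)
            colnames(design) <- levels(group)
            fit <- eBayes(contrasts.fit(lmFit(x, design),
                                        makeContrasts(T1-CTR, levels=design)))
            out <- data.frame(protein_id=rownames(x),
                              logFC=fit$coefficients[,1], t=fit$t[,1],
                              p=fit$p.value[,1], d0=fit$df.prior,
                              s0sq=fit$s2.prior)
            write.table(out, "limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        np.testing.assert_allclose(res["log2fc"], ref["logFC"], rtol=1e-8)
        np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["pvalue"], ref["p"], rtol=1e-6)
        est = ModeratedTTest(control="CTR").fit(m)
        assert est.prior_df_ == pytest.approx(ref["d0"][0], rel=1e-4)
        assert est.prior_var_ == pytest.approx(ref["s0sq"][0], rel=1e-4)

    def test_missing_values_rejected(self):
        vals = np.array([[10.0, np.nan, 10.0, 11.0]])
        m = _log2_matrix(vals, ("CTR", "CTR", "T1", "T1"))
        with pytest.raises(ValueError, match="impute"):
            moderated_ttest(m, prior=VariancePrior(df=4.0, var=0.25))


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_reference_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj,
                                   stats.false_discovery_control(p, method="bh"),
                                   rtol=1e-12)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestVolcano:
    def test_empty_result(self):
        empty = pd.DataFrame(columns=["protein_id", "comparison", "log2fc",
                                      "t", "df_residual", "df_total",
                                      "pvalue", "adj_pvalue"])
        table = volcano_table(empty)
        assert len(table) == 0
        assert summarize_calls(table).empty

    def test_single_enriched_protein(self):
        res = pd.DataFrame([{"protein_id": "P0", "comparison": "T1-vs-CTR",
                             "log2fc": 2.0, "t": 5.0, "df_residual": 4.0,
                             "df_total": 8.0, "pvalue": 0.001,
                             "adj_pvalue": 0.01}])
        table = volcano_table(res, adj_p_cut=0.05, lfc_cut=1.0)
        assert table.loc[0, "call"] == "enriched"
        counts = summarize_calls(table)
        assert counts.loc["T1-vs-CTR", "enriched"] == 1
        assert counts.loc["T1-vs-CTR", "depleted"] == 0

    def test_sign_convention_treatment_minus_control(self):
        # protein higher in treatment must come out with positive log2fc
        vals = np.array([[10.0, 10.1, 9.9, 12.0, 12.1, 11.9]])
        m = _log2_matrix(vals, ("CTR",) * 3 + ("T1",) * 3)
        res = moderated_ttest(m, prior=VariancePrior(df=4.0, var=0.01))
        assert res.loc[0, "log2fc"] == pytest.approx(2.0, abs=0.2)
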