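"""Differential-expression pipeline and the ethylene-responsive caller."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from woodnet.containers import GENOTYPES
from woodnet.response import (
    bh_adjust,
    call_ethylene_responsive,
    filter_low_counts,
    fit_genewise_model,
    log_cpm,
    moderate_variances,
    normalization_factors,
    relative_expression,
    response_table,
)
from woodnet.simulate import CountSimConfig, default_count_config, generate_count_experiment

from .conftest import make_count_experiment


class TestLowCountFilter:
    def test_single_low_library_drops_gene(self):
        counts = np.full((3, 6), 50)
        counts[0, 2] = 9
        exp = make_count_experiment(counts)
        assert filter_low_counts(exp).genes == ["g2", "g3"]

    def test_boundary_value_kept(self):
        counts = np.full((2, 6), 10)
        exp = make_count_experiment(counts)
        assert filter_low_counts(exp).genes == ["g1", "g2"]

    def test_identity_when_all_pass(self):
        counts = np.full((4, 6), 100)
        exp = make_count_experiment(counts)
        pd.testing.assert_frame_equal(filter_low_counts(exp).counts, exp.counts)

    def test_alternative_any_library_mode(self):
        counts = np.zeros((2, 6), dtype=int)
        counts[0, 0] = 10
        exp = make_count_experiment(counts)
        assert filter_low_counts(exp, mode="any_library_passes").genes == ["g1"]


class TestNormalizationFactors:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(20, 2000, size=200)
        counts = np.tile(col[:, None], (1, 6))
        factors = normalization_factors(make_count_experiment(counts))
        assert np.allclose(factors, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # doubling every gene is depth, not composition: TMM factor stays 1
        rng = np.random.default_rng(1)
        col = rng.integers(20, 2000, size=500)
        counts = np.tile(col[:, None], (1, 6))
        counts[:, 3] = col * 2
        factors = normalization_factors(make_count_experiment(counts))
        assert np.allclose(factors, 1.0, atol=1e-12)

    def test_geometric_mean_is_one(self):
        exp, _ = generate_count_experiment(default_count_config(seed=2))
        factors = normalization_factors(filter_low_counts(exp))
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        exp, _ = generate_count_experiment(
            CountSimConfig(seed=3, n_genes=300, responder_genes=["G0005"],
                           responder_log2fc=2.0)
        )
        exp = filter_low_counts(exp)
        mine = normalization_factors(exp)
        counts_file = tmp_path / "counts.tsv"
        exp.counts.to_csv(counts_file, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f'x <- as.matrix(read.delim("{counts_file}", row.names=1))\n'
            'cat(sprintf("%.15g", calcNormFactors(x, method="TMM")), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        assert np.abs(mine.to_numpy() - reference).max() < 1e-10

    def test_all_zero_library_rejected(self):
        counts = np.full((3, 6), 50)
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            normalization_factors(make_count_experiment(counts))


class TestLogCpm:
    def test_one_gene_library_formula(self):
        counts = np.full((1, 6), 10**6)
        lc = log_cpm(make_count_experiment(counts))
        expect = np.log2((1e6 + 0.5) / (1e6 + 1.0) * 1e6)
        assert lc.iloc[0, 0] == pytest.approx(expect, abs=1e-9)

    def test_zero_counts_stay_finite(self):
        counts = np.zeros((2, 6), dtype=int)
        counts[1] = 100
        lc = log_cpm(make_count_experiment(counts))
        assert np.isfinite(lc.to_numpy()).all()

    def test_depth_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(10, 1000, size=(50, 6))
        a = log_cpm(make_count_experiment(counts))
        b = log_cpm(make_count_experiment(counts * 2))
        # the 0.5 prior count shifts low counts slightly under doubling
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.05


class TestGenewiseFit:
    def test_noiseless_planted_effect_recovered(self):
        base = np.full((1, 18), 8.0)
        lc = pd.DataFrame(
            base, index=pd.Index(["g1"], name="gene"),
            columns=make_count_experiment(np.zeros((1, 18), dtype=int), n_reps=3).libraries,
        )
        exp = make_count_experiment(np.zeros((1, 18), dtype=int), n_reps=3)
        wt_acc = (exp.library_meta["genotype"] == "WT") & (
            exp.library_meta["treatment"] == "ACC"
        )
        lc.loc["g1", wt_acc.to_numpy()] = 9.0
        fit = fit_genewise_model(lc, exp.library_meta)
        assert fit.log2fc.loc["g1", "WT"] == pytest.approx(1.0)
        assert fit.log2fc.loc["g1", "etr1_LMX5"] == pytest.approx(0.0)
        assert fit.s2["g1"] == pytest.approx(0.0, abs=1e-20)

    def test_balanced_design_estimates_cell_means_and_s2(self):
        rng = np.random.default_rng(3)
        exp = make_count_experiment(np.zeros((2, 18), dtype=int), n_reps=3)
        y = rng.normal(5, 1, size=(2, 18))
        lc = pd.DataFrame(y, index=pd.Index(["g1", "g2"], name="gene"),
                          columns=exp.libraries)
        fit = fit_genewise_model(lc, exp.library_meta)
        cell = exp.library_meta["genotype"] + ":" + exp.library_meta["treatment"]
        for gene in ("g1", "g2"):
            resid = []
            for c in cell.unique():
                vals = lc.loc[gene, (cell == c).to_numpy()]
                assert fit.coefficients.loc[gene, c] == pytest.approx(vals.mean())
                resid.extend(vals - vals.mean())
            # hand-computed residual variance on 18 - 6 df
            assert fit.s2[gene] == pytest.approx(np.sum(np.square(resid)) / 12)
        assert fit.df == 12

    def test_empty_cell_rejected(self):
        exp = make_count_experiment(np.zeros((1, 18), dtype=int), n_reps=3)
        lc = pd.DataFrame(np.zeros((1, 18)), index=pd.Index(["g1"], name="gene"),
                          columns=exp.libraries)
        meta = exp.library_meta.copy()
        meta.loc[meta["genotype"] == "WT", "treatment"] = "mock"
        with pytest.raises(ValueError, match="empty design cell"):
            fit_genewise_model(lc, meta)


class TestModeration:
    def test_identical_variances_unchanged(self):
        mod = moderate_variances(pd.Series(np.full(50, 3.0)), df=10)
        assert mod.d0 >= 1e8
        assert np.allclose(mod.s2_post, 3.0)

    def test_prior_recovery_from_simulation(self):
        rng = np.random.default_rng(7)
        d0, s02, d, n = 4.0, 2.0, 10, 5000
        sigma2 = s02 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        mod = moderate_variances(pd.Series(s2), df=d)
        assert mod.d0 == pytest.approx(d0, rel=0.2)
        assert mod.s02 == pytest.approx(s02, rel=0.2)

    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(8)
        s2 = pd.Series(rng.chisquare(5, 100))
        mod = moderate_variances(s2, df=5, prior_df=0)
        assert np.allclose(mod.s2_post, s2)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            moderate_variances(pd.Series([0.0, 0.0]), df=3)

    def test_moderated_t_matches_limma_ebayes(self, tmp_path):
        # heteroscedastic normal data with a genuine inverse-chi-square
        # variance prior; compare d0, s0^2, t and p against limma
        rng = np.random.default_rng(11)
        exp = make_count_experiment(np.zeros((1, 18), dtype=int), n_reps=3)
        n, d0, s02 = 400, 4.0, 0.25
        sigma2 = s02 * d0 / rng.chisquare(d0, n)
        y = 5.0 + rng.normal(size=(n, 18)) * np.sqrt(sigma2)[:, None]
        lc = pd.DataFrame(y, index=pd.Index([f"G{i:04d}" for i in range(n)], name="gene"),
                          columns=exp.libraries)
        fit = fit_genewise_model(lc, exp.library_meta)
        mod = moderate_variances(fit.s2, fit.df)
        tstat = fit.log2fc["WT"] / (np.sqrt(mod.s2_post) * fit.se_unit["WT"])
        pval = 2 * t_dist.sf(np.abs(tstat), mod.d0 + fit.df)

        lc_file, meta_file = tmp_path / "lc.tsv", tmp_path / "meta.tsv"
        lc.to_csv(lc_file, sep="\t")
        exp.library_meta.to_csv(meta_file, sep="\t")
        script = tmp_path / "ebayes.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.delim("{lc_file}", row.names=1))
m <- read.delim("{meta_file}", row.names=1)
cell <- factor(paste(m$genotype, m$treatment, sep="."))
design <- model.matrix(~0+cell)
fit <- lmFit(y, design)
ct <- makeContrasts(cellWT.ACC - cellWT.mock, levels=design)
f <- eBayes(contrasts.fit(fit, ct))
cat(f$df.prior, f$s2.prior, "\\n")
write.csv(data.frame(t=f$t[,1], p=f$p.value[,1]), "{tmp_path}/limma.csv")
""")
        subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        with open(tmp_path / "limma.csv") as fh:
            ref = pd.read_csv(fh, index_col=0)
        assert np.abs(tstat.to_numpy() - ref["t"].to_numpy()).max() < 1e-8
        assert np.abs(pval - ref["p"].to_numpy()).max() < 1e-8


class TestBH:
    def test_stepup_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_order_preserved(self):
        rng = np.random.default_rng(4)
        p = rng.random(200)
        q = bh_adjust(p)
        assert (np.argsort(p) == np.argsort(q, kind="stable")).all() or (
            np.diff(q[np.argsort(p)]) >= -1e-15
        ).all()
        assert (q >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestResponsiveCaller:
    def _table(self, wt, lmx5, s35, q=0.001):
        return pd.DataFrame(
            {
                "log2fc_WT": [wt],
                "log2fc_etr1_LMX5": [lmx5],
                "log2fc_etr1_35S": [s35],
                "q_WT": [q],
            },
            index=pd.Index(["g"], name="gene"),
        )

    def test_wt_specific_induction_is_responsive(self):
        assert call_ethylene_responsive(self._table(2.0, 0.0, 0.0)).all()

    def test_shared_induction_is_not_responsive(self):
        # same response in the ethylene-insensitive lines: not specific
        assert not call_ethylene_responsive(self._table(2.0, 2.0, 2.0)).any()

    def test_sub_twofold_not_responsive(self):
        assert not call_ethylene_responsive(self._table(0.5, 0.0, 0.0)).any()

    def test_q_threshold_applies(self):
        assert not call_ethylene_responsive(self._table(2.0, 0.0, 0.0, q=0.02)).any()

    def test_one_insensitive_line_responding_disqualifies(self):
        assert not call_ethylene_responsive(self._table(2.0, 1.5, 0.0)).any()

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError, match="lacks column"):
            call_ethylene_responsive(pd.DataFrame({"log2fc_WT": [1.0]}))


class TestPipeline:
    def test_deterministic(self):
        exp, _ = generate_count_experiment(default_count_config(seed=5))
        a = response_table(exp)
        b = response_table(exp)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_responders_called(self):
        exp, truth = generate_count_experiment(default_count_config(seed=6))
        table = response_table(exp)
        called = set(table.index[table["responsive"]])
        planted = set(truth["responders"])
        assert len(called & planted) / len(planted) >= 0.8
        assert len(called - planted) / max(1, len(called)) <= 0.05

    def test_q_dominates_p(self):
        exp, _ = generate_count_experiment(default_count_config(seed=7))
        table = response_table(exp)
        for g in GENOTYPES:
            assert (table[f"q_{g}"] >= table[f"p_{g}"] - 1e-15).all()


def test_relative_expression_formula():
    assert relative_expression(20.0, 20.0) == 1.0
    assert relative_expression(21.0, 20.0) == 0.5
    assert relative_expression(18.0, 20.0) == 4.0
    with pytest.raises(ValueError):
        relative_expression(float("nan"), 20.0)
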