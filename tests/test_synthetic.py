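"""The synthetic generator: determinism, planted classes and planted structure."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ctdbalance.genes import genes_to_frame
from ctdbalance.synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_genes,
    generate_tags,
    latent_mark_table,
)


@pytest.fixture(scope="module")
def active_only_config():
    return SyntheticConfig(n_active=500, n_prcr=0, n_inactive=0, seed=7)


@pytest.fixture(scope="module")
def active_only_latents(active_only_config):
    genes = generate_genes(active_only_config)
    return latent_mark_table(genes, active_only_config)


class TestConfig:
    def test_zero_counts_empty_genome(self):
        cfg = SyntheticConfig(n_active=0, n_prcr=0, n_inactive=0)
        assert generate_genes(cfg) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_active=-1)

    def test_positive_methylation_path_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(sem_coefficients={"a": 0.4, "b": 0.4, "c": 0.2, "d": 0.1})

    def test_unknown_mark_in_profiles_rejected(self):
        from ctdbalance.synthetic import DEFAULT_PROFILE_PARAMS

        bad = dict(DEFAULT_PROFILE_PARAMS)
        bad["H3K9me3"] = {"shape": "gaussian", "center": 0, "spread": 100}
        with pytest.raises(ValueError, match="unknown mark"):
            SyntheticConfig(profile_params=bad)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="cannot place"):
            generate_genes(SyntheticConfig(n_active=5000, chrom_length=1_000_000))


class TestGenes:
    def test_seeded_determinism(self):
        cfg = SyntheticConfig(n_active=200, n_prcr=0, n_inactive=0, seed=1)
        g1 = genes_to_frame(generate_genes(cfg))
        g2 = genes_to_frame(generate_genes(SyntheticConfig(n_active=200, n_prcr=0, n_inactive=0, seed=1)))
        pd.testing.assert_frame_equal(g1, g2)

    def test_class_counts_and_silent_inactive(self):
        cfg = SyntheticConfig(n_active=200, n_prcr=0, n_inactive=100, seed=3)
        df = genes_to_frame(generate_genes(cfg))
        assert len(df) == 300
        assert (df["true_class"] == "inactive").sum() == 100
        assert (df.loc[df["true_class"] == "inactive", "fpkm"] == 0).all()
        assert (df.loc[df["true_class"] == "active", "fpkm"] > 0).all()

    def test_promoters_do_not_overlap(self):
        df = genes_to_frame(generate_genes(SyntheticConfig(seed=2))).sort_values("tss")
        tss = df["tss"].to_numpy()
        assert (np.diff(tss) >= 2000).all()


class TestTags:
    def test_null_signal(self):
        cfg = SyntheticConfig(
            n_active=0, n_prcr=0, n_inactive=0, background_rate=0.0, seed=0
        )
        tags = generate_tags([], cfg)
        assert all(len(ts) == 0 for ts in tags.values())

    def test_depth_within_poisson_error(self, small_config, small_run):
        _, tags = small_run
        for mark in ("S5p", "K7me2", "S2p"):
            n = len(tags[mark])
            mu = small_config.depth_per_mark
            assert abs(n - mu) < 5 * np.sqrt(mu)

    def test_mock_is_background_only(self, small_config, small_run):
        genes, tags = small_run
        mock = tags["mock"]
        expected = small_config.background_rate * small_config.chrom_length
        assert abs(len(mock) - expected) < 5 * np.sqrt(expected)
        # uniform: no promoter concentration
        hist, _ = np.histogram(mock.positions, bins=20)
        assert hist.max() < 2 * hist.mean()

    def test_run_log_conservation(self, small_config):
        genes = generate_genes(small_config)
        log = {}
        tags = generate_tags(genes, small_config, run_log=log)
        for mark, ts in tags.items():
            assert len(ts) == log[f"tags.{mark}.signal"] + log[f"tags.{mark}.background"]

    def test_prcr_genes_lack_elongation_marks(self, small_config, small_run):
        genes, tags = small_run
        prcr = [g for g in genes if g.true_class == "PRCr"]
        for mark in ("S7p", "S2p", "8WG16"):
            pos = tags[mark].positions
            near = sum(
                ((pos >= g.tss - 1000) & (pos < g.tss + 1000)).sum() for g in prcr
            )
            background = small_config.background_rate * 2000 * len(prcr)
            assert near < 3 * background + 20

    def test_k7me2_concentrates_at_tss(self, small_run):
        genes, tags = small_run
        active = [g for g in genes if g.true_class == "active"]
        pos = tags["K7me2"].positions
        near = sum(((pos >= g.tss - 200) & (pos < g.tss + 200)).sum() for g in active)
        assert near > 0.5 * len(pos)


class TestPlantedStructure:
    def test_promoter_marks_positively_correlated(self, active_only_latents):
        lat = active_only_latents
        marks = ["S5p", "S7p", "8WG16", "K7me1", "K7me2"]
        corr = lat[marks].corr(method="spearman")
        off_diag = corr.to_numpy()[np.triu_indices(5, k=1)]
        assert (off_diag > 0).all()

    def test_k7me2_s5p_marginal_correlation(self, active_only_latents):
        rho = stats.spearmanr(
            active_only_latents["K7me2"], active_only_latents["S5p"]
        ).statistic
        assert rho > 0.5

    def test_negative_partial_given_initiation_marks(self, active_only_latents):
        # residual-regression oracle on the latent masses
        lat = active_only_latents
        Z = sm.add_constant(lat[["S7p", "S5p", "K7ac"]].rank())
        rx = lat["K7me2"].rank() - Z @ np.linalg.lstsq(Z, lat["K7me2"].rank(), rcond=None)[0]
        ry = lat["S2p"].rank() - Z @ np.linalg.lstsq(Z, lat["S2p"].rank(), rcond=None)[0]
        assert np.corrcoef(rx, ry)[0, 1] < 0

    def test_sem_coefficient_recovery_by_ols(self, active_only_config, active_only_latents):
        lat = active_only_latents
        X = sm.add_constant(lat[["S7p", "K7ac", "S5p", "K7me"]])
        fit = sm.OLS(lat["S2p"], X).fit()
        d_true = active_only_config.sem_coefficients["d"]
        assert abs(fit.params["K7me"] - d_true) < 3 * fit.bse["K7me"]
        assert fit.params["S7p"] > 0 and fit.params["K7ac"] > 0

    def test_me1_me2_high_correlation(self, active_only_latents):
        r = np.corrcoef(active_only_latents["K7me1"], active_only_latents["K7me2"])[0, 1]
        assert r > 0.85


class TestExpression:
    def test_inactive_genes_silent(self, small_config):
        genes = generate_genes(small_config)
        fpkm, groseq, _ = generate_expression(genes, small_config)
        inactive = [g for g in genes if g.true_class == "inactive"]
        assert (fpkm.loc[[g.gene_id for g in inactive], "fpkm"] == 0).all()
        pos = groseq.positions
        body = sum(((pos >= g.start) & (pos < g.end)).sum() for g in inactive)
        assert body == 0

    def test_determinism(self, small_config):
        genes = generate_genes(small_config)
        f1, _, t1 = generate_expression(genes, small_config)
        f2, _, t2 = generate_expression(genes, small_config)
        pd.testing.assert_frame_equal(f1, f2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fpkm_tracks_elongation(self, active_only_config):
        genes = generate_genes(active_only_config)
        lat = latent_mark_table(genes, active_only_config)
        fpkm, _, _ = generate_expression(genes, active_only_config)
        rho = stats.spearmanr(fpkm["fpkm"], lat["S2p"]).statistic
        assert rho > 0.5

    def test_tsa_fold_change_tracks_planted_ratio(self, active_only_config):
        genes = generate_genes(active_only_config)
        lat = latent_mark_table(genes, active_only_config)
        _, _, tsa = generate_expression(genes, active_only_config)
        r = lat.loc[tsa.index, "K7me2"] - lat.loc[tsa.index, "K7ac"]
        rho = stats.spearmanr(np.log2(tsa["fold_change"]), r).statistic
        assert rho > 0.3
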