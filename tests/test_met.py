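"""Combined ANOVA, variance components, heritability, BLUEs, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcsel.met import (
    MetAnalyzer,
    VarianceComponents,
    anova_balanced,
    compute_blues,
    cv_percent,
    derive_ld_av,
    estimate_components,
    heritability,
    trait_correlations,
)
from pcsel.simulate import SimConfig, simulate_trial
from pcsel.trial_data import PhenotypeTable

from conftest import grid_table, gy_only_config


def sequential_ols_ss(d: pd.DataFrame, trait: str) -> dict[str, float]:
    """Independent oracle: incremental least-squares sums of squares.

    Terms added in the order mean, environment, rep-within-env, genotype,
    genotype x env, block; each SS is the drop in residual sum of squares,
    the residual is what remains.
    """
    y = d[trait].to_numpy(float)

    def dummies(cols):
        key = d[cols].astype(str).agg("|".join, axis=1)
        return pd.get_dummies(key).to_numpy(float)

    terms = {
        "environment": dummies(["environment"]),
        "rep_within_env": dummies(["environment", "replicate"]),
        "genotype": dummies(["genotype"]),
        "genotype_x_env": dummies(["genotype", "environment"]),
        "block_within_rep": dummies(["environment", "replicate", "block"]),
    }
    x = np.ones((len(d), 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    out = {}
    for name, cols in terms.items():
        x = np.hstack([x, cols])
        beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
        rss = float(((y - x @ beta) ** 2).sum())
        out[name] = rss_prev - rss
        rss_prev = rss
    out["residual"] = rss_prev
    return out


class TestAnovaBalanced:
    @pytest.mark.parametrize("n_blocks", [1, 2, 5])
    def test_matches_sequential_ols_oracle(self, n_blocks):
        rng = np.random.default_rng(17 + n_blocks)
        table = grid_table(10, 2, 2, n_blocks=n_blocks, rng=rng)
        anova = anova_balanced(table, "GY")
        oracle = sequential_ols_ss(table.data, "GY")
        for source, expected in oracle.items():
            got = anova.at[source, "ss"]
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-10), source

    def test_ss_and_df_totals(self):
        rng = np.random.default_rng(2)
        table = grid_table(12, 3, 2, n_blocks=3, rng=rng)
        anova = anova_balanced(table, "GY")
        y = table.data["GY"]
        assert anova["ss"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-12)
        assert anova["df"].sum() == len(y) - 1

    def test_pure_genotype_signal(self):
        # every observation equals its genotype mean -> all variation genotypic
        means = np.arange(6, dtype=float)
        values = np.tile(means, (2, 2, 1))
        table = grid_table(6, 2, 2, values=values)
        anova = anova_balanced(table, "GY")
        assert anova.at["residual", "ss"] == pytest.approx(0, abs=1e-12)
        assert anova.at["genotype_x_env", "ss"] == pytest.approx(0, abs=1e-12)
        assert anova.at["genotype", "ss"] == pytest.approx(((means - means.mean()) ** 2).sum() * 4)

    def test_constant_table_all_zero(self):
        table = grid_table(5, 2, 2, values=np.full((2, 2, 5), 3.3))
        anova = anova_balanced(table, "GY")
        assert np.allclose(anova["ss"], 0)

    def test_unbalanced_refused_with_remedy(self):
        table = grid_table(5, 2, 2)
        table.data.loc[0, "GY"] = np.nan
        with pytest.raises(ValueError, match="drop incomplete"):
            anova_balanced(table, "GY")

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        table = grid_table(8, 2, 2, n_blocks=2, rng=rng)
        shuffled = PhenotypeTable(
            data=table.data.sample(frac=1, random_state=1).reset_index(drop=True),
            traits=table.traits,
        )
        pd.testing.assert_frame_equal(
            anova_balanced(table, "GY"), anova_balanced(shuffled, "GY")
        )


class TestEstimateComponents:
    def test_equal_mean_squares_give_pure_residual(self):
        anova = pd.DataFrame(
            {"df": [1] * 6, "ss": [1.0] * 6, "ms": [1.0] * 6, "F": [np.nan] * 6},
            index=pd.Index(
                ["environment", "rep_within_env", "block_within_rep", "genotype",
                 "genotype_x_env", "residual"], name="source"),
        )
        vc = estimate_components(anova, e=4, r=2)
        assert (vc.sigma2_G, vc.sigma2_GE, vc.sigma2_e) == (0.0, 0.0, 1.0)

    def test_algebraic_inverse(self):
        ms_res, sge = 1.7, 0.72
        anova = pd.DataFrame(
            {"ms": {"genotype": ms_res + 2 * sge, "genotype_x_env": ms_res + 2 * sge,
                    "residual": ms_res}}
        )
        vc = estimate_components(anova, e=4, r=2)
        assert vc.sigma2_GE == pytest.approx(sge)
        assert vc.sigma2_e == pytest.approx(ms_res)
        assert vc.sigma2_G == 0.0

    def test_negative_solutions_truncated(self):
        anova = pd.DataFrame(
            {"ms": {"genotype": 0.1, "genotype_x_env": 1.0, "residual": 2.0}}
        )
        vc = estimate_components(anova, e=4, r=2)
        assert vc.sigma2_G == 0.0 and vc.sigma2_GE == 0.0

    def test_simulation_recovery_is_unbiased(self):
        # 120-seed check at trial scale; the heavier 200-seed run lives in
        # the acceptance suite
        est = []
        for s in range(120):
            table, _ = simulate_trial(gy_only_config(seed=s))
            vc = estimate_components(anova_balanced(table, "GY"), e=4, r=2)
            est.append([vc.sigma2_G, vc.sigma2_GE, vc.sigma2_e])
        est = np.array(est)
        mean, se = est.mean(0), est.std(0, ddof=1) / np.sqrt(len(est))
        for got, s, truth in zip(mean, se, (0.88, 0.72, 1.70)):
            assert abs(got - truth) <= 3 * s


class TestHeritability:
    @pytest.mark.parametrize(
        "vc, expected",
        [
            (VarianceComponents(0.88, 0.72, 1.70, 4, 2), 0.69),
            (VarianceComponents(0.04, 0.02, 0.18, 4, 2), 0.59),
        ],
    )
    def test_published_rows(self, vc, expected):
        assert round(heritability(vc), 2) == expected

    @pytest.mark.parametrize("c", [0.01, 1.0, 50.0])
    def test_pure_genotypic_variance_is_one(self, c):
        assert heritability(VarianceComponents(c, 0.0, 0.0, 4, 2)) == 1.0

    def test_all_zero_components(self):
        assert heritability(VarianceComponents(0.0, 0.0, 0.0, 4, 2)) == 0.0

    @given(
        sg=st.floats(0.01, 10), sge=st.floats(0, 10), se=st.floats(0, 10),
        delta=st.floats(0.01, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity(self, sg, sge, se, delta):
        base = heritability(VarianceComponents(sg, sge, se, 4, 2))
        assert heritability(VarianceComponents(sg + delta, sge, se, 4, 2)) >= base
        assert heritability(VarianceComponents(sg, sge + delta, se, 4, 2)) <= base
        assert heritability(VarianceComponents(sg, sge, se + delta, 4, 2)) <= base


class TestBlues:
    def test_simple_mean(self):
        values = np.array([4.0, 5.0, 6.0, 7.0]).reshape(2, 2, 1)
        table = grid_table(1, 2, 2, values=values)
        assert compute_blues(table, "GY").iloc[0] == pytest.approx(5.5)

    def test_constant_table(self):
        table = grid_table(4, 2, 2, values=np.full((2, 2, 4), 2.5))
        assert (compute_blues(table, "GY") == 2.5).all()

    def test_noise_free_blues_recover_genotype_effects(self):
        # with zero GE / residual / block variance the BLUE differences are
        # exactly the drawn genotype-effect differences
        cfg = SimConfig(
            n_genotypes=12, n_checks=0, n_environments=3, n_replicates=2,
            block_size=6, trait_names=["GY"], grand_means={"GY": 5.0},
            genetic_cov=pd.DataFrame([[0.9]], index=["GY"], columns=["GY"]),
            env_var={"GY": 1.0}, rep_var={"GY": 0.2}, seed=21,
        )
        table, truth = simulate_trial(cfg)
        blues = compute_blues(table, "GY")
        g = truth.genotype_effects["GY"]
        np.testing.assert_allclose(
            blues - blues.mean(), g - g.mean(), atol=1e-10
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        table = grid_table(6, 2, 2, rng=rng)
        shuffled = PhenotypeTable(
            data=table.data.sample(frac=1, random_state=0).reset_index(drop=True),
            traits=table.traits,
        )
        pd.testing.assert_series_equal(
            compute_blues(table, "GY"), compute_blues(shuffled, "GY")
        )


class TestCvAndLdAv:
    @pytest.mark.parametrize(
        "sigma_e2, mean, expected",
        [(1.0, 10.0, 10.0), (0.0, 5.0, 0.0), (1.70, 5.11, 25.5)],
    )
    def test_cv_percent(self, sigma_e2, mean, expected):
        vc = VarianceComponents(0.0, 0.0, sigma_e2, 4, 2)
        assert round(cv_percent(vc, mean), 1) == expected

    def test_cv_requires_positive_mean(self):
        with pytest.raises(ValueError):
            cv_percent(VarianceComponents(0, 0, 1, 4, 2), 0.0)

    def test_ld_av_published_means(self):
        df = pd.DataFrame({"LD1": [3.52], "LD2": [6.04], "LD3": [5.72]})
        assert round(derive_ld_av(df).iloc[0], 2) == 5.09

    def test_ld_av_unit_scores(self):
        df = pd.DataFrame({"LD1": [1.0], "LD2": [1.0], "LD3": [1.0]})
        assert derive_ld_av(df).iloc[0] == 1.0

    def test_ld_av_plot_vs_blue_route(self, default_trial):
        table, _ = default_trial
        plot_route = table.data.assign(LD_AV=derive_ld_av(table.data))
        plot_table = PhenotypeTable(data=plot_route, traits=table.traits)
        via_plots = compute_blues(plot_table, "LD_AV")
        via_blues = derive_ld_av(
            pd.DataFrame({t: compute_blues(table, t) for t in ("LD1", "LD2", "LD3")})
        )
        np.testing.assert_allclose(via_plots, via_blues, atol=1e-10)

    def test_ld_av_missing_component_rejected(self):
        with pytest.raises(KeyError, match="LD3"):
            derive_ld_av(pd.DataFrame({"LD1": [1.0], "LD2": [2.0]}))


class TestTraitCorrelations:
    def test_unit_diagonal_symmetric_psd(self, fitted_met):
        corr = trait_correlations(fitted_met.blues_)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        np.testing.assert_allclose(corr, corr.T)
        assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_independent_traits_uncorrelated(self):
        rng = np.random.default_rng(0)
        blues = pd.DataFrame(rng.standard_normal((10_000, 2)), columns=["a", "b"])
        assert abs(trait_correlations(blues).iloc[0, 1]) < 0.05

    def test_ld_block_strongly_correlated(self, fitted_met):
        corr = trait_correlations(fitted_met.blues_)
        ld = ["LD1", "LD2", "LD3"]
        off = corr.loc[ld, ld].to_numpy()[np.triu_indices(3, 1)]
        assert (off > 0.3).all() and (off < 0.95).all()

    def test_constant_column_named(self):
        blues = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="b"):
            trait_correlations(blues)


class TestMetAnalyzer:
    def test_fitted_surfaces(self, fitted_met):
        met = fitted_met
        assert set(met.results_) == {"LD1", "LD2", "LD3", "LD_AV", "ED", "ER", "GY"}
        assert met.blues_.shape == (192, 7)
        assert ((met.heritability_ >= 0) & (met.heritability_ <= 1)).all()
        assert (met.variance_components_[["sigma2_G", "sigma2_GE", "sigma2_e"]] >= 0).all().all()

    def test_per_trait_environment_count(self):
        cfg = gy_only_config(seed=1)
        cfg.trait_names = ["GY", "ER"]
        cfg.grand_means["ER"] = 8.14
        cfg.genetic_cov = pd.DataFrame(
            np.diag([0.88, 11.03]), index=["GY", "ER"], columns=["GY", "ER"]
        )
        cfg.ge_var["ER"] = 3.33
        cfg.resid_var["ER"] = 28.8
        cfg.trait_env_counts = {"ER": 3}
        table, _ = simulate_trial(cfg)
        met = MetAnalyzer(add_ld_av=False).fit(table)
        assert met.variance_components_.at["ER", "n_env"] == 3
        assert met.variance_components_.at["GY", "n_env"] == 4
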