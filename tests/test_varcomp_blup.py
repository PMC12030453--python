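import numpy as np
import pandas as pd
import pytest

from lignotrial.fiber_chemistry import composition_table
from lignotrial.synthetic_trial import SimulationConfig, generate_trial
from lignotrial.trial_data import plots_to_frame
from lignotrial.varcomp_blup import (
    ModelSpec,
    anova_moments_oracle,
    blup,
    design_matrices,
    fit_varcomp,
)

ONEWAY = ModelSpec(
    trait="y",
    include_environment=False,
    include_block=False,
    include_check_by_env=False,
    include_gxe=False,
)


def _oneway_frame(n_geno, reps, sigma_g, sigma_e, seed):
    rng = np.random.default_rng(seed)
    g_eff = rng.normal(0, sigma_g, n_geno)
    rows = []
    for i in range(n_geno):
        for _ in range(reps):
            rows.append({"genotype_id": f"G{i:02d}", "y": 10 + g_eff[i] + rng.normal(0, sigma_e)})
    return pd.DataFrame(rows)


def _twoway_frame(n_geno, reps, seed):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, 4.0, n_geno)
    e = {"IRRI": rng.normal(0, 2.0), "DRY": rng.normal(0, 2.0)}
    rows = []
    for i in range(n_geno):
        for env in ("IRRI", "DRY"):
            ge = rng.normal(0, 1.5)
            for _ in range(reps):
                rows.append(
                    {
                        "genotype_id": f"G{i:02d}",
                        "environment": env,
                        "y": 20 + g[i] + e[env] + ge + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestMomentsOracle:
    def test_hand_computed_mean_squares(self):
        # two genotypes, two reps: MS_G = 10, MS_within = 2
        a, b = np.sqrt(2.5), 1.0
        frame = pd.DataFrame(
            {
                "genotype_id": ["G1", "G1", "G2", "G2"],
                "y": [10 + a + b, 10 + a - b, 10 - a + b, 10 - a - b],
            }
        )
        vc = anova_moments_oracle(frame, "y")
        assert vc["genotype"] == pytest.approx((10 - 2) / 2)
        assert vc["residual"] == pytest.approx(2.0)

    def test_identical_observations_give_zero_components(self):
        frame = pd.DataFrame({"genotype_id": ["G1", "G1", "G2", "G2"], "y": [5.0] * 4})
        vc = anova_moments_oracle(frame, "y")
        assert vc["genotype"] == 0.0 and vc["residual"] == 0.0

    def test_refuses_unbalanced_layout(self):
        frame = pd.DataFrame({"genotype_id": ["G1", "G1", "G2"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="unbalanced"):
            anova_moments_oracle(frame, "y")


class TestEmReml:
    def test_matches_moments_oracle_on_balanced_oneway(self):
        frame = _oneway_frame(n_geno=10, reps=4, sigma_g=4.0, sigma_e=1.5, seed=21)
        oracle = anova_moments_oracle(frame, "y")
        assert oracle["genotype"] > 0  # interior estimate, REML == ANOVA
        vc = fit_varcomp(frame, ONEWAY, tol=1e-12, max_iter=50_000)
        assert vc.converged
        assert vc["genotype"] == pytest.approx(oracle["genotype"], abs=1e-6)
        assert vc["residual"] == pytest.approx(oracle["residual"], abs=1e-6)

    def test_matches_moments_oracle_on_balanced_twoway(self):
        frame = _twoway_frame(n_geno=12, reps=3, seed=8)
        frame["is_check"] = False
        frame["block"] = 1
        oracle = anova_moments_oracle(frame, "y", two_way=True)
        assert min(oracle.sigma2.values()) > 0  # interior: REML == ANOVA
        spec = ModelSpec(
            trait="y", include_block=False, include_check_by_env=False
        )
        vc = fit_varcomp(frame, spec, tol=1e-12, max_iter=50_000)
        for factor in ("environment", "genotype", "gxe", "residual"):
            assert vc[factor] == pytest.approx(oracle[factor], abs=1e-6), factor

    def test_matches_statsmodels_mixedlm_on_unbalanced_oneway(self):
        import statsmodels.formula.api as smf

        frame = _oneway_frame(n_geno=12, reps=3, sigma_g=3.0, sigma_e=1.0, seed=5)
        frame = frame.drop(index=[0, 7, 20]).reset_index(drop=True)  # unbalance it
        model = smf.mixedlm("y ~ 1", frame, groups=frame["genotype_id"])
        fit = model.fit(reml=True, method="lbfgs")
        vc = fit_varcomp(frame, ONEWAY, tol=1e-12, max_iter=50_000)
        assert vc["genotype"] == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-4)
        assert vc["residual"] == pytest.approx(float(fit.scale), rel=1e-4)

    def test_noiseless_simulation_drives_residual_to_zero(self):
        cfg = SimulationConfig(
            n_test_entries=8,
            n_checks=3,
            n_blocks_per_env=2,
            var_residual=0.0,
            seed=13,
        )
        plots, _ = generate_trial(cfg)
        frame = composition_table(plots_to_frame(plots))
        vc = fit_varcomp(frame, ModelSpec(trait="cellulose_pct"), tol=1e-8, max_iter=3000)
        assert vc["residual"] < 1e-4

    def test_loglik_monotone_and_components_nonnegative(self, small_trial):
        frame, _ = small_trial
        vc = fit_varcomp(frame, ModelSpec(trait="cellulose_pct"), tol=1e-6, max_iter=2000)
        trace = np.array(vc.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)
        assert all(v >= 0 for v in vc.sigma2.values())

    def test_row_permutation_leaves_estimates_unchanged(self, small_trial):
        # agreement is limited by the convergence tolerance: summation
        # order differs between row orders, so iterates stop at slightly
        # different points in the same fixed-point neighbourhood, and
        # components creeping to the zero boundary converge sublinearly
        frame, _ = small_trial
        spec = ModelSpec(trait="cellulose_pct")
        vc1 = fit_varcomp(frame, spec, tol=1e-10, max_iter=5000)
        shuffled = frame.sample(frac=1.0, random_state=99).reset_index(drop=True)
        vc2 = fit_varcomp(shuffled, spec, tol=1e-10, max_iter=5000)
        for factor, value in vc1.sigma2.items():
            assert vc2[factor] == pytest.approx(value, abs=1e-4)

    def test_nonconvergence_is_flagged_not_silent(self, small_trial):
        frame, _ = small_trial
        vc = fit_varcomp(frame, ModelSpec(trait="cellulose_pct"), tol=1e-12, max_iter=3)
        assert not vc.converged
        assert vc.n_iter == 3 and vc.final_change > 0

    def test_missing_responses_dropped_with_count(self, small_trial):
        frame, _ = small_trial
        frame = frame.copy()
        frame.loc[frame.index[:4], "cellulose_pct"] = np.nan
        vc = fit_varcomp(frame, ModelSpec(trait="cellulose_pct"), tol=1e-4, max_iter=500)
        assert vc.n_dropped == 4
        assert vc.n_obs == len(frame) - 4


class TestBlup:
    def test_agrees_with_dense_gls_solver_on_small_instance(self):
        # independent route: beta by GLS, u_i = sigma2_i Z_i' Vinv (y - X beta)
        frame = _twoway_frame(n_geno=4, reps=2, seed=3)
        frame["is_check"] = False
        frame["block"] = 1
        spec = ModelSpec(trait="y", include_block=False, include_check_by_env=False)
        sigma2 = {"environment": 2.0, "genotype": 5.0, "gxe": 1.0, "residual": 1.5}
        y, Zs, levels = design_matrices(frame, spec)
        n = y.size
        V = sigma2["residual"] * np.eye(n)
        for f, Z in Zs.items():
            V += sigma2[f] * Z @ Z.T
        Vinv = np.linalg.inv(V)
        ones = np.ones(n)
        mu = float(ones @ Vinv @ y) / float(ones @ Vinv @ ones)
        resid = y - mu
        u_g = sigma2["genotype"] * Zs["genotype"].T @ Vinv @ resid
        u_e = sigma2["environment"] * Zs["environment"].T @ Vinv @ resid
        u_ge = sigma2["gxe"] * Zs["gxe"].T @ Vinv @ resid

        table = blup(frame, spec, sigma2, scope="per_environment")
        assert table.grand_mean == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(table.overall.to_numpy(), mu + u_g, atol=1e-8)
        for j, env in enumerate(levels["environment"]):
            for i, g in enumerate(levels["genotype"]):
                k = list(levels["gxe"]).index(f"{g}:{env}")
                expected = mu + u_e[j] + u_g[i] + u_ge[k]
                assert table.by_env.loc[g, env] == pytest.approx(expected, abs=1e-8)

    def test_huge_genotype_variance_recovers_raw_means(self):
        frame = _oneway_frame(n_geno=6, reps=4, sigma_g=3.0, sigma_e=1.0, seed=17)
        table = blup(frame, ONEWAY, {"genotype": 1e8, "residual": 1.0})
        raw = frame.groupby("genotype_id")["y"].mean()
        np.testing.assert_allclose(
            table.overall.to_numpy(), raw.to_numpy(), atol=1e-4
        )

    def test_zero_genotype_variance_gives_full_shrinkage(self):
        frame = _oneway_frame(n_geno=6, reps=4, sigma_g=3.0, sigma_e=1.0, seed=17)
        table = blup(frame, ONEWAY, {"genotype": 0.0, "residual": 1.0})
        np.testing.assert_allclose(
            table.overall.to_numpy(), np.full(6, table.grand_mean), atol=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_shrinkage_variance_inequality(self, seed):
        """BLUP deviations are never more dispersed than raw genotype means."""
        cfg = SimulationConfig(
            n_test_entries=10, n_checks=3, n_blocks_per_env=2, seed=seed
        )
        plots, _ = generate_trial(cfg)
        frame = composition_table(plots_to_frame(plots))
        spec = ModelSpec(trait="cellulose_pct")
        vc = fit_varcomp(frame, spec, tol=1e-6, max_iter=2000)
        table = blup(frame, spec, vc)
        raw = frame.groupby("genotype_id")["cellulose_pct"].mean()
        assert table.overall.var() <= raw.var() + 1e-12

    def test_zero_residual_variance_rejected(self, small_trial):
        frame, _ = small_trial
        with pytest.raises(ValueError, match="residual"):
            blup(frame, ModelSpec(trait="cellulose_pct"), {"genotype": 1.0, "residual": 0.0})
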