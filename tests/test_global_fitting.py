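"""Global nonlinear fits: identities, recovery, diagnostics, model choice."""

import numpy as np
import pandas as pd
import pytest

from pingpongfit import (
    HillKineticsModel,
    InvalidInputError,
    MichaelisMentenModel,
    NoiseModel,
    PingPongBiBiModel,
    RateParamsPingPong,
    TitrationDesign,
    compare_models,
    design_default_grid,
    design_mm_series,
    fit_global_hill,
    fit_global_pingpong,
    fit_mm,
    runs_test,
    simulate_velocities,
)
from pingpongfit.rate_models import hill_velocity, pingpong_velocity
from tests.conftest import C8_TRUTH


def pingpong_table(kcat=0.09, km_a=139.0, km_b=16.0, e0=0.2, cv=0.0, seed=0):
    d = design_default_grid("C8-CoA")
    truth = RateParamsPingPong(kcat, km_a, km_b)
    return simulate_velocities(truth, d, NoiseModel(velocity_cv=cv, seed=seed))


class TestMichaelisMenten:
    def test_noiseless_identity_fit(self):
        s = design_mm_series(4.9)
        v = 0.037 * 0.1 * s / (4.9 + s)
        res = MichaelisMentenModel(v, s, 0.1).fit()
        assert res.converged
        assert res.Km_app == pytest.approx(4.9, rel=1e-6)
        assert res.kcat_app == pytest.approx(0.037, rel=1e-6)

    def test_noisy_recovery_within_combined_se(self):
        # four seeded biological replicates at cv 5%
        rng = np.random.default_rng(42)
        s = design_mm_series(4.9)
        kms, ses = [], []
        for _ in range(4):
            v = 0.037 * 0.1 * s / (4.9 + s) * (1 + rng.normal(0, 0.05, s.size))
            res = MichaelisMentenModel(v, s, 0.1).fit()
            kms.append(res.Km_app)
            ses.append(res.bse["Km_app"])
        combined_se = np.sqrt(np.mean(np.square(ses)) / 4)
        assert abs(np.mean(kms) - 4.9) <= max(combined_se, np.std(kms) / 2)

    def test_single_level_unidentifiable(self):
        with pytest.raises(InvalidInputError):
            MichaelisMentenModel([1.0, 1.1, 0.9, 1.0], [5.0, 5.0, 5.0, 5.0], 0.1)

    def test_summary_mentions_parameters(self):
        s = design_mm_series(4.9)
        res = MichaelisMentenModel(0.037 * 0.1 * s / (4.9 + s), s, 0.1).fit()
        out = res.summary()
        assert "Km_app" in out and "kcat_app" in out


class TestGlobalPingPong:
    def test_noiseless_exact_recovery(self):
        res = fit_global_pingpong(pingpong_table())
        assert res.converged
        assert res.params["kcat"] == pytest.approx(0.09, rel=1e-8)
        assert res.params["Km_XCoA"] == pytest.approx(139.0, rel=1e-8)
        assert res.params["Km_ACP"] == pytest.approx(16.0, rel=1e-8)
        assert res.rss == pytest.approx(0.0, abs=1e-16)

    def test_order_invariance(self):
        df = pingpong_table(cv=0.03, seed=4)
        res = fit_global_pingpong(df)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        res2 = fit_global_pingpong(shuffled)
        for k in res.params:
            assert res2.params[k] == pytest.approx(res.params[k], rel=1e-7)

    def test_rescaling_invariance(self):
        # scaling all concentrations by c rescales the K estimates by c (h=1)
        df = pingpong_table(cv=0.03, seed=4)
        scaled = df.assign(
            conc_xcoa_uM=df["conc_xcoa_uM"] * 10.0, conc_acp_uM=df["conc_acp_uM"] * 10.0
        )
        res = fit_global_pingpong(df)
        res_s = fit_global_pingpong(scaled)
        assert res_s.params["kcat"] == pytest.approx(res.params["kcat"], rel=1e-6)
        assert res_s.params["Km_XCoA"] == pytest.approx(10 * res.params["Km_XCoA"], rel=1e-6)
        assert res_s.params["Km_ACP"] == pytest.approx(10 * res.params["Km_ACP"], rel=1e-6)

    def test_misfit_to_cooperative_data_flags_ends(self, c8_noiseless_velocities):
        res = fit_global_pingpong(c8_noiseless_velocities)
        assert res.systematic_deviation
        diag = res.diagnostics()
        # hyperbola over sigmoid: same-sign residual clusters at the extremes
        assert (diag["runs_p"] < 0.05).mean() >= 0.5

    def test_too_few_series_rejected(self):
        d = TitrationDesign("C8-CoA", tuple(np.geomspace(1, 700, 12)), (20.0,), 0.2)
        df = simulate_velocities(RateParamsPingPong(0.09, 139, 16), d, NoiseModel())
        with pytest.raises(InvalidInputError):
            fit_global_pingpong(df)


class TestGlobalHill:
    def test_noiseless_identity_fit(self, c8_noiseless_velocities):
        res = fit_global_hill(c8_noiseless_velocities)
        assert res.converged
        assert res.params["kcat"] == pytest.approx(0.09, rel=1e-6)
        assert res.params["Kp_XCoA"] == pytest.approx(139.0, rel=1e-6)
        assert res.params["Kp_ACP"] == pytest.approx(16.0, rel=1e-6)
        assert res.params["h"] == pytest.approx(1.85, rel=1e-6)

    def test_noisy_recovery_within_2se(self, c8_noisy_velocities):
        res = fit_global_hill(c8_noisy_velocities)
        for key, truth in [("kcat", 0.09), ("Kp_XCoA", 139.0), ("Kp_ACP", 16.0), ("h", 1.85)]:
            assert abs(res.params[key] - truth) <= 2 * res.bse[key], key

    def test_nested_identity_h_fixed_to_one(self):
        df = pingpong_table(cv=0.03, seed=21)
        pp = fit_global_pingpong(df)
        hill1 = HillKineticsModel.from_dataframe(df, fix_h=1.0).fit()
        assert hill1.rss == pytest.approx(pp.rss, rel=1e-8)
        assert hill1.params["Kp_XCoA"] == pytest.approx(pp.params["Km_XCoA"], rel=1e-6)
        assert hill1.params["Kp_ACP"] == pytest.approx(pp.params["Km_ACP"], rel=1e-6)

    def test_per_substrate_exponents_supported(self, c8_noisy_velocities):
        res = fit_global_hill(c8_noisy_velocities, shared_h=False)
        assert set(res.param_names) == {"kcat", "Kp_XCoA", "Kp_ACP", "h_XCoA", "h_ACP"}
        assert abs(res.params["h_XCoA"] - 1.85) < 0.5
        assert abs(res.params["h_ACP"] - 1.85) < 0.5

    def test_report_contains_half_saturation(self, c8_noisy_velocities):
        res = fit_global_hill(c8_noisy_velocities)
        d = res.to_dict()
        assert d["K_half_XCoA"] == pytest.approx(res.params["Kp_XCoA"] ** (1 / res.params["h"]))
        assert "se_kcat" in d and d["model"] == "hill"

    def test_bootstrap_se_same_scale_as_asymptotic(self, c8_noisy_velocities):
        res = fit_global_hill(c8_noisy_velocities)
        boot = res.bootstrap(n_resamples=60, seed=0)
        for k in res.param_names:
            assert 0.2 * res.bse[k] < boot[k] < 5 * res.bse[k]


class TestPlotting:
    def test_fit_overlay_has_one_curve_per_series(self, c8_noisy_velocities):
        import matplotlib

        matplotlib.use("Agg")
        res = fit_global_hill(c8_noisy_velocities)
        ax = res.plot_fit()
        # one scatter + one curve per fixed-acceptor series
        assert len(ax.lines) == 2 * 6
        assert ax.get_xscale() == "log"


class TestOracleEquivalence:
    def test_optimizer_at_least_as_good_as_dense_grid(self):
        # independent brute-force oracle: 40-point/axis log grid on a
        # 3-parameter, 12-point problem must not beat the optimizer by >1%
        d = TitrationDesign("C8-CoA", tuple(np.geomspace(1.0, 700.0, 6)), (10.0, 80.0), 0.2)
        df = simulate_velocities(
            RateParamsPingPong(0.09, 139.0, 16.0), d, NoiseModel(velocity_cv=0.05, seed=17)
        )
        assert len(df) == 12
        res = fit_global_pingpong(df)
        a = df["conc_xcoa_uM"].to_numpy()
        b = df["conc_acp_uM"].to_numpy()
        v = df["v_uM_per_s"].to_numpy()
        kcats = np.geomspace(0.01, 1.0, 40)
        kas = np.geomspace(1.0, 2000.0, 40)
        kbs = np.geomspace(0.5, 500.0, 40)
        best = np.inf
        for kc in kcats:
            for ka in kas:
                pred = pingpong_velocity(a[None, :], b[None, :], 0.2, kc, ka, kbs[:, None])
                rss = ((pred - v[None, :]) ** 2).sum(axis=1).min()
                best = min(best, rss)
        assert res.rss <= best * 1.01


class TestDiagnostics:
    def test_all_zero_residuals_p_one(self):
        z, p = runs_test(np.zeros(12))
        assert p == 1.0

    def test_alternating_signs_not_flagged(self):
        signs = np.resize([1.0, -1.0], 12)
        _, p = runs_test(signs)
        assert p > 0.95

    def test_clustered_signs_flagged(self):
        signs = np.array([-1.0] * 4 + [1.0] * 4 + [-1.0] * 4)
        _, p = runs_test(signs)
        assert p < 0.05

    def test_matches_reference_implementation(self):
        from statsmodels.sandbox.stats.runs import runstest_1samp

        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        z_ours, _ = runs_test(np.sign(x))
        z_ref, _ = runstest_1samp(x, cutoff=0, correction=False)
        assert z_ours == pytest.approx(z_ref, abs=1e-10)

    def test_short_series_skipped(self):
        d = TitrationDesign("C8-CoA", tuple(np.geomspace(1, 700, 5)), (10.0, 80.0), 0.2)
        df = simulate_velocities(RateParamsPingPong(0.09, 139, 16), d, NoiseModel(seed=1))
        res = fit_global_pingpong(df)
        assert res.diagnostics()["runs_p"].isna().all()

    def test_misfit_flag_rate_over_seeds(self, c8_design):
        # forcing the non-cooperative law onto cooperative (h=1.85) data must
        # flag systematic end deviations in >= 80% of seeds at cv 3%
        flags = 0
        n_seeds = 40
        for s in range(n_seeds):
            df = simulate_velocities(C8_TRUTH, c8_design, NoiseModel(velocity_cv=0.03, seed=1000 + s))
            flags += fit_global_pingpong(df).systematic_deviation
        assert flags / n_seeds >= 0.80


class TestModelComparison:
    def test_equal_rss_prefers_simpler(self, c8_noisy_velocities):
        pp = fit_global_pingpong(c8_noisy_velocities)
        hill = fit_global_hill(c8_noisy_velocities)
        # synthetic tie: pretend the hill fit bought nothing
        tied = compare_models(pp, pp.__class__(**{**pp.__dict__}))
        assert tied.preferred == "pingpong"
        # real case: cooperative data decisively prefers the hill law
        real = compare_models(pp, hill)
        assert real.preferred == "hill"
        assert real.delta_aic > 2
        assert real.f_pvalue < 1e-6

    def test_cooperative_data_prefers_hill_across_seeds(self, c8_design):
        prefs = 0
        n_seeds = 40
        for s in range(n_seeds):
            df = simulate_velocities(C8_TRUTH, c8_design, NoiseModel(velocity_cv=0.03, seed=1000 + s))
            c = compare_models(fit_global_pingpong(df), fit_global_hill(df))
            prefs += c.preferred == "hill"
        assert prefs / n_seeds >= 0.95

    def test_null_data_rarely_prefers_hill_when_weighted(self):
        # variance-matched (1/v^2-weighted) fits keep the extra Hill
        # parameter unrewarded on non-cooperative data
        not_preferred = 0
        n_seeds = 30
        deltas = []
        for s in range(n_seeds):
            df = pingpong_table(cv=0.03, seed=5000 + s)
            w = 1.0 / np.maximum(df["v_true_uM_per_s"].to_numpy(), 1e-9) ** 2
            args = (df["v_uM_per_s"], df["conc_xcoa_uM"], df["conc_acp_uM"], 0.2)
            c = compare_models(
                PingPongBiBiModel(*args, weights=w).fit(),
                HillKineticsModel(*args, weights=w).fit(),
            )
            not_preferred += c.preferred != "hill"
            # unweighted default: record the AIC margin
            cu = compare_models(
                PingPongBiBiModel(*args).fit(), HillKineticsModel(*args).fit()
            )
            deltas.append(cu.delta_aic)
        assert not_preferred / n_seeds >= 0.80
        # unweighted AIC margin stays small on median even though
        # multiplicative noise inflates its tail
        assert np.median(deltas) < 2.0

    def test_different_datasets_rejected(self, c8_noisy_velocities):
        pp = fit_global_pingpong(c8_noisy_velocities)
        other = fit_global_pingpong(pingpong_table(cv=0.03, seed=77))
        with pytest.raises(InvalidInputError):
            compare_models(pp, other)


class TestRecoveryStudy:
    def test_bias_small_and_coverage_calibrated(self, c8_design):
        # 60 seeds at cv 3%: median relative bias <= 3% per parameter and
        # nominal 68% intervals cover truth at a plausible rate
        truth = {"kcat": 0.09, "Kp_XCoA": 139.0, "Kp_ACP": 16.0, "h": 1.85}
        bias = {k: [] for k in truth}
        cover = {k: 0 for k in truth}
        n_seeds = 60
        for s in range(n_seeds):
            df = simulate_velocities(C8_TRUTH, c8_design, NoiseModel(velocity_cv=0.03, seed=3000 + s))
            res = fit_global_hill(df)
            for k, t in truth.items():
                bias[k].append((res.params[k] - t) / t)
                cover[k] += abs(res.params[k] - t) <= res.bse[k]
        for k in truth:
            assert abs(np.median(bias[k])) <= 0.03, k
            assert 0.55 <= cover[k] / n_seeds <= 0.80, k
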