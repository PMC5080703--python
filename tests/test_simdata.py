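import numpy as np
import pytest
from scipy import special, stats

from valimpute import (
    IncompleteDataset, SimulationConfig, auc, effect_spec, generate_complete,
    impose_missingness, read_dataset, simulate, solve_effect_size,
    solve_missingness_intercept, theoretical_auc, write_dataset,
)
from valimpute.simdata import ConfigurationError, build_missingness_model

AUC_GRID = [0.5, 0.58, 0.66, 0.74, 0.82]


class TestSolveEffectSize:
    def test_null_auc_gives_zero_shift(self):
        assert solve_effect_size(0.5, np.eye(3)) == 0.0

    def test_single_covariate_closed_form(self):
        # with Sigma = [1]: d = 2 * Phi^{-1}(auc)
        d = solve_effect_size(0.66, np.eye(1))
        assert d == pytest.approx(2 * stats.norm.ppf(0.66), abs=1e-8)
        assert d == pytest.approx(0.8250, abs=1e-4)

    def test_independent_covariates_closed_form(self):
        # Sigma = I_p: quadform = p d^2, so d = 2 Phi^{-1}(auc) / sqrt(p)
        d = solve_effect_size(0.82, np.eye(5))
        assert d == pytest.approx(2 * stats.norm.ppf(0.82) / np.sqrt(5),
                                  abs=1e-8)

    @pytest.mark.parametrize("target", AUC_GRID)
    @pytest.mark.parametrize("p,rho", [(1, 0.0), (5, 0.0), (10, 0.0),
                                       (10, 0.25), (20, 0.25)])
    def test_round_trip_over_grid(self, target, p, rho):
        sigma = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        d = solve_effect_size(target, sigma)
        assert theoretical_auc(np.full(p, d), sigma) == pytest.approx(
            target, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            solve_effect_size(0.4, np.eye(2))
        with pytest.raises(ValueError):
            solve_effect_size(1.0, np.eye(2))
        with pytest.raises(np.linalg.LinAlgError):
            solve_effect_size(0.7, np.zeros((2, 2)))


class TestEffectSpec:
    def test_situation2_baseline_and_added(self):
        cfg = SimulationConfig(n=100, p0=5, p1=10, auc0=0.60,
                               auc_target=0.12, rho1=0.25)
        eff = effect_spec(cfg)
        sigma0 = cfg.sigma()[:5, :5]
        assert theoretical_auc(eff.delta_mu[:5], sigma0) == pytest.approx(
            0.60, abs=1e-6)
        assert eff.theoretical_auc == pytest.approx(0.72, abs=1e-6)

    def test_gamma_is_sigma_inverse_delta_mu(self):
        cfg = SimulationConfig(n=50, p1=4, auc_target=0.74, rho1=0.25)
        eff = effect_spec(cfg)
        np.testing.assert_allclose(eff.sigma @ eff.gamma, eff.delta_mu)


class TestGenerateComplete:
    def test_null_effect_no_class_shift(self, rng):
        cfg = SimulationConfig(n=5000, p1=3, auc_target=0.5)
        d = generate_complete(cfg, rng=rng)
        diff = d.X[d.y == 1].mean(0) - d.X[d.y == 0].mean(0)
        assert np.all(np.abs(diff) < 0.1)

    def test_single_covariate_realized_binormal_auc(self, rng):
        # the solved shift d gives Mahalanobis distance delta = 2 Phi^-1(t);
        # the realized AUC of a binormal score is Phi(delta / sqrt(2))
        cfg = SimulationConfig(n=10_000, p1=1, auc_target=0.74)
        d = generate_complete(cfg, rng=rng)
        realized = stats.norm.cdf(np.sqrt(2) * stats.norm.ppf(0.74))
        assert auc(d.y, d.X[:, 0]) == pytest.approx(realized, abs=0.01)

    def test_case_fraction(self, rng):
        cfg = SimulationConfig(n=10_000, p1=1, auc_target=0.5, frac=0.25)
        d = generate_complete(cfg, rng=rng)
        assert d.y.mean() == pytest.approx(0.25, abs=0.01)

    def test_class_mean_difference_matches_delta_mu(self, rng):
        cfg = SimulationConfig(n=20_000, p1=2, auc_target=0.82)
        eff = effect_spec(cfg)
        d = generate_complete(cfg, rng=rng)
        diff = d.X[d.y == 1].mean(0) - d.X[d.y == 0].mean(0)
        np.testing.assert_allclose(diff, eff.delta_mu, atol=0.05)


class TestSolveMissingnessIntercept:
    def test_half_missing_zero_intercept(self):
        assert solve_missingness_intercept(np.zeros(100), 0.5) == \
            pytest.approx(0.0, abs=1e-8)

    def test_quarter_missing_logit(self):
        b0 = solve_missingness_intercept(np.zeros(50), 0.25)
        assert b0 == pytest.approx(special.logit(0.25), abs=1e-8)

    def test_heterogeneous_predictors_hit_target(self, rng):
        lp = rng.normal(size=500) * 3
        b0 = solve_missingness_intercept(lp, 0.375)
        assert np.mean(special.expit(b0 + lp)) == pytest.approx(
            0.375, abs=1e-8)


class TestImposeMissingness:
    def test_zero_miss_is_identity(self, rng):
        cfg = SimulationConfig(n=50, p1=3, auc_target=0.66)
        d = generate_complete(cfg, rng=rng)
        out = impose_missingness(d, cfg, rng=rng)
        assert not out.mask.any()

    @pytest.mark.parametrize("mechanism", ["MCAR", "MAR", "MARblock"])
    def test_exact_counts_per_covariate(self, mechanism, rng):
        cfg = SimulationConfig(n=200, p1=10, auc_target=0.66, miss1=0.25,
                               mechanism=mechanism)
        d = generate_complete(cfg, rng=rng)
        out = impose_missingness(d, cfg, rng=rng)
        np.testing.assert_array_equal(out.mask.sum(0), np.full(10, 50))
        assert not np.isnan(out.X[~out.mask]).any()
        np.testing.assert_array_equal(out.X[~out.mask],
                                      out.X_complete[~out.mask])

    def test_mar_masking_enriched_in_cases(self, rng):
        cfg = SimulationConfig(n=10_000, p1=3, auc_target=0.5, miss1=0.375,
                               mechanism="MAR")
        d = generate_complete(cfg, rng=rng)
        out = impose_missingness(d, cfg, rng=rng)
        masked_any = out.mask.any(axis=1)
        assert d.y[masked_any].mean() > d.y[~masked_any].mean()

    def test_mcar_mask_independent_of_outcome_and_values(self, rng):
        cfg = SimulationConfig(n=5000, p1=2, auc_target=0.5, miss1=0.25)
        d = generate_complete(cfg, rng=rng)
        out = impose_missingness(d, cfg, rng=rng)
        m = out.mask[:, 0].astype(float)
        tau_y = stats.kendalltau(m, d.y).statistic
        tau_x = stats.kendalltau(m, d.X_complete[:, 0]).statistic
        assert abs(tau_y) < 0.05 and abs(tau_x) < 0.05

    def test_marblock_mask_overlap_exceeds_mcar(self, rng):
        def mean_overlap(mechanism):
            cfg = SimulationConfig(n=2000, p1=9, auc_target=0.5, miss1=0.375,
                                   mechanism=mechanism)
            d = generate_complete(cfg, rng=rng)
            out = impose_missingness(d, cfg, rng=rng)
            model = None
            if mechanism == "MARblock":
                # pairs within the same block share a partner
                pass
            overlaps = []
            for j in range(9):
                for k in range(j + 1, 9):
                    inter = np.sum(out.mask[:, j] & out.mask[:, k])
                    overlaps.append(inter / out.mask[:, j].sum())
            return np.max(overlaps)

        assert mean_overlap("MARblock") > mean_overlap("MCAR") + 0.1

    def test_outcome_never_masked_and_error_on_excess(self, rng):
        cfg = SimulationConfig(n=8, p1=2, auc_target=0.5, miss1=0.875)
        d = generate_complete(cfg, rng=rng)
        with pytest.raises(ConfigurationError):
            impose_missingness(d, cfg, rng=rng)

    def test_mar_first_covariate_has_no_lag_term(self, rng):
        cfg = SimulationConfig(n=100, p1=4, auc_target=0.5, miss1=0.25,
                               mechanism="MAR")
        model = build_missingness_model(cfg, rng=rng)
        assert model.beta1[0] == 0.0 and model.beta2[0] == 0.0
        assert set(model.beta1[1:]) <= {-1.0, 1.0}
        assert np.all(model.beta2[1:] == 2.0)
        assert np.all(model.partner != np.arange(4))

    def test_marblock_partners_outside_block(self, rng):
        cfg = SimulationConfig(n=100, p1=10, auc_target=0.5, miss1=0.25,
                               mechanism="MARblock")
        model = build_missingness_model(cfg, rng=rng)
        assert len(np.unique(model.blocks)) <= 3
        for j in range(10):
            assert model.blocks[model.partner[j]] != model.blocks[j]


class TestPipelineAndIO:
    def test_simulate_is_seed_deterministic(self):
        cfg = SimulationConfig(n=60, p1=3, auc_target=0.66, miss1=0.25,
                               mechanism="MAR", seed=11)
        a, b = simulate(cfg), simulate(cfg)
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.X[~a.mask], b.X[~b.mask])

    def test_csv_round_trip(self, tmp_path, rng):
        cfg = SimulationConfig(n=30, p1=3, auc_target=0.66, miss1=0.25)
        d = simulate(cfg, seed=5)
        path = tmp_path / "d.csv"
        write_dataset(d, path, manifest={"config": cfg.to_dict()})
        back = read_dataset(path)
        np.testing.assert_array_equal(back.y, d.y)
        np.testing.assert_array_equal(back.mask, d.mask)
        np.testing.assert_allclose(back.X[~back.mask], d.X[~d.mask])
        assert (tmp_path / "d.manifest.json").exists()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=1, p1=1, auc_target=0.6)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=10, p1=1, auc_target=0.6, frac=0.7)
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=10, p1=1, auc_target=0.6, mechanism="nope")
        with pytest.raises(ConfigurationError):
            SimulationConfig(n=10, p1=1, p0=2, auc_target=0.6)  # no auc0
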