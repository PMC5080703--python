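import numpy as np
import pytest
from scipy import stats

from valimpute import (
    ImputationSpec, IncompleteDataset, SimulationConfig, StrategySpec,
    ValidationSpec, effect_spec, fit_logistic, generate_complete,
    jiang_percentile_ci, pooled_delong_ci, run_strategy, simulate,
)
from valimpute.measures import delong_variance
from valimpute.strategies import DegenerateSplitError, PerformanceReport


class TestFitLogistic:
    def test_null_effect_predicts_case_fraction(self, rng):
        X = rng.normal(size=(5000, 3))
        y = (rng.random(5000) < 0.3).astype(int)
        model = fit_logistic(X, y)
        assert np.allclose(model.params[1:], 0, atol=0.1)
        assert model.predict(X).mean() == pytest.approx(0.3, abs=0.02)

    def test_recovers_generating_coefficients(self, rng):
        # data built so that P(y=1|x) = logistic(gamma . x)
        cfg = SimulationConfig(n=50_000, p1=3, auc_target=0.74, rho1=0.25)
        eff = effect_spec(cfg)
        d = generate_complete(cfg, rng=rng)
        model = fit_logistic(d.X, d.y)
        np.testing.assert_allclose(model.params[1:], eff.gamma, atol=0.05)

    def test_separable_fixture_flagged(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(X, y)
        assert model.separation
        p = model.predict(X)
        assert np.all((p > 0) & (p < 1))

    def test_single_class_raises(self):
        with pytest.raises(DegenerateSplitError):
            fit_logistic(np.ones((4, 1)), np.zeros(4))


class TestReductionToCompleteData:
    """With an empty mask every strategy must collapse to complete-data
    validation bit-identically (imputation becomes a no-op and all
    strategies share the resampling-plan seed stream)."""

    @pytest.mark.parametrize("name", ["val-mi", "mi-val", "mi-noy-val"])
    @pytest.mark.parametrize("vstrat,K", [("BS", None), ("SS", None),
                                          ("CVK", 3)])
    def test_strategies_collapse_on_complete_data(self, name, vstrat, K):
        cfg = SimulationConfig(n=80, p1=3, auc_target=0.66)
        d = generate_complete(cfg, rng=np.random.default_rng(5))
        val = ValidationSpec(strategy=vstrat, B=4, K=K)
        ref = run_strategy(d, StrategySpec(name="val", validation=val),
                           seed=99)
        for M in (1, 3):
            rep = run_strategy(
                d, StrategySpec(name=name, validation=val,
                                imputation=ImputationSpec(M=M)), seed=99)
            assert rep.estimates.keys() == ref.estimates.keys()
            for k in ref.estimates:
                assert rep.estimates[k] == pytest.approx(
                    ref.estimates[k], abs=1e-12), (name, M, k)

    def test_val_requires_complete_data(self):
        cfg = SimulationConfig(n=60, p1=2, auc_target=0.66, miss1=0.25)
        d = simulate(cfg, seed=1)
        with pytest.raises(ValueError, match="complete"):
            run_strategy(d, StrategySpec(name="val"), seed=0)


@pytest.fixture(scope="module")
def incomplete():
    cfg = SimulationConfig(n=150, p1=4, auc_target=0.74, miss1=0.25,
                           mechanism="MAR")
    return simulate(cfg, seed=7)


class TestRunStrategy:
    @pytest.mark.parametrize("name", ["val-mi", "mi-val", "mi-noy-val"])
    def test_report_structure_and_raw_pooling(self, incomplete, name):
        spec = StrategySpec(name=name, validation=ValidationSpec("BS", B=6),
                            imputation=ImputationSpec(M=2))
        rep = run_strategy(incomplete, spec, seed=3)
        assert rep.n_splits == 12
        assert len(rep.raw["oob"]) == 12 - rep.skipped_splits
        # the reported oob is the mean of the per-(b, m) values
        assert rep.estimates["oob"] == pytest.approx(
            float(np.mean(rep.raw["oob"])))
        assert set(rep.estimates) >= {"apparent", "oob", "opt_corr",
                                      "e0632", "e0632plus"}
        assert 0.632 <= rep.diagnostics["w"] <= 1.0

    def test_outcome_inclusion_forced_by_strategy_name(self):
        spec = StrategySpec(name="mi-noy-val",
                            imputation=ImputationSpec(include_outcome=True))
        assert spec.imputation.include_outcome is False
        spec = StrategySpec(name="val-mi",
                            imputation=ImputationSpec(include_outcome=False))
        assert spec.imputation.include_outcome is True

    def test_seed_determinism(self, incomplete):
        spec = StrategySpec(name="val-mi", validation=ValidationSpec("BS", 4),
                            imputation=ImputationSpec(M=2))
        a = run_strategy(incomplete, spec, seed=11)
        b = run_strategy(incomplete, spec, seed=11)
        assert a.estimates == b.estimates

    def test_cv_reports_cv_estimate_only(self, incomplete):
        spec = StrategySpec(name="mi-val",
                            validation=ValidationSpec("CVKrep", B=2, K=3),
                            imputation=ImputationSpec(M=2))
        rep = run_strategy(incomplete, spec, seed=5)
        assert "cv" in rep.estimates
        assert "e0632plus" not in rep.estimates

    def test_mi_without_validation_pools_apparent(self, incomplete):
        rep = run_strategy(
            incomplete,
            StrategySpec(name="mi", imputation=ImputationSpec(M=3)), seed=2)
        assert set(rep.estimates) == {"apparent"}
        assert rep.estimates["apparent"] == pytest.approx(
            float(np.mean(rep.raw["apparent"])))

    def test_added_measure_requires_baseline(self, incomplete):
        with pytest.raises(ValueError, match="baseline"):
            run_strategy(incomplete,
                         StrategySpec(name="val-mi", measure="dauc"), seed=0)

    def test_added_measure_runs(self, incomplete):
        spec = StrategySpec(name="val-mi", measure="dauc",
                            baseline_covariates=(0,),
                            validation=ValidationSpec("BS", B=4),
                            imputation=ImputationSpec(M=2))
        rep = run_strategy(incomplete, spec, seed=8)
        assert rep.diagnostics["noinfo"] == 0.0
        assert -2 <= rep.estimates["e0632plus"] <= 2

    def test_too_many_degenerate_splits_hard_error(self):
        y = np.zeros(12, dtype=int)
        y[0] = 1  # almost every bootstrap training draw is single-class
        X = np.random.default_rng(0).normal(size=(12, 1))
        d = IncompleteDataset(y, X, np.zeros_like(X, dtype=bool))
        with pytest.raises(RuntimeError, match="degenerate"):
            run_strategy(d, StrategySpec(name="val",
                                         validation=ValidationSpec("BS", 20)),
                         seed=0)


class TestJiangInterval:
    def _report(self, train_train, plus):
        return PerformanceReport(
            strategy="val-mi", measure="auc",
            estimates={"e0632plus": plus}, diagnostics={},
            raw={"train_train": np.asarray(train_train)},
        )

    def test_degenerate_w_collapses_to_point(self):
        rep = self._report(np.full(50, 0.7), plus=0.65)
        lo, hi = jiang_percentile_ci(rep, apparent_full=0.7)
        assert lo == pytest.approx(0.65) and hi == pytest.approx(0.65)

    def test_symmetric_w_gives_point_plus_minus_d(self):
        w = np.concatenate([np.linspace(-0.1, 0.1, 201)])
        rep = self._report(0.7 + w, plus=0.6)
        lo, hi = jiang_percentile_ci(rep, apparent_full=0.7)
        assert lo == pytest.approx(0.6 - 0.095)
        assert hi == pytest.approx(0.6 + 0.095)
        assert lo <= 0.6 <= hi

    def test_interval_ordering_on_simulated_data(self):
        cfg = SimulationConfig(n=100, p1=2, auc_target=0.66, miss1=0.25)
        d = simulate(cfg, seed=3)
        spec = StrategySpec(name="val-mi",
                            validation=ValidationSpec("BS", B=40),
                            imputation=ImputationSpec(M=1), ci="jiang")
        rep = run_strategy(d, spec, seed=4)
        lo, hi = rep.ci
        assert lo <= rep.estimates["e0632plus"] <= hi

    def test_too_few_resamples_rejected(self):
        rep = self._report(np.array([0.7]), plus=0.6)
        with pytest.raises(ValueError):
            jiang_percentile_ci(rep, apparent_full=0.7)


class TestPooledDeLong:
    def test_complete_data_reduces_to_plain_delong(self, four_row_scores):
        y, p = four_row_scores
        # build a dataset whose fitted single covariate reproduces the
        # score ordering; compare against the direct formula
        X = p.reshape(-1, 1)
        d = IncompleteDataset(y, X, np.zeros_like(X, dtype=bool))
        est, lo, hi = pooled_delong_ci(
            d, StrategySpec(name="mi", measure="auc"))
        assert est == pytest.approx(0.75)
        model_p = None  # interval from the model's predicted probabilities
        # the fitted monotone model preserves ranks, so the DeLong
        # variance equals that of the raw scores
        half = stats.norm.ppf(0.975) * np.sqrt(delong_variance(y, p))
        assert hi - lo == pytest.approx(2 * half, rel=1e-6)

    def test_incomplete_data_pools_over_imputations(self):
        cfg = SimulationConfig(n=120, p1=2, auc_target=0.74, miss1=0.25)
        d = simulate(cfg, seed=9)
        est, lo, hi = pooled_delong_ci(
            d, StrategySpec(name="mi", imputation=ImputationSpec(M=5),
                            measure="auc", seed=2))
        assert lo < est < hi
        assert 0.5 < est <= 1.0
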