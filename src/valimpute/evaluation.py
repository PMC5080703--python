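"""Simulation-based evaluation of the validation x imputation strategies.

The reference ("true") performance of a configuration is defined against
large independent complete test data: the model is fitted on a fresh
complete data set of the configured size and evaluated on an independent
complete data set of size ``n_test`` (default 10,000), averaged over
replicates.  Small-sample estimation error makes this truth fall short
of the theoretical AUC used to solve the effect sizes, which is why
estimates are compared against the former.

On top of the truth oracle this module provides bias / variance / MSE
summaries across simulation replicates, CI-based type-1 error and power
curves, the B/M variability law (the SD of a B-resample estimate scales
as 1/sqrt(B)), and the incomplete-future-data experiment (performance of
a complete-data model on test data with increasing missingness, imputed
without the outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from ._util import spawn
from .measures import get_measure
from .mice_pmm import ImputationSpec, run_mice
from .simdata import SimulationConfig, effect_spec, generate_complete, simulate
from .strategies import StrategySpec, _evaluate, _fit_models, run_strategy


@dataclass(frozen=True)
class EvaluationSummary:
    truth: float
    n_replicates: int
    bias: float
    variance: float
    mse: float
    mean: float


def true_performance(config: SimulationConfig, measure: str = "auc",
                     baseline_covariates=None, n_test: int = 10_000,
                     n_replicates: int = 10, seed=None) -> float:
    """Average fit-on-complete / evaluate-on-independent performance."""
    meas = get_measure(measure)
    effect = effect_spec(config)
    vals = []
    for s in spawn(seed, n_replicates):
        rng = np.random.default_rng(s)
        train = generate_complete(config, rng=rng, effect=effect)
        test_cfg = dc_replace(config, n=n_test)
        test = generate_complete(test_cfg, rng=rng, effect=effect)
        model, base = _fit_models(train.X, train.y, baseline_covariates)
        vals.append(_evaluate(meas, model, base, test.X, test.y,
                              baseline_covariates, config.frac))
    return float(np.mean(vals))


def summarize_bias_mse(estimates, truth: float) -> EvaluationSummary:
    """Bias, sampling variance and MSE of replicate estimates vs. truth."""
    est = np.asarray(estimates, dtype=float)
    est = est[~np.isnan(est)]
    if len(est) < 2:
        raise ValueError("need at least 2 replicate estimates")
    mean = float(est.mean())
    bias = mean - truth
    variance = float(est.var(ddof=1))
    mse = float(np.mean((est - truth) ** 2))
    return EvaluationSummary(truth, len(est), bias, variance, mse, mean)


def type1_power_experiment(configs, spec: StrategySpec, n_sim: int = 250,
                           null_value: float | None = None,
                           seed=None) -> pd.DataFrame:
    """Rejection rate of the CI-based test across a configuration grid.

    A simulation counts as a rejection when the confidence interval lies
    entirely above the null value (0.5 for AUC, 0 for added measures).
    At a null configuration the rate is the type-1 error; under a true
    effect it is the power.
    """
    if null_value is None:
        null_value = 0.5 if spec.measure == "auc" else 0.0
    rows = []
    for c, config in enumerate(configs):
        seeds = spawn(np.random.SeedSequence(entropy=0) if seed is None
                      else np.random.SeedSequence(int(seed) + c), n_sim)
        rejected = 0
        n_ok = 0
        for s in seeds:
            s_data, s_strat = s.spawn(2)
            data = simulate(config, seed=s_data)
            ci_spec = spec if spec.ci else dc_replace(spec, ci="jiang")
            report = run_strategy(data, ci_spec, seed=s_strat)
            if report.ci is None:
                continue
            n_ok += 1
            if report.ci[0] > null_value:
                rejected += 1
        rows.append({
            "auc_target": config.auc_target, "n": config.n, "p": config.p,
            "miss": config.miss1, "mechanism": config.mechanism,
            "n_sim": n_ok, "rejection_rate": rejected / max(n_ok, 1),
        })
    return pd.DataFrame(rows)


def variability_curve(datasets, spec: StrategySpec, B_grid, M_grid,
                      n_runs: int = 10, estimate: str = "e0632plus",
                      seed=None) -> pd.DataFrame:
    """SD of the point estimate across repeated runs, per (B, M).

    For each fixture data set and each (B, M) combination the strategy
    is re-run ``n_runs`` times with fresh resampling/imputation seeds;
    the table reports the run-to-run SD averaged over fixtures, the raw
    material for the 1/sqrt(B) scaling law.
    """
    rows = []
    top = spawn(seed, len(datasets))
    for d, data in enumerate(datasets):
        for B in B_grid:
            for M in M_grid:
                run_spec = dc_replace(
                    spec,
                    validation=dc_replace(spec.validation, B=int(B)),
                    imputation=dc_replace(spec.imputation, M=int(M)),
                )
                vals = []
                for s in top[d].spawn(n_runs):
                    rep = run_strategy(data, run_spec, seed=s)
                    vals.append(rep.estimates.get(estimate,
                                                  rep.estimates.get("cv")))
                rows.append({"dataset": d, "B": int(B), "M": int(M),
                             "sd": float(np.std(vals, ddof=1)),
                             "mean": float(np.mean(vals))})
    out = pd.DataFrame(rows)
    return out.groupby(["B", "M"], as_index=False).agg(
        sd=("sd", "mean"), mean=("mean", "mean")
    )


def future_missingness_experiment(config: SimulationConfig, miss_grid,
                                  measure: str = "auc", n_test: int = 2000,
                                  M: int = 5, seed=None) -> pd.DataFrame:
    """Performance of a complete-data model on incomplete future data.

    The model is fitted on a complete training set; for each test
    missingness level, MCAR missingness is imposed on an independent test
    set and imputed *without* the outcome (which is unavailable at the
    application stage), and the measure is averaged over the M
    imputations.
    """
    from .simdata import impose_missingness

    meas = get_measure(measure)
    effect = effect_spec(config)
    s_train, s_test, s_miss, s_imp = spawn(seed, 4)
    train = generate_complete(config, rng=np.random.default_rng(s_train),
                              effect=effect)
    model, _ = _fit_models(train.X, train.y, None)
    test_cfg = dc_replace(config, n=n_test, miss0=0.0, miss1=0.0)
    test = generate_complete(test_cfg, rng=np.random.default_rng(s_test),
                             effect=effect)
    rows = []
    miss_grid = list(miss_grid)
    miss_seeds = s_miss.spawn(len(miss_grid))
    imp_seeds = s_imp.spawn(len(miss_grid))
    for i, miss in enumerate(miss_grid):
        if miss == 0:
            vals = [meas(test.y, model.predict(test.X))]
        else:
            mcfg = dc_replace(test_cfg, mechanism="MCAR",
                              miss0=float(miss) if config.p0 else 0.0,
                              miss1=float(miss))
            masked = impose_missingness(
                test, mcfg, rng=np.random.default_rng(miss_seeds[i])
            )
            copies = run_mice(
                masked, ImputationSpec(M=M, include_outcome=False),
                seed=imp_seeds[i],
            )
            vals = [meas(test.y, model.predict(Xm)) for Xm in copies.copies]
        rows.append({"miss": float(miss), "value": float(np.mean(vals))})
    return pd.DataFrame(rows)
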