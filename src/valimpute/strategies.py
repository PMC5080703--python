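"""Validation x imputation strategies for performance estimation.

The estimand is the predictive performance (or added performance) of a
logistic prediction model developed on an incomplete data set.  Three
orders of combining internal validation with multiple imputation are
provided:

* ``val-mi``    - draw validation splits of the incomplete data first,
  then impute the training and test parts *separately* (each as a
  self-contained data set, outcome included).  Training and test parts
  never share an imputation model.
* ``mi-val``    - impute the full data set first (outcome included in
  the imputation models), then draw validation splits from each
  completed copy.
* ``mi-noy-val`` - as ``mi-val`` but the outcome is withheld from the
  imputation models, keeping the future test parts blind to the
  covariate-outcome association.
* ``mi`` / ``mi-noy`` - multiple imputation without validation:
  Rubin-pooled apparent performance only.
* ``val``       - internal validation of complete data (reference).

For resampling strategies with an out-of-bag test set (bootstrap,
subsampling) the report carries apparent, out-of-bag, ordinary
optimism-corrected, 0.632 and 0.632+ estimates; cross-validation reports
the plain CV estimate.  Confidence intervals follow a modified Jiang
percentile procedure: the per-(b, m) resample-apparent deviations
``w_bm = theta(BS(b,m),BS(b,m)) - theta(Orig,Orig)`` provide the
percentiles, and the interval is centred at the 0.632+ estimate,

    [ theta_0.632+ - xi_{1-alpha/2} ,  theta_0.632+ - xi_{alpha/2} ].

For the no-validation strategies an analytic DeLong interval for the
(delta) AUC is provided, Rubin-pooled over the imputations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from ._util import as_generator, spawn
from .estimators import (estimate_0632, estimate_0632plus, noinfo_performance,
                         optimism_corrected)
from .measures import (DegenerateMeasureError, Measure, delong_variance,
                       delong_variance_diff, get_measure)
from .mice_pmm import CompletedDatasets, ImputationSpec, pool_rubin, run_mice
from .resampling import ResamplingPlan, draw_resamples
from .simdata import IncompleteDataset

PROB_CLIP = 1e-12

STRATEGY_NAMES = ("val", "val-mi", "mi-val", "mi-noy-val", "mi", "mi-noy")


class DegenerateSplitError(Exception):
    """A training split cannot support model fitting (single class)."""


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedLogistic:
    """Maximum-likelihood logistic model; predicts clipped probabilities."""

    params: np.ndarray
    converged: bool
    separation: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.params[0] + X @ self.params[1:]
        return np.clip(special.expit(eta), PROB_CLIP, 1 - PROB_CLIP)


def fit_logistic(X: np.ndarray, y: np.ndarray) -> FittedLogistic:
    """Fit an unpenalized logistic regression.

    Raises :class:`DegenerateSplitError` on a single-class outcome.
    Perfect separation / non-convergence is flagged on the result rather
    than raised, since clipped predicted probabilities remain usable.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if len(np.unique(y)) < 2:
        raise DegenerateSplitError("training outcome has a single class")
    Z = np.column_stack([np.ones(len(y)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Z).fit(disp=0, maxiter=100)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            # separation or singular Hessian: fall back to IRLS via GLM
            res = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
            params = np.asarray(res.params, dtype=float)
            converged = False
    separation = (not converged) or bool(np.max(np.abs(params)) > 1e3)
    return FittedLogistic(params, converged, separation)


# ---------------------------------------------------------------------------
# specifications and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationSpec:
    strategy: str = "BS"   # BS | SS | CVK | CVKrep
    B: int = 10
    K: int | None = None


@dataclass(frozen=True)
class StrategySpec:
    name: str = "val-mi"
    validation: ValidationSpec = field(default_factory=ValidationSpec)
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    measure: str = "auc"
    baseline_covariates: tuple[int, ...] | None = None
    alpha: float = 0.05
    ci: str | None = None  # None | "jiang" | "delong"
    n_perm_noinfo: int = 1000
    frac: float | None = None  # risk-category basis; default: observed
    seed: int | None = None

    def __post_init__(self):
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        # the outcome is necessarily included when imputing train/test
        # separately, and necessarily excluded for the (-y) strategies
        include = {"val-mi": True, "mi-noy-val": False, "mi-noy": False,
                   "mi-val": True, "mi": True}.get(self.name)
        if include is not None and self.imputation.include_outcome != include:
            object.__setattr__(
                self, "imputation",
                replace(self.imputation, include_outcome=include),
            )


@dataclass
class PerformanceReport:
    strategy: str
    measure: str
    estimates: dict
    diagnostics: dict
    raw: dict
    ci: tuple[float, float] | None = None
    skipped_splits: int = 0
    n_splits: int = 0

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "measure": self.measure,
            "estimates": self.estimates,
            "diagnostics": self.diagnostics,
            "raw": {k: np.asarray(v).tolist() for k, v in self.raw.items()},
            "ci": None if self.ci is None else list(self.ci),
            "skipped_splits": self.skipped_splits,
            "n_splits": self.n_splits,
        }


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def _fit_models(X, y, baseline_cols):
    """Fit the extended model and, if requested, the baseline model."""
    model = fit_logistic(X, y)
    base = None
    if baseline_cols is not None:
        base = fit_logistic(X[:, list(baseline_cols)], y)
    return model, base


def _evaluate(measure: Measure, model, base, X, y, baseline_cols, frac):
    p = model.predict(X)
    pb = None
    if base is not None:
        pb = base.predict(X[:, list(baseline_cols)])
    return measure(y, p, pb, frac=frac)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def run_strategy(data: IncompleteDataset, spec: StrategySpec,
                 seed=None) -> PerformanceReport:
    """Estimate predictive performance of a logistic model on ``data``.

    The seed (``seed`` argument or ``spec.seed``) is split into four
    streams - resampling plan, imputation, apparent-performance
    imputation, no-information permutations - so that all strategies
    share the same plan stream and collapse to the complete-data ``val``
    run when the data carry no missing values.
    """
    measure = get_measure(spec.measure)
    baseline = spec.baseline_covariates
    if measure.needs_baseline and baseline is None:
        raise ValueError(f"measure {measure.name!r} needs baseline_covariates")
    frac = spec.frac
    if frac is None:
        f = float(np.mean(data.y))
        frac = min(f, 1 - f) if 0 < f < 1 else 0.5
    s_plan, s_imp, s_app, s_noinfo = spawn(
        seed if seed is not None else spec.seed, 4
    )

    if spec.name in ("mi", "mi-noy"):
        return _run_no_validation(data, spec, measure, baseline, frac, s_imp)

    v = spec.validation
    plan = draw_resamples(data.n, v.strategy, v.B, v.K, seed=s_plan)

    # completed copies of the full data: apparent performance basis, and
    # (mi-val) the basis from which splits are evaluated
    if spec.name == "val":
        if not data.is_complete():
            raise ValueError("strategy 'val' requires complete data")
        full = CompletedDatasets(data.y.copy(), [data.X.copy()])
    elif spec.name == "val-mi":
        app_spec = replace(spec.imputation, include_outcome=True)
        full = run_mice(data, app_spec, seed=s_app)
    else:  # mi-val / mi-noy-val
        full = run_mice(data, spec.imputation, seed=s_imp)

    apparent_vals = []
    apparent_preds = []
    for Xm in full.copies:
        model, base = _fit_models(Xm, data.y, baseline)
        apparent_vals.append(
            _evaluate(measure, model, base, Xm, data.y, baseline, frac)
        )
        apparent_preds.append(model.predict(Xm))
    apparent = float(np.mean(apparent_vals))

    raw = {"b": [], "m": [], "train_train": [], "train_orig": [], "oob": []}
    skipped = 0

    if spec.name in ("val", "mi-val", "mi-noy-val"):
        for m, Xm in enumerate(full.copies):
            for b, (tr, te) in enumerate(plan):
                try:
                    model, base = _fit_models(Xm[tr], data.y[tr], baseline)
                    tt = _evaluate(measure, model, base, Xm[tr], data.y[tr],
                                   baseline, frac)
                    to = _evaluate(measure, model, base, Xm, data.y,
                                   baseline, frac)
                    ob = _evaluate(measure, model, base, Xm[te], data.y[te],
                                   baseline, frac)
                except (DegenerateSplitError, DegenerateMeasureError):
                    skipped += 1
                    continue
                _append(raw, b, m, tt, to, ob)
    else:  # val-mi
        b_seeds = s_imp.spawn(len(plan))
        for b, (tr, te) in enumerate(plan):
            s_tr, s_te = b_seeds[b].spawn(2)
            try:
                train_copies = run_mice(data.subset(tr), spec.imputation,
                                        seed=s_tr)
                test_copies = run_mice(data.subset(te), spec.imputation,
                                       seed=s_te)
            except Exception:
                skipped += spec.imputation.M
                continue
            for m in range(spec.imputation.M):
                Xtr, Xte = train_copies.copies[m], test_copies.copies[m]
                Xfull = full.copies[min(m, full.M - 1)]
                try:
                    model, base = _fit_models(Xtr, data.y[tr], baseline)
                    tt = _evaluate(measure, model, base, Xtr, data.y[tr],
                                   baseline, frac)
                    to = _evaluate(measure, model, base, Xfull, data.y,
                                   baseline, frac)
                    ob = _evaluate(measure, model, base, Xte, data.y[te],
                                   baseline, frac)
                except (DegenerateSplitError, DegenerateMeasureError):
                    skipped += 1
                    continue
                _append(raw, b, m, tt, to, ob)

    total = len(plan) * full.M if spec.name != "val-mi" \
        else len(plan) * spec.imputation.M
    if total and skipped > 0.2 * total:
        raise RuntimeError(
            f"{skipped}/{total} degenerate splits; data too sparse for the "
            f"requested validation plan"
        )
    raw = {k: np.asarray(v) for k, v in raw.items()}

    estimates = {"apparent": apparent}
    diagnostics = {"skipped": skipped}
    is_cv = v.strategy in ("CVK", "CVKrep")
    oob_mean = float(np.mean(raw["oob"])) if len(raw["oob"]) else np.nan
    if is_cv:
        estimates["cv"] = _cv_estimate(raw, plan)
        estimates["oob"] = oob_mean
    else:
        estimates["oob"] = oob_mean
        estimates["opt_corr"] = optimism_corrected(
            apparent, float(np.mean(raw["train_train"])),
            float(np.mean(raw["train_orig"])),
        )
        if measure.supports_0632:
            noinfo = _noinfo(measure, data.y, apparent_preds,
                             spec.n_perm_noinfo, s_noinfo)
            estimates["e0632"] = estimate_0632(apparent, oob_mean)
            plus = estimate_0632plus(apparent, oob_mean, noinfo)
            estimates["e0632plus"] = plus.value
            diagnostics.update(R=plus.R, w=plus.w, noinfo=noinfo)

    report = PerformanceReport(
        strategy=spec.name, measure=measure.name, estimates=estimates,
        diagnostics=diagnostics, raw=raw, skipped_splits=skipped,
        n_splits=total,
    )
    if spec.ci == "jiang":
        center = estimates.get("e0632plus", estimates.get("cv"))
        report.ci = jiang_percentile_ci(report, apparent, spec.alpha,
                                        center=center)
    return report


def _append(raw, b, m, tt, to, ob):
    raw["b"].append(b)
    raw["m"].append(m)
    raw["train_train"].append(tt)
    raw["train_orig"].append(to)
    raw["oob"].append(ob)


def _cv_estimate(raw, plan: ResamplingPlan) -> float:
    """Mean test performance per CV repetition, then across repetitions."""
    if plan.repetition is None:
        return float(np.mean(raw["oob"]))
    reps = plan.repetition[raw["b"].astype(int)] if len(raw["b"]) else []
    per_rep = [np.mean(np.asarray(raw["oob"])[reps == r])
               for r in np.unique(reps)]
    return float(np.mean(per_rep))


def _noinfo(measure, y, apparent_preds, n_perm, seed):
    if measure.noinfo is not None:
        return measure.noinfo
    rng = as_generator(seed)
    vals = [noinfo_performance(measure, y, p, n_perm=n_perm, rng=rng)
            for p in apparent_preds]
    return float(np.mean(vals))


def _run_no_validation(data, spec, measure, baseline, frac, s_imp):
    copies = run_mice(data, spec.imputation, seed=s_imp)
    vals = []
    for Xm in copies.copies:
        model, base = _fit_models(Xm, data.y, baseline)
        vals.append(_evaluate(measure, model, base, Xm, data.y,
                              baseline, frac))
    pooled = pool_rubin(vals)
    report = PerformanceReport(
        strategy=spec.name, measure=measure.name,
        estimates={"apparent": pooled.point},
        diagnostics={}, raw={"apparent": np.asarray(vals)},
        n_splits=0,
    )
    if spec.ci == "delong":
        est, lo, hi = pooled_delong_ci(data, spec, copies=copies)
        report.ci = (lo, hi)
    return report


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def jiang_percentile_ci(report: PerformanceReport, apparent_full: float,
                        alpha: float = 0.05,
                        center: float | None = None) -> tuple[float, float]:
    """Modified Jiang percentile interval centred at the 0.632+ estimate.

    ``w_bm`` is the resample-apparent value minus the full-data apparent
    value; the interval is [center - xi_{1-a/2}, center - xi_{a/2}] with
    the percentiles taken over all B x M resamples.
    """
    w = np.asarray(report.raw["train_train"], dtype=float) - apparent_full
    if len(w) < 2:
        raise ValueError("need at least 2 resample values for a CI")
    if len(w) < 40:
        warnings.warn("fewer than 40 resamples; percentile CI is unstable")
    if center is None:
        center = report.estimates.get("e0632plus")
    if center is None:
        raise ValueError("no 0.632+ estimate to centre the interval at")
    lo_q, hi_q = np.quantile(w, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(center - hi_q), float(center - lo_q))


def pooled_delong_ci(data: IncompleteDataset, spec: StrategySpec,
                     copies: CompletedDatasets | None = None,
                     seed=None) -> tuple[float, float, float]:
    """Apparent (delta) AUC with a Rubin-pooled DeLong interval.

    Per completed copy the model is fitted and evaluated on the full
    data; DeLong's placement-value variance of the (difference in) AUC
    is pooled with Rubin's rules and a normal-approximation interval
    returned.  On complete data this reduces to the plain DeLong
    interval.
    """
    measure = get_measure(spec.measure)
    if measure.name not in ("auc", "dauc"):
        raise ValueError("DeLong intervals apply to auc and dauc only")
    baseline = spec.baseline_covariates
    if copies is None:
        if data.is_complete():
            copies = CompletedDatasets(data.y.copy(), [data.X.copy()])
        else:
            copies = run_mice(data, spec.imputation,
                              seed=seed if seed is not None else spec.seed)
    ests, variances = [], []
    for Xm in copies.copies:
        model, base = _fit_models(Xm, data.y, baseline)
        p = model.predict(Xm)
        if measure.name == "auc":
            ests.append(get_measure("auc")(data.y, p))
            variances.append(delong_variance(data.y, p))
        else:
            pb = base.predict(Xm[:, list(baseline)])
            ests.append(measure(data.y, p, pb))
            variances.append(delong_variance_diff(data.y, p, pb))
    pooled = pool_rubin(ests, variances)
    z = stats.norm.ppf(1 - spec.alpha / 2.0)
    half = z * np.sqrt(pooled.total_variance)
    return pooled.point, pooled.point - half, pooled.point + half
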