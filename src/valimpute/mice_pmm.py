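"""Multiple imputation by chained equations with predictive mean matching.

Each incomplete covariate is imputed by a Bayesian linear regression on
the remaining covariates (and optionally the outcome): the residual
variance is drawn from its scaled inverse-chi-square posterior, the
coefficients from a normal around the least-squares fit, and each missing
entry is filled with the *observed* value of a donor whose prediction
(under the point-estimate coefficients) is among the ``n_donors`` closest
to the missing entry's prediction (under the drawn coefficients, i.e.
type-1 matching).  Because donors are observed values, imputations never
leave the observed support of a variable.

Before chaining, each incomplete variable is moved to the scale (raw,
natural log, cube root, square root) on which its observed values look
most normal by the Shapiro-Wilk statistic; the chain runs on that scale
and PMM makes the final inverse transform lossless.

Withholding the outcome from the imputation models (``include_outcome =
False``, the *MI(-y)* strategy) deliberately weakens the imputation model
when a true covariate-outcome association exists; both variants are
provided because they play different roles when imputation is combined
with internal validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import as_generator, spawn
from .simdata import IncompleteDataset

TRANSFORMS = {
    "raw": (lambda v: v, lambda v: v),
    "log": (np.log, np.exp),
    "cbrt": (np.cbrt, lambda v: v**3),
    "sqrt": (np.sqrt, np.square),
}


class DegenerateVariableError(ValueError):
    """An incomplete variable has too few or constant observed values."""


@dataclass(frozen=True)
class ImputationSpec:
    M: int = 5
    include_outcome: bool = True
    n_donors: int = 5
    n_iterations: int = 5
    transform: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.M < 1 or self.n_donors < 1 or self.n_iterations < 1:
            raise ValueError("M, n_donors and n_iterations must be >= 1")


@dataclass
class CompletedDatasets:
    """The M completed copies produced by one MICE run."""

    y: np.ndarray
    copies: list[np.ndarray]
    transform_log: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.copies)


def choose_transformation(x: np.ndarray) -> tuple[str, dict]:
    """Pick the normality-improving transformation of a variable.

    Candidates are raw, natural log, cube root and square root applied to
    the observed values; log requires strictly positive and square root
    non-negative observations.  Returns the label with the largest
    Shapiro-Wilk W together with the per-candidate statistics.
    """
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if len(obs) < 3:
        raise DegenerateVariableError("need at least 3 observed values")
    if np.ptp(obs) == 0:
        raise DegenerateVariableError("constant observed values")
    candidates = ["raw", "cbrt"]
    if np.all(obs > 0):
        candidates.append("log")
    if np.all(obs >= 0):
        candidates.append("sqrt")
    stats_w = {}
    for name in candidates:
        fwd = TRANSFORMS[name][0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # shapiro warns at n > 5000
            stats_w[name] = float(stats.shapiro(fwd(obs)).statistic)
    best = max(stats_w, key=lambda k: (stats_w[k], k == "raw"))
    return best, stats_w


def _posterior_linear_draw(Z: np.ndarray, t: np.ndarray, rng,
                           ridge: float = 1e-8):
    """Bayesian linear regression draw (non-informative prior).

    Returns (beta_hat, beta_draw).  A small ridge is added if the normal
    equations are singular (collinear predictors), with a warning.
    """
    n, q = Z.shape
    ZtZ = Z.T @ Z
    try:
        xtx_inv = np.linalg.inv(ZtZ)
        beta_hat = xtx_inv @ (Z.T @ t)
    except np.linalg.LinAlgError:
        warnings.warn("collinear predictors; ridge-stabilized PMM fit")
        ZtZ = ZtZ + ridge * np.trace(ZtZ) / q * np.eye(q)
        xtx_inv = np.linalg.inv(ZtZ)
        beta_hat = xtx_inv @ (Z.T @ t)
    resid = t - Z @ beta_hat
    df = max(n - q, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    cov = sigma2 * xtx_inv
    # symmetrize before the Cholesky-based draw
    cov = (cov + cov.T) / 2.0
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(q))
    beta_draw = beta_hat + L @ rng.standard_normal(q)
    return beta_hat, beta_draw


def draw_pmm_imputation(target: np.ndarray, predictors: np.ndarray,
                        n_donors: int = 5, rng=None) -> np.ndarray:
    """Fill the missing entries of ``target`` by predictive mean matching.

    ``predictors`` must be fully observed (the chain's current working
    values).  Observed rows are scored with the point-estimate
    coefficients, missing rows with posterior-drawn coefficients; each
    missing entry copies the observed value of one donor drawn uniformly
    from the ``n_donors`` observed rows with the closest predictions.
    """
    rng = as_generator(rng)
    target = np.asarray(target, dtype=float)
    missing = np.isnan(target)
    if not missing.any():
        return target.copy()
    predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
    if predictors.shape[0] != len(target):
        predictors = predictors.T
    Z = np.column_stack([np.ones(len(target)), predictors])
    obs = ~missing
    if obs.sum() < 1:
        raise DegenerateVariableError("no observed values to donate")
    beta_hat, beta_draw = _posterior_linear_draw(Z[obs], target[obs], rng)
    pred_obs = Z[obs] @ beta_hat
    pred_mis = Z[missing] @ beta_draw
    donors_pool = target[obs]
    k = min(n_donors, len(donors_pool))
    out = target.copy()
    # donor ties at the pool boundary break by observed-row index
    # (stable sort of |prediction difference|)
    diff = np.abs(pred_obs[None, :] - pred_mis[:, None])
    order = np.argsort(diff, axis=1, kind="stable")[:, :k]
    pick = rng.integers(0, k, size=len(pred_mis))
    out[missing] = donors_pool[order[np.arange(len(pred_mis)), pick]]
    return out


def run_mice(data: IncompleteDataset, spec: ImputationSpec,
             seed=None) -> CompletedDatasets:
    """Produce ``spec.M`` completed copies of an incomplete data set.

    Incomplete variables are visited in order of increasing missingness
    count (ties by column index); each is regressed on all other
    covariates, plus the outcome iff ``spec.include_outcome``.  With a
    single incomplete variable one sweep is exact (its own working values
    never enter its predictor set), so further sweeps are elided.
    """
    if data.is_complete():
        return CompletedDatasets(data.y.copy(),
                                 [data.X.copy() for _ in range(spec.M)])
    miss_counts = data.mask.sum(axis=0)
    incomplete = np.flatnonzero(miss_counts > 0)
    for j in incomplete:
        if data.n - miss_counts[j] < 3:
            raise DegenerateVariableError(
                f"covariate x{j + 1} has fewer than 3 observed values"
            )
    visit = sorted(incomplete, key=lambda j: (miss_counts[j], j))

    # transformation search on observed values, once, before chaining
    transform_log: dict = {}
    work_base = data.X.copy()
    for j in incomplete:
        if spec.transform:
            name, w = choose_transformation(data.X[:, j])
        else:
            name, w = "raw", {}
        transform_log[f"x{j + 1}"] = {"transform": name, "shapiro_w": w}
        work_base[:, j] = TRANSFORMS[name][0](work_base[:, j])

    n_iter = 1 if len(incomplete) == 1 else spec.n_iterations
    seeds = spawn(seed if seed is not None else spec.seed, spec.M)
    copies = []
    for m in range(spec.M):
        rng = np.random.default_rng(seeds[m])
        work = work_base.copy()
        # initial fill: random draws from each variable's observed values
        for j in incomplete:
            obs_vals = work[~data.mask[:, j], j]
            work[data.mask[:, j], j] = rng.choice(
                obs_vals, size=miss_counts[j], replace=True
            )
        for _ in range(n_iter):
            for j in visit:
                tgt = work_base[:, j]  # NaN at the masked cells
                pred_cols = [k for k in range(data.p) if k != j]
                preds = work[:, pred_cols]
                if spec.include_outcome:
                    preds = np.column_stack([preds, data.y])
                if preds.shape[1] == 0:
                    preds = np.empty((data.n, 0))
                work[:, j] = draw_pmm_imputation(
                    tgt, preds, n_donors=spec.n_donors, rng=rng
                )
        out = data.X.copy()
        for j in incomplete:
            inv = TRANSFORMS[transform_log[f"x{j + 1}"]["transform"]][1]
            out[data.mask[:, j], j] = inv(work[data.mask[:, j], j])
        copies.append(out)
    return CompletedDatasets(data.y.copy(), copies, transform_log)


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    total_variance: float | None = None
    within_variance: float | None = None
    between_variance: float | None = None


def pool_rubin(estimates, variances=None) -> PooledEstimate:
    """Rubin's rules: mean point estimate; total variance combining the
    mean within-imputation variance and the (1 + 1/M)-inflated
    between-imputation variance."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("no estimates to pool")
    point = float(estimates.mean())
    if variances is None:
        return PooledEstimate(point)
    variances = np.asarray(variances, dtype=float)
    if variances.shape != estimates.shape or np.any(variances < 0):
        raise ValueError("variances must match estimates and be >= 0")
    M = len(estimates)
    within = float(variances.mean())
    between = float(estimates.var(ddof=1)) if M > 1 else 0.0
    total = within + (1.0 + 1.0 / M) * between
    return PooledEstimate(point, total, within, between)
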