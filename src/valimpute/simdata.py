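"""De-novo simulation of binary-outcome data with controlled discrimination
and controlled missingness.

The generator draws a binary outcome ``y`` with case probability ``frac``
and multivariate-normal covariates (unit variances, exchangeable
correlation ``rho`` within each covariate set).  A common class-mean shift
``delta_mu`` is applied to every covariate in a set, with ``delta_mu``
solved numerically from the theoretical relationship between the mean
shift and the area under the ROC curve,

    AUC = Phi( 1/2 * sqrt( dmu' Sigma^{-1} dmu ) ),

where ``Phi`` is the standard-normal CDF.  Under this construction the
outcome follows a logistic model with coefficient vector
``gamma = Sigma^{-1} dmu``.

Missingness is imposed on the covariates (never the outcome) by one of
three mechanisms:

* ``MCAR`` - cells masked uniformly at random, per covariate;
* ``MAR``  - the masking probability of covariate ``j`` follows a logistic
  model on the missingness of the previous covariate, the value of a
  randomly chosen partner covariate, and the outcome;
* ``MARblock`` - covariates are grouped into three blocks and every
  covariate in a block shares one strong partner covariate outside the
  block, producing blockwise-correlated missingness.

Per covariate, exactly ``round(n * miss)`` cells are masked: cells are
drawn without replacement with probabilities proportional to the model
missingness probabilities, so the nominal missingness proportion is hit
exactly in every data set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._util import as_generator, round_half_even, spawn

MECHANISMS = ("MCAR", "MAR", "MARblock")

#: coefficient on the outcome in the MAR / MARblock missingness models
OUTCOME_COEF = 2.0
#: coefficient on the shared block-partner covariate in MARblock
BLOCK_PARTNER_COEF = 10.0
N_BLOCKS = 3


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated data-generating process.

    Situation 1 (single covariate set): leave ``p0 = 0`` and ``auc0 = None``;
    ``auc_target`` is the theoretical AUC of the ``p1`` covariates.

    Situation 2 (added performance): set ``p0 >= 1`` and ``auc0``; then
    ``auc_target`` is the theoretical *increase* in AUC contributed by the
    ``p1`` additional covariates on top of the baseline set.
    """

    n: int
    p1: int
    auc_target: float
    p0: int = 0
    auc0: float | None = None
    rho0: float = 0.0
    rho1: float = 0.0
    frac: float = 0.5
    miss0: float = 0.0
    miss1: float = 0.0
    mechanism: str = "MCAR"
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError("n must be at least 2")
        if self.p0 + self.p1 < 1:
            raise ConfigurationError("at least one covariate is required")
        if not 0.0 < self.frac <= 0.5:
            raise ConfigurationError("frac must lie in (0, 0.5]")
        if self.p0 > 0 and self.auc0 is None:
            raise ConfigurationError("auc0 is required when p0 > 0")
        if self.p0 == 0 and self.auc0 is not None:
            raise ConfigurationError("auc0 requires p0 > 0")
        aucs = [self.auc_target] if self.auc0 is None else [self.auc0]
        for a in aucs:
            if not 0.5 <= a < 1.0:
                raise ConfigurationError("theoretical AUC must lie in [0.5, 1)")
        if self.auc0 is not None:
            if not 0.0 <= self.auc_target < 1.0 - self.auc0:
                raise ConfigurationError("added AUC must lie in [0, 1 - auc0)")
        for r in (self.rho0, self.rho1):
            if not 0.0 <= r < 1.0:
                raise ConfigurationError("rho must lie in [0, 1)")
        for m in (self.miss0, self.miss1):
            if not 0.0 <= m < 1.0:
                raise ConfigurationError("miss must lie in [0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")

    @property
    def p(self) -> int:
        return self.p0 + self.p1

    def sigma(self) -> np.ndarray:
        """Block-diagonal covariance: exchangeable within each covariate set."""
        s = np.eye(self.p)
        s[: self.p0, : self.p0] = _exchangeable(self.p0, self.rho0)
        s[self.p0 :, self.p0 :] = _exchangeable(self.p1, self.rho1)
        return s

    def miss_per_column(self) -> np.ndarray:
        return np.array([self.miss0] * self.p0 + [self.miss1] * self.p1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _exchangeable(p: int, rho: float) -> np.ndarray:
    if p == 0:
        return np.zeros((0, 0))
    return np.full((p, p), rho) + (1.0 - rho) * np.eye(p)


@dataclass(frozen=True)
class EffectSpec:
    """Solved class-mean shifts and the implied logistic coefficients."""

    delta_mu: np.ndarray  # length-p vector of per-covariate mean shifts
    sigma: np.ndarray
    gamma: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "gamma", np.linalg.solve(self.sigma, self.delta_mu)
        )

    @property
    def theoretical_auc(self) -> float:
        return theoretical_auc(self.delta_mu, self.sigma)


@dataclass
class IncompleteDataset:
    """A binary outcome, a covariate matrix with NaN holes, and its mask."""

    y: np.ndarray
    X: np.ndarray
    mask: np.ndarray
    X_complete: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.X.shape != self.mask.shape or len(self.y) != len(self.X):
            raise ValueError("inconsistent shapes")
        if not np.array_equal(np.isnan(self.X), self.mask):
            raise ValueError("mask must flag exactly the NaN cells of X")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def is_complete(self) -> bool:
        return not self.mask.any()

    def subset(self, idx: np.ndarray) -> "IncompleteDataset":
        xc = None if self.X_complete is None else self.X_complete[idx]
        return IncompleteDataset(self.y[idx], self.X[idx], self.mask[idx], xc)

    def to_frame(self) -> pd.DataFrame:
        cols = {"y": self.y}
        for j in range(self.p):
            cols[f"x{j + 1}"] = self.X[:, j]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IncompleteDataset":
        xcols = [c for c in frame.columns if c != "y"]
        X = frame[xcols].to_numpy(dtype=float)
        return cls(frame["y"].to_numpy(dtype=int), X, np.isnan(X))


@dataclass
class MissingnessModel:
    """Realised coefficients of the logistic missingness models.

    ``beta0`` holds the per-covariate intercepts solved so the expected
    missingness proportion equals the target exactly; they are filled in
    while the mask is generated (MAR needs the realised mask of the
    previous covariate).
    """

    mechanism: str
    beta0: np.ndarray
    beta1: np.ndarray          # coefficient on previous covariate's mask
    beta2: np.ndarray          # coefficient on the partner covariate (MAR)
    partner: np.ndarray        # partner covariate index per covariate
    outcome_coef: float = OUTCOME_COEF
    blocks: np.ndarray | None = None          # MARblock only
    block_partner_coef: float = BLOCK_PARTNER_COEF

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "beta0": self.beta0.tolist(),
            "beta1": self.beta1.tolist(),
            "beta2": self.beta2.tolist(),
            "partner": self.partner.tolist(),
            "outcome_coef": self.outcome_coef,
            "blocks": None if self.blocks is None else self.blocks.tolist(),
            "block_partner_coef": self.block_partner_coef,
        }


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def theoretical_auc(delta_mu: np.ndarray, sigma: np.ndarray) -> float:
    """AUC implied by a class-mean shift under equal-covariance normality."""
    delta_mu = np.atleast_1d(np.asarray(delta_mu, dtype=float))
    q = float(delta_mu @ np.linalg.solve(sigma, delta_mu))
    return float(stats.norm.cdf(0.5 * np.sqrt(q)))


def solve_effect_size(auc_target: float, sigma: np.ndarray, tol: float = 1e-12) -> float:
    """Common per-covariate mean shift achieving a theoretical AUC.

    Solves ``Phi(0.5 * sqrt(d^2 * 1' Sigma^{-1} 1)) = auc_target`` for
    ``d >= 0`` by bracketed root finding.  ``auc_target = 0.5`` maps to a
    zero shift.
    """
    if not 0.5 <= auc_target < 1.0:
        raise ValueError("auc_target must lie in [0.5, 1)")
    sigma = np.asarray(sigma, dtype=float)
    p = sigma.shape[0]
    ones = np.ones(p)
    s = float(ones @ np.linalg.solve(sigma, ones))
    if s <= 0:
        raise np.linalg.LinAlgError("sigma is not positive definite")
    if auc_target == 0.5:
        return 0.0

    def f(d):
        return stats.norm.cdf(0.5 * d * np.sqrt(s)) - auc_target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=tol))


def effect_spec(config: SimulationConfig) -> EffectSpec:
    """Solve the per-set mean shifts for a configuration.

    In situation 2 the baseline shift is solved on the baseline block
    alone for ``auc0``; holding it fixed, the shift of the additional set
    is then solved so the full covariate vector attains ``auc0 +
    auc_target``.
    """
    sigma = config.sigma()
    if config.p0 == 0:
        d = solve_effect_size(config.auc_target, sigma)
        return EffectSpec(np.full(config.p, d), sigma)

    sigma0 = sigma[: config.p0, : config.p0]
    d0 = solve_effect_size(config.auc0, sigma0)
    total = config.auc0 + config.auc_target

    def dmu(d1):
        return np.concatenate(
            [np.full(config.p0, d0), np.full(config.p1, d1)]
        )

    def f(d1):
        return theoretical_auc(dmu(d1), sigma) - total

    if config.auc_target == 0.0:
        return EffectSpec(dmu(0.0), sigma)
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    d1 = float(optimize.brentq(f, 0.0, hi, xtol=1e-12))
    return EffectSpec(dmu(d1), sigma)


# ---------------------------------------------------------------------------
# complete data
# ---------------------------------------------------------------------------

def generate_complete(config: SimulationConfig, rng=None,
                      effect: EffectSpec | None = None) -> IncompleteDataset:
    """Draw a complete data set (all-zero mask) from the configuration.

    Outcomes are i.i.d. Bernoulli(``frac``); covariates are MVN(0, Sigma)
    shifted by ``+dmu/2`` for cases and ``-dmu/2`` for controls.
    """
    rng = as_generator(rng if rng is not None else config.seed)
    if effect is None:
        effect = effect_spec(config)
    y = (rng.random(config.n) < config.frac).astype(int)
    X = rng.multivariate_normal(
        np.zeros(config.p), effect.sigma, size=config.n, method="cholesky"
    )
    X += np.where(y[:, None] == 1, 0.5, -0.5) * effect.delta_mu
    return IncompleteDataset(y, X, np.zeros_like(X, dtype=bool), X.copy())


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def solve_missingness_intercept(linear_predictor: np.ndarray, miss: float,
                                tol: float = 1e-12) -> float:
    """Intercept making the mean logistic missingness probability ``miss``.

    ``linear_predictor`` holds the per-observation linear predictor
    excluding the intercept; the mean of ``logistic(b0 + lp)`` is monotone
    increasing in ``b0``, so the root is bracketed by expansion.
    """
    if not 0.0 < miss < 1.0:
        raise ValueError("miss must lie in (0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)

    def f(b0):
        return float(np.mean(special.expit(b0 + lp))) - miss

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -1e6:
            raise RuntimeError("could not bracket missingness intercept")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not bracket missingness intercept")
    return float(optimize.brentq(f, lo, hi, xtol=tol))


def build_missingness_model(config: SimulationConfig, rng=None) -> MissingnessModel:
    """Draw the random structure of the MAR / MARblock missingness models.

    MAR: covariate ``j`` (0-based) gets ``beta1 = +/-1`` (fair coin) for
    ``j >= 1`` and 0 for the first covariate; ``beta2 = 2`` for ``j >= 1``
    (dropped for the first covariate and in the single-covariate case);
    the partner is uniform among the other covariates.  MARblock: three
    random blocks; every covariate in a block shares one partner outside
    the block.  Intercepts are solved later against the realised data.
    """
    rng = as_generator(rng)
    p = config.p
    beta0 = np.full(p, np.nan)
    beta1 = np.zeros(p)
    beta2 = np.zeros(p)
    partner = np.full(p, -1, dtype=int)
    blocks = None
    if config.mechanism == "MAR":
        for j in range(p):
            if j >= 1:
                beta1[j] = rng.choice([-1.0, 1.0])
                beta2[j] = 2.0
            if p > 1:
                others = [k for k in range(p) if k != j]
                partner[j] = rng.choice(others)
    elif config.mechanism == "MARblock":
        if p < 2:
            raise ConfigurationError("MARblock requires at least 2 covariates")
        blocks = rng.integers(0, N_BLOCKS, size=p)
        for b in range(N_BLOCKS):
            members = np.flatnonzero(blocks == b)
            outside = np.flatnonzero(blocks != b)
            if len(members) == 0:
                continue
            if len(outside) == 0:
                # degenerate assignment: all covariates in one block;
                # reassign one member to the next block and retry partner
                blocks[members[0]] = (b + 1) % N_BLOCKS
                outside = np.array([members[0]])
                members = members[1:]
            k_b = rng.choice(outside)
            partner[members] = k_b
    return MissingnessModel(
        mechanism=config.mechanism, beta0=beta0, beta1=beta1, beta2=beta2,
        partner=partner, blocks=blocks,
    )


def _mask_exact(rng, prob: np.ndarray, k: int) -> np.ndarray:
    """Indices of exactly ``k`` cells, drawn without replacement with
    probabilities proportional to ``prob``."""
    if k == 0:
        return np.empty(0, dtype=int)
    prob = np.asarray(prob, dtype=float)
    prob = np.clip(prob, 1e-300, None)
    return rng.choice(len(prob), size=k, replace=False, p=prob / prob.sum())


def impose_missingness(data: IncompleteDataset, config: SimulationConfig,
                       model: MissingnessModel | None = None,
                       rng=None) -> IncompleteDataset:
    """Mask covariate cells of a complete data set per the configuration.

    Every covariate of set ``s`` ends up with exactly
    ``round(n * miss_s)`` masked cells.  The outcome is never masked.
    """
    if not data.is_complete():
        raise ValueError("impose_missingness expects a complete data set")
    rng = as_generator(rng)
    n, p = data.n, data.p
    miss = config.miss_per_column()
    counts = np.array([round_half_even(n * m) for m in miss])
    if np.any(counts > n - 2):
        raise ConfigurationError(
            "miss leaves fewer than 2 observed values in a covariate"
        )
    if model is None and config.mechanism in ("MAR", "MARblock"):
        model = build_missingness_model(config, rng)
    if model is None:
        model = MissingnessModel(
            mechanism="MCAR", beta0=np.full(p, np.nan), beta1=np.zeros(p),
            beta2=np.zeros(p), partner=np.full(p, -1, dtype=int),
        )

    mask = np.zeros((n, p), dtype=bool)
    y = data.y.astype(float)
    Xc = data.X
    for j in range(p):
        k = counts[j]
        if k == 0:
            continue
        if config.mechanism == "MCAR":
            idx = rng.choice(n, size=k, replace=False)
        else:
            if config.mechanism == "MAR":
                lp = model.outcome_coef * y
                if j >= 1:
                    lp = lp + model.beta1[j] * mask[:, j - 1]
                if model.partner[j] >= 0 and model.beta2[j] != 0.0:
                    lp = lp + model.beta2[j] * Xc[:, model.partner[j]]
            else:  # MARblock
                lp = model.outcome_coef * y
                lp = lp + model.block_partner_coef * Xc[:, model.partner[j]]
            b0 = solve_missingness_intercept(lp, miss[j])
            model.beta0[j] = b0
            idx = _mask_exact(rng, special.expit(b0 + lp), k)
        mask[idx, j] = True

    X = data.X.copy()
    X[mask] = np.nan
    return IncompleteDataset(data.y, X, mask, data.X.copy())


def simulate(config: SimulationConfig, seed=None) -> IncompleteDataset:
    """Full pipeline: solve effects, draw complete data, impose missingness.

    ``seed`` overrides ``config.seed``.  The seed is split into two child
    streams (complete-data draw, missingness) so the same complete data
    can be reproduced with and without masking.
    """
    s_data, s_miss = spawn(seed if seed is not None else config.seed, 2)
    effect = effect_spec(config)
    data = generate_complete(config, rng=np.random.default_rng(s_data),
                             effect=effect)
    if np.any(config.miss_per_column() > 0):
        data = impose_missingness(data, config,
                                  rng=np.random.default_rng(s_miss))
    return data


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def write_dataset(data: IncompleteDataset, path, manifest: dict | None = None):
    """Write a data set as CSV (missing cells empty) plus a JSON manifest."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False, na_rep="")
    if manifest is not None:
        with open(path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)


def read_dataset(path) -> IncompleteDataset:
    return IncompleteDataset.from_frame(pd.read_csv(path))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
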