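"""Optimism-corrected performance estimators built from resampling averages.

Notation follows the fit-on/evaluate-on convention: ``apparent`` is the
model fitted and evaluated on the original data, ``train_train`` the
average of fit-and-evaluate on each resample, ``train_orig`` the average
of fit-on-resample / evaluate-on-original, and ``oob`` the average
fit-on-resample / evaluate-on-test performance.

* ordinary optimism correction:  apparent - (train_train - train_orig)
* 0.632:    0.368 * apparent + 0.632 * oob
* 0.632+:   (1 - w) * apparent + w * oob  with  w = 0.632 / (1 - 0.368 R)
  and relative overfitting rate
  R = (oob - apparent) / (noinfo - apparent), clipped to [0, 1] so that
  w stays in [0.632, 1].  The clipping guard follows the original 0.632+
  construction; the algebra is direction-agnostic because the
  no-information value sits on the pessimistic side for both
  larger-is-better and smaller-is-better measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import as_generator
from .measures import Measure, brier, get_measure


@dataclass(frozen=True)
class EstimatorInputs:
    apparent: float
    train_train: float | None = None
    train_orig: float | None = None
    oob: float | None = None
    noinfo: float | None = None
    larger_is_better: bool = True


@dataclass(frozen=True)
class Estimate0632Plus:
    value: float
    R: float
    w: float


def noinfo_performance(measure, y=None, p_hat=None, n_perm: int = 1000,
                       rng=None) -> float:
    """No-information performance of a measure.

    Known constants where available (AUC: 0.5; added measures: 0);
    otherwise (Brier) approximated as the average over ``n_perm`` random
    permutations of the predictions against the fixed outcomes.
    """
    if isinstance(measure, str):
        measure = get_measure(measure)
    if not isinstance(measure, Measure):
        raise ValueError("measure must be a Measure or its name")
    if measure.noinfo is not None:
        return measure.noinfo
    if not measure.supports_0632:
        raise ValueError(
            f"no-information performance is undefined for {measure.name}"
        )
    if y is None or p_hat is None:
        raise ValueError(f"{measure.name} needs (y, p_hat) for permutation")
    rng = as_generator(rng)
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    vals = np.empty(n_perm)
    for i in range(n_perm):
        vals[i] = brier(y, rng.permutation(p))
    return float(vals.mean())


def optimism_corrected(apparent: float, train_train: float,
                       train_orig: float) -> float:
    """Ordinary optimism-corrected estimate."""
    return apparent - (train_train - train_orig)


def estimate_0632(apparent: float, oob: float) -> float:
    """Fixed-weight 0.632 combination of apparent and out-of-bag values."""
    return 0.368 * apparent + 0.632 * oob


def estimate_0632plus(apparent: float, oob: float,
                      noinfo: float) -> Estimate0632Plus:
    """0.632+ estimate with its diagnostics (R, w).

    If the no-information value coincides with the apparent value there
    is no estimable overfitting and R is defined as 0, which reduces the
    estimate to the plain 0.632 combination.
    """
    denom = noinfo - apparent
    if denom == 0:
        R = 0.0
    else:
        R = (oob - apparent) / denom
    R = float(np.clip(R, 0.0, 1.0))
    w = 0.632 / (1.0 - 0.368 * R)
    value = (1.0 - w) * apparent + w * oob
    return Estimate0632Plus(float(value), R, float(w))
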