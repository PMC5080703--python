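"""Performance and added-performance measures for binary predictions.

Discrimination: AUC (concordance; ties count one half).  Calibration:
intercept and slope of a logistic regression of the outcome on the logit
of the predicted probability (ideal 0 and 1).  Overall: Brier score.
Added performance of an extended over a baseline model: change in AUC,
categorical net reclassification improvement over the three risk
categories [0, frac/2], (frac/2, 3 frac/2], (3 frac/2, 1], continuous
NRI, and the integrated discrimination improvement.

Measures that need both outcome classes raise
:class:`DegenerateMeasureError` on a single-class sample; the resampling
layer treats that as a skippable split rather than a silent 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

PROB_CLIP = 1e-12


class DegenerateMeasureError(ValueError):
    """The sample does not permit evaluating the measure (e.g. one class)."""


class CalibrationWarning(UserWarning):
    """Calibration fit did not converge (e.g. perfect separation)."""


def _check(y, p, probability=True):
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and predictions must have equal length")
    if probability and np.any((p < 0) | (p > 1)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return y, p


def _require_both_classes(y):
    if len(np.unique(y)) < 2:
        raise DegenerateMeasureError("both outcome classes are required")


def auc(y, p_hat) -> float:
    """Concordance probability via mid-ranks; ties contribute one half.

    Rank-based, so arbitrary risk scores (not only probabilities) are
    accepted.
    """
    y, p = _check(y, p_hat, probability=False)
    _require_both_classes(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def brier(y, p_hat) -> float:
    y, p = _check(y, p_hat)
    return float(np.mean((y - p) ** 2))


def calibration_coefficients(y, p_hat) -> tuple[float, float]:
    """(intercept, slope) of the logistic recalibration model.

    The outcome is regressed on logit(p_hat) (probabilities clipped away
    from 0/1 first); perfectly calibrated predictions give (0, 1).
    Non-convergence (e.g. perfect separation) is flagged with a
    :class:`CalibrationWarning` and the last iterate returned.
    """
    import statsmodels.api as sm

    y, p = _check(y, p_hat)
    _require_both_classes(y)
    x = special.logit(np.clip(p, PROB_CLIP, 1 - PROB_CLIP))
    Z = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, Z).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        warnings.warn("calibration fit did not converge", CalibrationWarning)
    return float(res.params[0]), float(res.params[1])


def delta_auc(y, p_hat, p_hat_base) -> float:
    """AUC of the extended minus AUC of the baseline model, same data."""
    return auc(y, p_hat) - auc(y, p_hat_base)


def risk_categories(frac: float) -> np.ndarray:
    """Cut points (frac/2, 3 frac/2) of the three frac-based risk bands."""
    if not 0 < frac <= 0.5:
        raise ValueError("frac must lie in (0, 0.5]")
    return np.array([frac / 2.0, 1.5 * frac])


def nri_categorical(y, p_hat, p_hat_base, frac: float | None = None,
                    cutpoints=None) -> float:
    """Categorical net reclassification improvement (per-class version).

    NRI = [P(up|case) - P(down|case)] + [P(down|control) - P(up|control)],
    where up/down is movement across the frac-based risk categories.
    """
    y, p = _check(y, p_hat)
    if p_hat_base is None:
        raise ValueError("nri_categorical requires baseline predictions")
    _, pb = _check(y, p_hat_base)
    _require_both_classes(y)
    if cutpoints is None:
        if frac is None:
            frac = float(np.mean(y))
            frac = min(frac, 1 - frac)
            if frac == 0:
                raise DegenerateMeasureError("cannot derive categories")
        cutpoints = risk_categories(frac)
    cat_new = np.digitize(p, cutpoints, right=True)
    cat_old = np.digitize(pb, cutpoints, right=True)
    move = np.sign(cat_new - cat_old)
    case, ctrl = y == 1, y == 0
    nri_case = np.mean(move[case] > 0) - np.mean(move[case] < 0)
    nri_ctrl = np.mean(move[ctrl] < 0) - np.mean(move[ctrl] > 0)
    return float(nri_case + nri_ctrl)


def nri_continuous(y, p_hat, p_hat_base) -> float:
    """Category-free NRI: any increase/decrease counts; ties contribute 0."""
    y, p = _check(y, p_hat)
    _, pb = _check(y, p_hat_base)
    _require_both_classes(y)
    move = np.sign(p - pb)
    case, ctrl = y == 1, y == 0
    return float((np.mean(move[case] > 0) - np.mean(move[case] < 0))
                 + (np.mean(move[ctrl] < 0) - np.mean(move[ctrl] > 0)))


def idi(y, p_hat, p_hat_base) -> float:
    """Integrated discrimination improvement (difference of mean risks)."""
    y, p = _check(y, p_hat)
    _, pb = _check(y, p_hat_base)
    _require_both_classes(y)
    case, ctrl = y == 1, y == 0
    return float((p[case].mean() - pb[case].mean())
                 - (p[ctrl].mean() - pb[ctrl].mean()))


# ---------------------------------------------------------------------------
# DeLong variance of the (difference in) AUC
# ---------------------------------------------------------------------------

def _placements(y, p):
    """DeLong placement values V10 (per case) and V01 (per control)."""
    y, p = _check(y, p, probability=False)
    cases = p[y == 1]
    ctrls = p[y == 0]
    v10 = np.empty(len(cases))
    for i, c in enumerate(cases):
        v10[i] = np.mean((c > ctrls) + 0.5 * (c == ctrls))
    v01 = np.empty(len(ctrls))
    for i, c in enumerate(ctrls):
        v01[i] = np.mean((cases > c) + 0.5 * (cases == c))
    return v10, v01


def delong_variance(y, p_hat) -> float:
    """Variance of the empirical AUC by DeLong's placement-value method."""
    _require_both_classes(np.asarray(y))
    v10, v01 = _placements(y, p_hat)
    if len(v10) < 2 or len(v01) < 2:
        raise DegenerateMeasureError("DeLong variance needs >= 2 per class")
    return float(v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01))


def delong_variance_diff(y, p_hat, p_hat_base) -> float:
    """Variance of AUC(extended) - AUC(baseline) on paired predictions."""
    _require_both_classes(np.asarray(y))
    v10a, v01a = _placements(y, p_hat)
    v10b, v01b = _placements(y, p_hat_base)
    if len(v10a) < 2 or len(v01a) < 2:
        raise DegenerateMeasureError("DeLong variance needs >= 2 per class")
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] - 2 * s10[0, 1] + s10[1, 1]) / m \
        + (s01[0, 0] - 2 * s01[0, 1] + s01[1, 1]) / n
    return float(max(var, 0.0))


# ---------------------------------------------------------------------------
# measure registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Measure:
    """A named performance measure with its evaluation metadata.

    ``noinfo`` is the performance of a model carrying no information
    (used by the 0.632+ weight): a known constant for the AUC (0.5) and
    for added measures (0), ``None`` where it must be approximated by
    permutation (Brier), and not defined for the calibration
    coefficients.
    """

    name: str
    needs_baseline: bool
    larger_is_better: bool
    noinfo: float | None
    supports_0632: bool = True

    def __call__(self, y, p_hat, p_hat_base=None, frac=None) -> float:
        if self.needs_baseline and p_hat_base is None:
            raise ValueError(f"{self.name} requires baseline predictions")
        if self.name == "auc":
            return auc(y, p_hat)
        if self.name == "brier":
            return brier(y, p_hat)
        if self.name == "calib_intercept":
            return calibration_coefficients(y, p_hat)[0]
        if self.name == "calib_slope":
            return calibration_coefficients(y, p_hat)[1]
        if self.name == "dauc":
            return delta_auc(y, p_hat, p_hat_base)
        if self.name == "nri":
            return nri_categorical(y, p_hat, p_hat_base, frac=frac)
        if self.name == "nricont":
            return nri_continuous(y, p_hat, p_hat_base)
        if self.name == "idi":
            return idi(y, p_hat, p_hat_base)
        raise ValueError(f"unknown measure {self.name!r}")


MEASURES = {
    m.name: m
    for m in [
        Measure("auc", False, True, 0.5),
        Measure("brier", False, False, None),
        Measure("calib_intercept", False, True, None, supports_0632=False),
        Measure("calib_slope", False, True, None, supports_0632=False),
        Measure("dauc", True, True, 0.0),
        Measure("nri", True, True, 0.0),
        Measure("nricont", True, True, 0.0),
        Measure("idi", True, True, 0.0),
    ]
}


def get_measure(name: str) -> Measure:
    try:
        return MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; choose from {sorted(MEASURES)}"
        ) from None
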