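"""Point and interval estimation of the overall effect.

Three weighting schemes: fixed-effect / inverse-variance (IV) at a given
tau^2, and SSW, which weights each study by its effective sample size
n_T n_C / n and therefore never touches estimated variances.  Interval
families: normal-theory IV intervals, the Hartung-Knapp-Sidik-Jonkman (HKSJ)
t-interval with its weighted residual variance, and t-intervals around SSW
with the model-based variance sum.  All are symmetric about their midpoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effect_measures import EffectRecord, effective_size
from .q_moments import InsufficientStudiesError

__all__ = ["PooledResult", "pool_iv", "pool_hksj", "pool_ssw", "i_squared"]


@dataclass(frozen=True)
class PooledResult:
    """Overall-effect estimate with its interval and provenance."""

    estimate: float
    se: float
    lower: float
    upper: float
    weighting: str        # FE, IV or SSW
    tau2: float
    ci_family: str        # NORMAL, HKSJ or SSW_T
    df: Optional[float] = None

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _check(records: Sequence[EffectRecord]) -> None:
    if len(records) < 2:
        raise InsufficientStudiesError("pooling needs at least two studies")


def _arrays(records):
    y = np.array([r.estimate for r in records], float)
    v2 = np.array([r.variance for r in records], float)
    return y, v2


def pool_iv(records: Sequence[EffectRecord], tau2: float = 0.0,
            level: float = 0.95) -> PooledResult:
    """Inverse-variance weighted mean with the customary variance (sum w)^-1.

    tau^2 = 0 gives the fixed-effect estimator; critical values are normal.
    """
    _check(records)
    y, v2 = _arrays(records)
    w = 1.0 / (v2 + tau2)
    est = float(np.sum(w * y) / w.sum())
    se = 1.0 / math.sqrt(w.sum())
    z = stats.norm.ppf(0.5 + level / 2)
    return PooledResult(est, se, est - z * se, est + z * se,
                        "FE" if tau2 == 0 else "IV", tau2, "NORMAL")


def pool_hksj(records: Sequence[EffectRecord], tau2: float,
              level: float = 0.95) -> PooledResult:
    """HKSJ interval: IV midpoint, weighted residual variance, t_{K-1} critical values.

    Var = sum w_i (y_i - yhat)^2 / ((K-1) sum w_i) with w_i = 1/(v_i^2 + tau^2).
    Invoked with the WT or KDB tau^2 this is the "HKSJ WT"/"HKSJ KDB" variant.
    """
    _check(records)
    k = len(records)
    if k == 2:
        warnings.warn("HKSJ with K=2 gives an extremely wide t_1 interval", RuntimeWarning)
    y, v2 = _arrays(records)
    w = 1.0 / (v2 + tau2)
    est = float(np.sum(w * y) / w.sum())
    var = float(np.sum(w * (y - est) ** 2) / ((k - 1) * w.sum()))
    se = math.sqrt(var)
    tc = stats.t.ppf(0.5 + level / 2, k - 1)
    return PooledResult(est, se, est - tc * se, est + tc * se, "IV", tau2, "HKSJ",
                        df=float(k - 1))


def pool_ssw(records: Sequence[EffectRecord], tau2: float,
             level: float = 0.95) -> PooledResult:
    """Sample-size weighted estimator with a t_{K-1} interval.

    Point: sum ntilde_i y_i / sum ntilde_i.  Variance:
    sum ntilde_i^2 (v_i^2 + tau^2) / (sum ntilde_i)^2 — the weights involve
    only arm sizes, so the point estimate inherits no bias from estimated
    variances; tau^2 (from a good estimator such as CDL for MD or KDB for
    SMD) enters only through the variance.
    """
    _check(records)
    k = len(records)
    y, v2 = _arrays(records)
    nt = np.array([effective_size(r) for r in records], float)
    est = float(np.sum(nt * y) / nt.sum())
    var = float(np.sum(nt**2 * (v2 + tau2)) / nt.sum() ** 2)
    se = math.sqrt(var)
    tc = stats.t.ppf(0.5 + level / 2, k - 1)
    return PooledResult(est, se, est - tc * se, est + tc * se, "SSW", tau2, "SSW_T",
                        df=float(k - 1))


def i_squared(records: Sequence[EffectRecord], tau2: float) -> float:
    """I^2 = 100 tau^2 / (tau^2 + s^2), with s^2 the typical within-study variance.

    s^2 is the Higgins-Thompson form s^2 = (K-1) sum w / ((sum w)^2 - sum w^2),
    w_i = 1/v_i^2.  Reported for completeness only: I^2 depends on the
    studies' precisions, so identical heterogeneity yields higher I^2 in
    larger studies, and it is a poor substitute for tau^2 itself.
    """
    _check(records)
    _, v2 = _arrays(records)
    k = len(records)
    w = 1.0 / v2
    s2 = (k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    return 100.0 * tau2 / (tau2 + s2)
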