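"""Effect measures for two-arm comparative studies: MD and SMD.

A study compares a treatment arm (T) and a control arm (C), each summarised by
(sample size, mean, SD).  The mean difference (MD) lives on the measurement
scale; the standardized mean difference (SMD) divides by the pooled
within-study SD and is estimated by Hedges's g, the bias-corrected version of
Cohen's d.  Every estimator downstream consumes :class:`EffectRecord` objects,
so arm-level data never needs to travel past this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import special

__all__ = [
    "ArmSummary",
    "EffectRecord",
    "DegenerateInputError",
    "md_effect",
    "smd_effect",
    "hedges_j",
    "effective_size",
]

MD = "MD"
SMD = "SMD"


class DegenerateInputError(ValueError):
    """Raised when arm summaries cannot yield a usable effect record."""


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm summary statistics: size ``n``, sample ``mean`` and sample ``sd``.

    ``sd`` is the usual sample standard deviation with divisor ``n - 1``;
    it is accepted as given and never re-derived.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm needs n >= 2 to define a sample variance, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"arm sd must be nonnegative, got {self.sd}")


@dataclass(frozen=True)
class EffectRecord:
    """One study's effect estimate and the quantities estimators need.

    ``estimate`` is y_i (MD) or g_i (SMD); ``variance`` its estimated
    within-study variance v_i^2.  Arm sizes are always kept; arm SDs are kept
    for MD records because the Welch-type corrected moments need them.
    """

    estimate: float
    variance: float
    n_treat: int
    n_control: int
    measure: str
    arm_sd_treat: Optional[float] = None
    arm_sd_control: Optional[float] = None

    def __post_init__(self) -> None:
        if self.measure not in (MD, SMD):
            raise ValueError(f"measure must be 'MD' or 'SMD', got {self.measure!r}")
        if not self.variance > 0:
            raise DegenerateInputError(
                f"within-study variance must be positive, got {self.variance}"
            )
        if self.n_treat < 1 or self.n_control < 1:
            raise ValueError("arm sizes must be positive")
        if self.measure == SMD and self.n_treat + self.n_control < 4:
            raise ValueError(
                "SMD needs n_treat + n_control >= 4 so that m = n - 2 >= 2"
            )

    @property
    def n(self) -> int:
        """Total sample size of the study."""
        return self.n_treat + self.n_control

    @property
    def m(self) -> int:
        """Within-study degrees of freedom n - 2 (SMD)."""
        return self.n - 2

    @property
    def q(self) -> float:
        """Fraction of the study in the control arm."""
        return self.n_control / self.n

    @property
    def has_arm_sds(self) -> bool:
        return self.arm_sd_treat is not None and self.arm_sd_control is not None


def hedges_j(m: float) -> float:
    """Small-sample bias-correction factor J(m) for the SMD.

    J(m) = Gamma(m/2) / ( sqrt(m/2) * Gamma((m-1)/2) ), evaluated on the log
    scale for numerical stability.  The familiar 1 - 3/(4m - 1) is only an
    approximation to this quantity; the exact form is used throughout.
    """
    if m < 2:
        raise ValueError(f"J(m) requires m >= 2, got m={m}")
    return math.exp(
        special.gammaln(m / 2.0) - 0.5 * math.log(m / 2.0) - special.gammaln((m - 1) / 2.0)
    )


def md_effect(treat: ArmSummary, control: ArmSummary) -> EffectRecord:
    """Mean difference y = mean_T - mean_C with variance s_T^2/n_T + s_C^2/n_C."""
    variance = treat.sd**2 / treat.n + control.sd**2 / control.n
    if variance <= 0:
        raise DegenerateInputError(
            "both arm SDs are zero; the MD has no estimable variance"
        )
    return EffectRecord(
        estimate=treat.mean - control.mean,
        variance=variance,
        n_treat=treat.n,
        n_control=control.n,
        measure=MD,
        arm_sd_treat=treat.sd,
        arm_sd_control=control.sd,
    )


def smd_effect(treat: ArmSummary, control: ArmSummary) -> EffectRecord:
    """Hedges's g with its unbiased variance estimator.

    Pools the two arm variances with weights (n_j - 1), multiplies the plug-in
    standardized difference by J(m), and uses
    v^2 = (n_T + n_C)/(n_T n_C) + (1 - (m-2)/(m J(m)^2)) g^2.
    """
    n_t, n_c = treat.n, control.n
    m = n_t + n_c - 2
    if m < 2:
        raise ValueError("SMD needs m = n_T + n_C - 2 >= 2")
    pooled_var = ((n_t - 1) * treat.sd**2 + (n_c - 1) * control.sd**2) / m
    if pooled_var <= 0:
        raise DegenerateInputError("pooled SD is zero; SMD is undefined")
    j = hedges_j(m)
    g = j * (treat.mean - control.mean) / math.sqrt(pooled_var)
    variance = (n_t + n_c) / (n_t * n_c) + (1.0 - (m - 2.0) / (m * j**2)) * g**2
    return EffectRecord(
        estimate=g,
        variance=variance,
        n_treat=n_t,
        n_control=n_c,
        measure=SMD,
        arm_sd_treat=treat.sd,
        arm_sd_control=control.sd,
    )


def effective_size(record: EffectRecord) -> float:
    """Effective sample size n_T n_C / (n_T + n_C) of one study."""
    return record.n_treat * record.n_control / (record.n_treat + record.n_control)
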