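"""CSV input/output, the packaged OCD example dataset, and the analyze workflow.

Two CSV schemas are accepted:

* ``arm_level`` — study_id, n_treat, mean_treat, sd_treat, n_control,
  mean_control, sd_control; rows are converted through the effect-measure
  functions.
* ``effect_level`` — study_id, estimate, variance, n_treat, n_control
  [, sd_treat, sd_control]; effects are taken as given.

The packaged fixture is the 24-trial meta-analysis of psychological
treatments for obsessive-compulsive disorder (SMD scale, Hedges's g with its
printed variances).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .effect_measures import (
    MD,
    SMD,
    ArmSummary,
    EffectRecord,
    md_effect,
    smd_effect,
)
from . import pooling
from . import tau2_estimation as t2
from .q_moments import InsufficientStudiesError

__all__ = [
    "Dataset",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "load_ocd_example",
    "analyze",
    "AnalysisReport",
]

log = logging.getLogger("metaq")

ARM_COLUMNS = [
    "study_id", "n_treat", "mean_treat", "sd_treat",
    "n_control", "mean_control", "sd_control",
]
EFFECT_COLUMNS = ["study_id", "estimate", "variance", "n_treat", "n_control"]


class ValidationError(ValueError):
    """Input data failed validation; the message names the offending row."""


@dataclass
class Dataset:
    """A validated collection of effect records with one common measure."""

    study_ids: List[str]
    records: List[EffectRecord]
    measure: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.study_ids)) != len(self.study_ids):
            raise ValidationError("study_id values must be unique")
        for sid, r in zip(self.study_ids, self.records):
            if r.measure != self.measure:
                raise ValidationError(f"study {sid}: measure {r.measure} != {self.measure}")

    def __len__(self) -> int:
        return len(self.records)


def read_dataset(path, schema: str, measure: str = SMD, provenance: str = "") -> Dataset:
    """Read a CSV in the given schema and return a validated Dataset."""
    if schema not in ("arm_level", "effect_level"):
        raise ValueError("schema must be 'arm_level' or 'effect_level'")
    if measure not in (MD, SMD):
        raise ValueError("measure must be 'MD' or 'SMD'")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    required = ARM_COLUMNS if schema == "arm_level" else EFFECT_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    ids: List[str] = []
    records: List[EffectRecord] = []
    for idx, row in frame.iterrows():
        try:
            if schema == "arm_level":
                treat = ArmSummary(int(row.n_treat), float(row.mean_treat), float(row.sd_treat))
                ctrl = ArmSummary(
                    int(row.n_control), float(row.mean_control), float(row.sd_control)
                )
                rec = md_effect(treat, ctrl) if measure == MD else smd_effect(treat, ctrl)
            else:
                sd_t = float(row.sd_treat) if "sd_treat" in frame.columns else None
                sd_c = float(row.sd_control) if "sd_control" in frame.columns else None
                rec = EffectRecord(
                    estimate=float(row.estimate),
                    variance=float(row.variance),
                    n_treat=int(row.n_treat),
                    n_control=int(row.n_control),
                    measure=measure,
                    arm_sd_treat=sd_t,
                    arm_sd_control=sd_c,
                )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: row {idx} (study {row.study_id}): {exc}") from exc
        ids.append(str(row.study_id))
        records.append(rec)
    return Dataset(ids, records, measure, provenance or str(path))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset in the effect_level schema at full precision."""
    rows = []
    for sid, r in zip(dataset.study_ids, dataset.records):
        row = dict(
            study_id=sid, estimate=repr(r.estimate), variance=repr(r.variance),
            n_treat=r.n_treat, n_control=r.n_control,
        )
        if r.has_arm_sds:
            row["sd_treat"] = repr(r.arm_sd_treat)
            row["sd_control"] = repr(r.arm_sd_control)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ocd_example() -> Dataset:
    """The 24-study OCD psychological-treatment meta-analysis (SMD)."""
    ref = resources.files("metaq").joinpath("data/ocd_smd.csv")
    with ref.open("rb") as fh:
        return read_dataset(
            io.BytesIO(fh.read()), "effect_level", SMD,
            provenance="OCD psychological treatments, 24 trials",
        )


# ---------------------------------------------------------------------------
# The analyze workflow
# ---------------------------------------------------------------------------

_DEFAULT_TAU2 = {"MD": ["DL", "REML", "MP", "J", "WT", "CDL"],
                 "SMD": ["DL", "REML", "MP", "J", "KDB"]}
_DEFAULT_CI = {"MD": ["QP", "PL", "BJ", "J", "WT"],
               "SMD": ["QP", "PL", "BJ", "J", "KDB"]}
_MEASURE_ONLY = {"WT": MD, "CDL": MD, "KDB": SMD}
# which tau^2 point method each tau^2 interval naturally accompanies
_CI_PAIRING = {"QP": "MP", "PL": "REML", "BJ": "DL", "J": "J", "WT": "WT", "KDB": "KDB"}


@dataclass
class AnalysisReport:
    """Tidy results of a full analysis; renders as a CSV frame or a text table."""

    measure: str
    k: int
    level: float
    q_classical: float
    i2: float
    tau2: Dict[str, t2.Tau2Result] = field(default_factory=dict)
    tau2_ci: Dict[str, t2.IntervalResult] = field(default_factory=dict)
    pooled: Dict[str, pooling.PooledResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, r in self.tau2.items():
            ci = self.tau2_ci.get(_reverse_pairing(name))
            rows.append(dict(
                kind="tau2", method=name, estimate=r.estimate,
                lower=ci.lower if ci else np.nan, upper=ci.upper if ci else np.nan,
                converged=r.converged, untruncated=r.untruncated,
            ))
        for name, ci in self.tau2_ci.items():
            rows.append(dict(kind="tau2_ci", method=name, estimate=np.nan,
                             lower=ci.lower, upper=ci.upper, converged=True,
                             untruncated=np.nan))
        for name, p in self.pooled.items():
            rows.append(dict(kind="effect", method=name, estimate=p.estimate,
                             lower=p.lower, upper=p.upper, converged=True,
                             untruncated=np.nan))
        return pd.DataFrame(rows)

    def text_table(self) -> str:
        """Plain-text summary laid out method x (tau2, CI, effect, CI, width)."""
        out = [
            f"Random-effects meta-analysis ({self.measure}), K = {self.k} studies",
            f"Classical Q = {self.q_classical:.4f}   "
            f"I^2 = {self.i2:.1f}% (discouraged; precision-dependent)",
            "",
            f"{'method':<12}{'tau^2':>8}{'L':>8}{'U':>8}   "
            f"{'effect':>8}{'L':>8}{'U':>8}{'width':>8}",
        ]

        def fmt(x):
            return f"{x:8.4f}" if x is not None and np.isfinite(x) else " " * 8

        for name, r in self.tau2.items():
            ci = self.tau2_ci.get(_reverse_pairing(name))
            pooled = self.pooled.get(f"IV-{name}")
            line = f"{name + '&IV':<12}" + fmt(r.estimate)
            line += fmt(ci.lower if ci else None) + fmt(ci.upper if ci else None) + "   "
            if pooled:
                line += fmt(pooled.estimate) + fmt(pooled.lower) + fmt(pooled.upper)
                line += fmt(pooled.width)
            out.append(line)
        for name, p in self.pooled.items():
            if name.startswith("IV-"):
                continue
            line = f"{name:<12}" + " " * 27
            line += fmt(p.estimate) + fmt(p.lower) + fmt(p.upper) + fmt(p.width)
            out.append(line)
        return "\n".join(out)


def _reverse_pairing(tau2_method: str) -> str:
    for ci, tm in _CI_PAIRING.items():
        if tm == tau2_method:
            return ci
    return ""


def analyze(
    dataset: Dataset,
    tau2_methods: Optional[Sequence[str]] = None,
    ci_methods: Optional[Sequence[str]] = None,
    pool_methods: Sequence[str] = ("FE", "IV", "HKSJ", "SSW"),
    level: float = 0.95,
) -> AnalysisReport:
    """Run the requested tau^2 and pooled-effect estimators on a dataset.

    Measure/method incompatibilities (for instance WT on SMD data) are
    refused with an explicit message.  The report contains every requested
    combination; IV pooling is computed at each tau^2 point estimate, HKSJ at
    the DL and (when available) WT/KDB estimates, and SSW at the
    recommended corrected estimate (CDL for MD, KDB for SMD, otherwise MP).
    """
    records = dataset.records
    if len(records) < 2:
        raise InsufficientStudiesError("analysis needs at least two studies")
    measure = dataset.measure
    tau2_methods = list(tau2_methods or _DEFAULT_TAU2[measure])
    ci_methods = list(ci_methods or _DEFAULT_CI[measure])
    for name in list(tau2_methods) + list(ci_methods):
        req = _MEASURE_ONLY.get(name)
        if req and req != measure:
            raise ValueError(
                f"method {name} is defined only for {req} data, but the dataset is {measure}"
            )

    report = AnalysisReport(
        measure=measure, k=len(records), level=level,
        q_classical=t2.cochran_q(records, 0.0), i2=np.nan,
    )
    for name in tau2_methods:
        res = t2.tau2_estimate(records, name)
        report.tau2[name] = res
        log.info("tau2[%s] = %.6f (converged=%s, untruncated=%.6f)",
                 name, res.estimate, res.converged, res.untruncated)
    for name in ci_methods:
        ci = t2.tau2_interval(records, name, level)
        report.tau2_ci[name] = ci
        log.info("tau2 CI[%s] = (%.6f, %.6f) note=%s", name, ci.lower, ci.upper,
                 ci.boundary_note)

    ref_tau2 = report.tau2.get("DL", next(iter(report.tau2.values()))).estimate
    report.i2 = pooling.i_squared(records, ref_tau2)

    for name in pool_methods:
        if name == "FE":
            report.pooled["FE"] = pooling.pool_iv(records, 0.0, level)
        elif name == "IV":
            for tname, tres in report.tau2.items():
                report.pooled[f"IV-{tname}"] = pooling.pool_iv(records, tres.estimate, level)
        elif name == "HKSJ":
            for tname in ("DL", "WT", "KDB"):
                if tname in report.tau2:
                    report.pooled[f"HKSJ-{tname}"] = pooling.pool_hksj(
                        records, report.tau2[tname].estimate, level
                    )
        elif name == "SSW":
            for pref in ("CDL", "KDB", "MP", "DL"):
                if pref in report.tau2:
                    report.pooled[f"SSW-{pref}"] = pooling.pool_ssw(
                        records, report.tau2[pref].estimate, level
                    )
                    break
        else:
            raise ValueError(f"unknown pooling method {name!r}")
    return report
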