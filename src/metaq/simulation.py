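"""Generative models and the factorial evaluation harness.

The data-generating mechanisms mirror the random-effects model exactly:

* MD — per-arm sample variances are drawn as sigma^2 chi2_{n-1}/(n-1) and the
  estimated mean difference as N(mu, sigma_T^2/n_T + sigma_C^2/n_C + tau^2);
  the estimate is independent of its estimated variance.
* SMD — true effects delta_i ~ N(delta, tau^2), then Hedges's g is drawn
  directly from its exact scaled noncentral-t distribution and the variance
  estimator is the deterministic Hedges formula in g.

Seeding uses numpy SeedSequence spawning with per-(configuration, replicate)
keys, so any single replicate is reproducible in isolation and results do not
depend on how replications are chunked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .effect_measures import MD, SMD, EffectRecord, hedges_j
from . import tau2_estimation as t2
from . import pooling

__all__ = [
    "SimConfig",
    "UNEQUAL_PATTERNS",
    "simulate_md",
    "simulate_smd",
    "simulate_meta",
    "run_grid",
    "coverage_mc_se",
]

# Unequal-size patterns (mean size -> the five study totals); for K = 10 or 30
# the same set is used two or six times.
UNEQUAL_PATTERNS: Dict[int, Tuple[int, ...]] = {
    30: (12, 16, 18, 20, 84),
    60: (24, 32, 36, 40, 168),
    100: (64, 72, 76, 80, 208),
    160: (124, 132, 136, 140, 268),
}


@dataclass(frozen=True)
class SimConfig:
    """One cell of the simulation design.

    ``sizes`` holds the per-study total sample sizes; ``q`` the control-arm
    fraction (arm sizes are n_T = ceil((1-q) n), n_C = n - n_T).  ``effect``
    is mu for MD and delta for SMD; ``sigma2_treat``/``sigma2_control`` are
    used for MD only.
    """

    measure: str
    sizes: Tuple[int, ...]
    q: float = 0.5
    effect: float = 0.0
    tau2: float = 0.0
    sigma2_treat: float = 1.0
    sigma2_control: float = 1.0

    @staticmethod
    def equal(measure: str, k: int, n: int, **kw) -> "SimConfig":
        return SimConfig(measure=measure, sizes=(n,) * k, **kw)

    @staticmethod
    def unequal(measure: str, k: int, nbar: int, **kw) -> "SimConfig":
        pat = UNEQUAL_PATTERNS[nbar]
        if k % len(pat):
            raise ValueError(f"K={k} is not a multiple of the pattern length {len(pat)}")
        return SimConfig(measure=measure, sizes=pat * (k // len(pat)), **kw)

    @property
    def k(self) -> int:
        return len(self.sizes)

    def arm_sizes(self) -> Tuple[np.ndarray, np.ndarray]:
        n = np.asarray(self.sizes, dtype=int)
        n_t = np.ceil((1.0 - self.q) * n).astype(int)
        return n_t, n - n_t


def simulate_md(config: SimConfig, rng: np.random.Generator) -> List[EffectRecord]:
    """Draw one MD meta-analysis: chi-square arm variances, normal estimates."""
    if config.measure != MD:
        raise ValueError("config.measure must be 'MD'")
    n_t, n_c = config.arm_sizes()
    s2_t = config.sigma2_treat * rng.chisquare(n_t - 1) / (n_t - 1)
    s2_c = config.sigma2_control * rng.chisquare(n_c - 1) / (n_c - 1)
    total_var = config.sigma2_treat / n_t + config.sigma2_control / n_c + config.tau2
    y = rng.normal(config.effect, np.sqrt(total_var))
    v2 = s2_t / n_t + s2_c / n_c
    return [
        EffectRecord(
            estimate=float(y[i]),
            variance=float(v2[i]),
            n_treat=int(n_t[i]),
            n_control=int(n_c[i]),
            measure=MD,
            arm_sd_treat=float(np.sqrt(s2_t[i])),
            arm_sd_control=float(np.sqrt(s2_c[i])),
        )
        for i in range(config.k)
    ]


def simulate_smd(config: SimConfig, rng: np.random.Generator) -> List[EffectRecord]:
    """Draw one SMD meta-analysis from the exact noncentral-t model for g."""
    if config.measure != SMD:
        raise ValueError("config.measure must be 'SMD'")
    n_t, n_c = config.arm_sizes()
    n = n_t + n_c
    m = n - 2
    ntilde = n_t * n_c / n
    j = np.array([hedges_j(mi) for mi in m])
    delta_i = rng.normal(config.effect, math.sqrt(config.tau2), size=config.k)
    ncp = np.sqrt(ntilde) * delta_i
    z = rng.standard_normal(config.k)
    chi2 = rng.chisquare(m)
    t_nc = (z + ncp) / np.sqrt(chi2 / m)
    g = j * t_nc / np.sqrt(ntilde)
    v2 = (n_t + n_c) / (n_t * n_c) + (1.0 - (m - 2.0) / (m * j**2)) * g**2
    return [
        EffectRecord(
            estimate=float(g[i]),
            variance=float(v2[i]),
            n_treat=int(n_t[i]),
            n_control=int(n_c[i]),
            measure=SMD,
        )
        for i in range(config.k)
    ]


def simulate_meta(config: SimConfig, rng: np.random.Generator) -> List[EffectRecord]:
    """Dispatch on the configured effect measure."""
    return simulate_md(config, rng) if config.measure == MD else simulate_smd(config, rng)


def coverage_mc_se(level: float, reps: int) -> float:
    """Monte-Carlo standard error of an estimated coverage at the nominal level."""
    return math.sqrt(level * (1.0 - level) / reps)


def _rep_rng(seed: int, config_index: int, rep: int) -> np.random.Generator:
    """Independent substream for one (configuration, replicate) pair."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(config_index, rep))
    )


def run_grid(
    configs: Sequence[SimConfig],
    reps: int = 2000,
    seed: int = 0,
    tau2_methods: Sequence[str] = ("DL", "REML", "MP", "J"),
    interval_methods: Sequence[str] = (),
    pool_methods: Sequence[str] = ("IV",),
    level: float = 0.95,
    use_untruncated: bool = False,
    progress: Optional[Callable[[int, int], None]] = None,
) -> pd.DataFrame:
    """Evaluate estimators over a factorial grid; returns a tidy DataFrame.

    For each configuration x tau^2 point method: bias and MSE of the
    estimate; for interval methods: empirical coverage of the true tau^2 and
    mean width; for pooling (IV uses each tau^2 method in turn, SSW pairs
    with the last tau^2 method listed): bias of the effect estimate and
    coverage of the true effect.  Replicate-level estimator failures are
    counted, never fatal.
    """
    rows = []
    for ci, cfg in enumerate(configs):
        acc: Dict[Tuple[str, str], List[float]] = {}
        failures: Dict[str, int] = {}

        def add(kind: str, name: str, value: float) -> None:
            acc.setdefault((kind, name), []).append(value)

        for rep in range(reps):
            rng = _rep_rng(seed, ci, rep)
            records = simulate_meta(cfg, rng)
            tau_hat: Dict[str, float] = {}
            for name in tau2_methods:
                try:
                    res = t2.tau2_estimate(records, name)
                    est = res.untruncated if use_untruncated else res.estimate
                    tau_hat[name] = res.estimate
                    add("tau2", name, est)
                except Exception:
                    failures[name] = failures.get(name, 0) + 1
            for name in interval_methods:
                try:
                    iv = t2.tau2_interval(records, name, level)
                    add("tau2_cover", name, float(iv.lower <= cfg.tau2 <= iv.upper))
                    add("tau2_width", name, iv.upper - iv.lower)
                except Exception:
                    failures["ci_" + name] = failures.get("ci_" + name, 0) + 1
            for name in pool_methods:
                try:
                    if name == "IV":
                        for tname, th in tau_hat.items():
                            pr = pooling.pool_iv(records, th, level)
                            add("effect", f"IV-{tname}", pr.estimate)
                            add("effect_cover", f"IV-{tname}",
                                float(pr.lower <= cfg.effect <= pr.upper))
                    elif name == "HKSJ":
                        for tname, th in tau_hat.items():
                            pr = pooling.pool_hksj(records, th, level)
                            add("effect", f"HKSJ-{tname}", pr.estimate)
                            add("effect_cover", f"HKSJ-{tname}",
                                float(pr.lower <= cfg.effect <= pr.upper))
                    elif name == "SSW":
                        th = tau_hat[list(tau_hat)[-1]] if tau_hat else 0.0
                        pr = pooling.pool_ssw(records, th, level)
                        add("effect", "SSW", pr.estimate)
                        add("effect_cover", "SSW",
                            float(pr.lower <= cfg.effect <= pr.upper))
                    elif name == "FE":
                        pr = pooling.pool_iv(records, 0.0, level)
                        add("effect", "FE", pr.estimate)
                        add("effect_cover", "FE", float(pr.lower <= cfg.effect <= pr.upper))
                except Exception:
                    failures[name] = failures.get(name, 0) + 1
            if progress is not None:
                progress(ci, rep)

        base = dict(
            measure=cfg.measure, K=cfg.k, n_mean=float(np.mean(cfg.sizes)), q=cfg.q,
            effect=cfg.effect, tau2=cfg.tau2, reps=reps,
        )
        for (kind, name), vals in acc.items():
            arr = np.asarray(vals)
            if kind == "tau2":
                rows.append(dict(base, method=name, metric="tau2_bias",
                                 value=arr.mean() - cfg.tau2, n_ok=len(arr)))
                rows.append(dict(base, method=name, metric="tau2_mse",
                                 value=float(np.mean((arr - cfg.tau2) ** 2)), n_ok=len(arr)))
            elif kind == "effect":
                rows.append(dict(base, method=name, metric="effect_bias",
                                 value=arr.mean() - cfg.effect, n_ok=len(arr)))
                rows.append(dict(base, method=name, metric="effect_mse",
                                 value=float(np.mean((arr - cfg.effect) ** 2)), n_ok=len(arr)))
            elif kind.endswith("_cover"):
                rows.append(dict(base, method=name, metric=kind,
                                 value=arr.mean(), n_ok=len(arr),
                                 mc_se=coverage_mc_se(level, len(arr))))
            elif kind.endswith("_width"):
                rows.append(dict(base, method=name, metric=kind,
                                 value=arr.mean(), n_ok=len(arr)))
        for name, cnt in failures.items():
            rows.append(dict(base, method=name, metric="failures", value=cnt, n_ok=reps))
    return pd.DataFrame(rows)
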