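"""Publication-bias diagnostics and leave-one-out sensitivity analysis.

Two classical small-study-effect tests operate on per-study log odds
ratios and their variances:

* **Begg-Mazumdar rank correlation** — Kendall's S between the
  variance-standardized deviations from the fixed-effect mean and the
  study variances, normalized by the tie-corrected Kendall variance.
  A significant correlation suggests that smaller (higher-variance)
  studies report systematically different effects.
* **Egger regression** — ordinary least squares of the standardized
  effect theta_i/se_i on precision 1/se_i.  Under no small-study
  effect the line passes through the origin; the intercept's t test
  (k - 2 df) quantifies funnel asymmetry.

Leave-one-out sensitivity analysis re-pools the corpus k times, each
time omitting one study, to show whether any single study drives the
pooled conclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd
from scipy.stats import linregress
from scipy.stats import norm as _norm
from scipy.stats import t as _t_dist

from .data_model import GeneticModel, GenotypeCountRecord, ValidationError
from .pooling import MetaConfig, PooledResult, StudyEffect, meta_analyze


@dataclass(frozen=True)
class BeggResult:
    z: float
    p: float
    s: int
    k: int


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p: float
    slope: float
    k: int


@dataclass(frozen=True)
class BiasTestResult:
    """One published-bias table row: Begg's z/p and Egger's t/p."""

    begg_z: float
    begg_p: float
    egger_intercept: float
    egger_se: float
    egger_t: float
    egger_p: float
    k: int


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_study_id: str
    result: PooledResult


@dataclass(frozen=True)
class LeaveOneOutAnalysis:
    """All k omission re-analyses plus the pooled-OR range they span."""

    results: tuple[LeaveOneOutResult, ...]
    or_min: float
    or_max: float

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)


def _kendall_s_and_var(x: Sequence[float], y: Sequence[float]) -> tuple[int, float]:
    """Kendall's S for paired sequences and its tie-corrected variance."""
    k = len(x)
    s = 0
    for i in range(k):
        for j in range(i + 1, k):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            prod = dx * dy
            if prod > 0:
                s += 1
            elif prod < 0:
                s -= 1

    def tie_sizes(values):
        counts: dict[float, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        return [c for c in counts.values() if c > 1]

    tx, ty = tie_sizes(x), tie_sizes(y)
    v0 = k * (k - 1) * (2 * k + 5)
    vt = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in ty)
    var = (v0 - vt - vu) / 18.0
    if k > 2:
        var += (sum(t * (t - 1) * (t - 2) for t in tx)
                * sum(u * (u - 1) * (u - 2) for u in ty)
                ) / (9.0 * k * (k - 1) * (k - 2))
    var += (sum(t * (t - 1) for t in tx) * sum(u * (u - 1) for u in ty)
            ) / (2.0 * k * (k - 1))
    return s, var


def begg_test(effects: Sequence[StudyEffect],
              continuity: bool = False) -> BeggResult:
    """Begg-Mazumdar adjusted rank-correlation test.

    Each effect is standardized against the fixed-effect mean,
    t_i = (theta_i - theta_hat) / sqrt(v_i - v_hat), and Kendall's S
    between t_i and v_i is normalized by the tie-corrected variance.
    ``continuity`` subtracts 1 from |S| before normalizing (the
    continuity-corrected variant); the default matches the classical
    uncorrected statistic.
    """
    k = len(effects)
    if k < 3:
        raise ValidationError("insufficient studies for Begg's test (k >= 3)")
    variances = [e.variance for e in effects]
    weights = [1.0 / v for v in variances]
    total = sum(weights)
    mean = sum(w * e.log_or for w, e in zip(weights, effects)) / total
    v_hat = 1.0 / total
    std = [(e.log_or - mean) / math.sqrt(e.variance - v_hat) for e in effects]
    s, var = _kendall_s_and_var(std, variances)
    if var <= 0:
        return BeggResult(z=0.0, p=1.0, s=s, k=k)
    if continuity and s != 0:
        z = (abs(s) - 1) / math.sqrt(var) * (1 if s > 0 else -1)
    else:
        z = s / math.sqrt(var)
    p = float(2 * _norm.sf(abs(z)))
    return BeggResult(z=z, p=min(p, 1.0), s=s, k=k)


def egger_test(effects: Sequence[StudyEffect]) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise ValidationError("insufficient studies for Egger's test (k >= 3)")
    precision = [1.0 / e.se for e in effects]
    standardized = [e.log_or / e.se for e in effects]
    if max(precision) == min(precision):
        raise ValidationError(
            "all precisions identical: Egger regression is degenerate")
    fit = linregress(precision, standardized)
    intercept = float(fit.intercept)
    se = float(fit.intercept_stderr)
    if se == 0.0:
        # exact fit: the t statistic degenerates
        t_stat = math.inf if intercept != 0 else 0.0
        p = 0.0 if intercept != 0 else 1.0
    else:
        t_stat = intercept / se
        p = float(2 * _t_dist.sf(abs(t_stat), df=k - 2))
    return EggerResult(intercept=intercept, se=se, t=t_stat, p=p,
                       slope=float(fit.slope), k=k)


def bias_tests(effects: Sequence[StudyEffect]) -> BiasTestResult:
    """Run both publication-bias tests on one set of study effects."""
    begg = begg_test(effects)
    egger = egger_test(effects)
    return BiasTestResult(
        begg_z=begg.z, begg_p=begg.p,
        egger_intercept=egger.intercept, egger_se=egger.se,
        egger_t=egger.t, egger_p=egger.p,
        k=len(effects),
    )


def leave_one_out(records: Sequence[GenotypeCountRecord],
                  model: Union[GeneticModel, str],
                  config: Optional[MetaConfig] = None) -> LeaveOneOutAnalysis:
    """Re-pool k times, omitting each study in turn."""
    if len(records) < 2:
        raise ValidationError("leave-one-out needs at least 2 studies")
    results = []
    for i, omitted in enumerate(records):
        subset = [r for j, r in enumerate(records) if j != i]
        results.append(LeaveOneOutResult(
            omitted_study_id=omitted.study_id,
            result=meta_analyze(subset, model, config)))
    ors = [r.result.or_ for r in results]
    return LeaveOneOutAnalysis(results=tuple(results),
                               or_min=min(ors), or_max=max(ors))


def funnel_data(effects: Sequence[StudyEffect]) -> pd.DataFrame:
    """Per-study funnel-plot coordinates (no statistics computed)."""
    if not effects:
        raise ValidationError("no effects")
    return pd.DataFrame({
        "study_id": [e.study_id for e in effects],
        "log_or": [e.log_or for e in effects],
        "se": [e.se for e in effects],
        "precision": [1.0 / e.se for e in effects],
        "standardized_effect": [e.log_or / e.se for e in effects],
    })
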