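"""Fixed- and random-effects pooling of 2x2 tables.

One call to :func:`meta_analyze` reproduces one row of a classical
case-control meta-analysis table: pooled odds ratio with 95% CI, the
normal z statistic and two-sided association p-value, Cochran's Q with
its p-value, I-squared, and the between-study variance tau^2.

Model selection follows the conventional decision rule: a fixed-effect
Mantel-Haenszel pool is reported when the heterogeneity p-value exceeds
0.05 *and* I-squared is below 50%; otherwise a DerSimonian-Laird
random-effects (inverse-variance with moment tau^2) pool is reported.

Numerical conventions
---------------------
* Per-study log odds ratios use the Haldane-Anscombe correction: if any
  cell of a study's table is zero, 0.5 is added to all four cells of
  that table before taking logs.  The Mantel-Haenszel sums themselves
  are computed on uncorrected counts (zero cells simply contribute
  zero terms), as in standard software.
* The standard error of the Mantel-Haenszel log odds ratio is the
  Robins-Breslow-Greenland estimator, which remains consistent both
  with sparse strata and with few large strata.
* Cochran's Q uses inverse-variance weights about the inverse-variance
  fixed-effect mean (the form the DerSimonian-Laird moment estimator
  requires), regardless of which estimate is reported.
* k = 1 conventions: Q = 0, df = 0, p_het = 1, I-squared = 0, fixed
  effect.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm

from .data_model import (
    GeneticModel,
    GenotypeCountRecord,
    TwoByTwoTable,
    ValidationError,
    build_contrast,
)


class PoolingMethod(str, enum.Enum):
    FIXED_MH = "fixed_MH"
    RANDOM_DL = "random_DL"


@dataclass(frozen=True)
class MetaConfig:
    """Tunable thresholds of the pipeline.

    ci_level
        Confidence level of the pooled interval (default 0.95).
    het_p_threshold, i2_threshold_pct
        The fixed/random decision rule: fixed effect iff the Q p-value
        exceeds ``het_p_threshold`` and I-squared is below
        ``i2_threshold_pct``.
    continuity_correction
        Value added to every cell of a zero-cell table before the
        per-study log odds ratio (Haldane-Anscombe; default 0.5).
    hwe_alpha
        Significance level of the control-arm HWE eligibility filter.
    """

    ci_level: float = 0.95
    het_p_threshold: float = 0.05
    i2_threshold_pct: float = 50.0
    continuity_correction: float = 0.5
    hwe_alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must be in (0, 1)")
        if not 0 <= self.het_p_threshold <= 1:
            raise ValidationError("het_p_threshold must be in [0, 1]")
        if not 0 <= self.i2_threshold_pct <= 100:
            raise ValidationError("i2_threshold_pct must be in [0, 100]")
        if self.continuity_correction < 0:
            raise ValidationError("continuity_correction must be >= 0")


@dataclass(frozen=True)
class StudyEffect:
    """One study's log odds ratio and its standard error."""

    study_id: str
    log_or: float
    se: float
    corrected: bool = False

    def __post_init__(self):
        if not self.se > 0:
            raise ValidationError("standard error must be positive")

    @property
    def variance(self) -> float:
        return self.se * self.se


@dataclass(frozen=True)
class PooledResult:
    """One pooled analysis: estimate, CI, association test, heterogeneity."""

    or_: float
    ci_low: float
    ci_high: float
    z: float
    p_assoc: float
    q: float
    df: int
    p_het: float
    i2_pct: float
    tau2: float
    method: PoolingMethod
    k: int
    n_case: int
    n_ctrl: int
    se: float = field(default=float("nan"))

    @property
    def log_or(self) -> float:
        return math.log(self.or_)


def study_effect(table: TwoByTwoTable, correction: float = 0.5,
                 study_id: str = "") -> StudyEffect:
    """Log odds ratio and Woolf standard error for one 2x2 table.

    A zero anywhere triggers the Haldane-Anscombe correction on all
    four cells.  A table with two or more empty margins carries no
    information about the odds ratio and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = (a + b, c + d, a + c, b + d)
    if sum(m == 0 for m in margins) >= 2:
        raise ValidationError("table has no information (two empty margins)")
    corrected = table.has_zero_cell()
    if corrected:
        if correction <= 0:
            raise ValidationError(
                "zero cell present but continuity correction is disabled")
        a, b, c, d = a + correction, b + correction, c + correction, d + correction
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return StudyEffect(study_id=study_id, log_or=log_or, se=se,
                       corrected=corrected)


def mantel_haenszel_pool(
    tables: Sequence[TwoByTwoTable],
) -> tuple[float, float]:
    """Mantel-Haenszel pooled log odds ratio and its RBG standard error.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the variance of its
    log is the Robins-Breslow-Greenland estimator.  No continuity
    correction is applied inside the sums.
    """
    if not tables:
        raise ValidationError("no tables to pool")
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    for t in tables:
        n = t.n
        if n <= 0:
            raise ValidationError("table with zero total")
        P = (t.a + t.d) / n
        Q = (t.b + t.c) / n
        Ri = t.a * t.d / n
        Si = t.b * t.c / n
        R += Ri
        S += Si
        sum_PR += P * Ri
        sum_PSQR += P * Si + Q * Ri
        sum_QS += Q * Si
    if S == 0:
        raise ValidationError("Mantel-Haenszel odds ratio is infinite "
                              "(no unexposed-case/exposed-control mass)")
    if R == 0:
        raise ValidationError("Mantel-Haenszel odds ratio is zero "
                              "(no exposed-case/unexposed-control mass)")
    log_or = math.log(R / S)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    return log_or, math.sqrt(var)


def inverse_variance_pool(effects: Sequence[StudyEffect],
                          tau2: float = 0.0) -> tuple[float, float]:
    """Inverse-variance pooled log odds ratio; tau2 > 0 gives the
    DerSimonian-Laird random-effects pool."""
    if not effects:
        raise ValidationError("no effects to pool")
    weights = [1.0 / (e.variance + tau2) for e in effects]
    total = sum(weights)
    log_or = sum(w * e.log_or for w, e in zip(weights, effects)) / total
    return log_or, 1.0 / math.sqrt(total)


def cochran_q(
    effects: Sequence[StudyEffect],
) -> tuple[float, int, float, float]:
    """Cochran's Q about the fixed-effect inverse-variance mean.

    Returns ``(q, df, p_het, i2_pct)`` with
    I^2 = max(0, (Q - df)/Q) * 100 (zero when Q = 0).
    """
    k = len(effects)
    if k == 0:
        raise ValidationError("no effects")
    if k == 1:
        return 0.0, 0, 1.0, 0.0
    weights = [1.0 / e.variance for e in effects]
    total = sum(weights)
    mean = sum(w * e.log_or for w, e in zip(weights, effects)) / total
    q = sum(w * (e.log_or - mean) ** 2 for w, e in zip(weights, effects))
    df = k - 1
    p_het = float(_chi2_dist.sf(q, df=df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, p_het, i2


def dersimonian_laird_tau2(effects: Sequence[StudyEffect]) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance,
    truncated at zero."""
    k = len(effects)
    if k < 2:
        return 0.0
    weights = [1.0 / e.variance for e in effects]
    total = sum(weights)
    q, df, _, _ = cochran_q(effects)
    denom = total - sum(w * w for w in weights) / total
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def select_method(q_p: float, i2_pct: float,
                  config: Optional[MetaConfig] = None) -> PoolingMethod:
    """Fixed effect iff heterogeneity is both non-significant and mild."""
    config = config or MetaConfig()
    if q_p > config.het_p_threshold and i2_pct < config.i2_threshold_pct:
        return PoolingMethod.FIXED_MH
    return PoolingMethod.RANDOM_DL


def study_effects(records: Sequence[GenotypeCountRecord],
                  model: Union[GeneticModel, str],
                  config: Optional[MetaConfig] = None) -> list[StudyEffect]:
    """Per-study corrected effects under one genetic model."""
    config = config or MetaConfig()
    return [
        study_effect(build_contrast(rec, model),
                     correction=config.continuity_correction,
                     study_id=rec.study_id)
        for rec in records
    ]


def meta_analyze(records: Sequence[GenotypeCountRecord],
                 model: Union[GeneticModel, str],
                 config: Optional[MetaConfig] = None) -> PooledResult:
    """Pool one SNP's studies under one genetic model.

    Heterogeneity (Q, I^2, tau^2) is assessed on per-study corrected
    effects; the reported estimate is Mantel-Haenszel when the fixed
    model is selected and DerSimonian-Laird inverse-variance when the
    random model is selected.  Reported sample sizes are full subject
    counts for every model (including those whose 2x2 table excludes a
    genotype class).
    """
    if not records:
        raise ValidationError("no studies to meta-analyze")
    config = config or MetaConfig()
    effects = study_effects(records, model, config)
    k = len(effects)
    q, df, p_het, i2 = cochran_q(effects)
    tau2 = dersimonian_laird_tau2(effects)
    method = select_method(p_het, i2, config)

    if method is PoolingMethod.FIXED_MH:
        tables = [build_contrast(rec, model) for rec in records]
        if k == 1 and tables[0].has_zero_cell():
            # a single sparse table: MH without correction is degenerate
            log_or, se = effects[0].log_or, effects[0].se
        else:
            log_or, se = mantel_haenszel_pool(tables)
        tau2_used = 0.0
    else:
        log_or, se = inverse_variance_pool(effects, tau2=tau2)
        tau2_used = tau2

    crit = float(_norm.ppf(0.5 + config.ci_level / 2))
    z = abs(log_or) / se
    p_assoc = float(2 * _norm.sf(z))
    return PooledResult(
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - crit * se),
        ci_high=math.exp(log_or + crit * se),
        z=z,
        p_assoc=p_assoc,
        q=q,
        df=df,
        p_het=p_het,
        i2_pct=i2,
        tau2=tau2_used,
        method=method,
        k=k,
        n_case=sum(r.n_case for r in records),
        n_ctrl=sum(r.n_ctrl for r in records),
        se=se,
    )


def z_from_or_ci(or_: float, lo: float, hi: float,
                 ci_level: float = 0.95) -> float:
    """Back out the association z statistic from a printed OR and CI.

    The CI is assumed symmetric on the log scale, so
    se = (ln hi - ln lo) / (2 * z_crit) and z = |ln OR| / se.  Useful
    for consistency-checking published tables.
    """
    if not (0 < lo <= or_ <= hi):
        raise ValidationError("require 0 < lo <= OR <= hi")
    if lo >= hi:
        raise ValidationError("degenerate interval")
    crit = float(_norm.ppf(0.5 + ci_level / 2))
    se = (math.log(hi) - math.log(lo)) / (2 * crit)
    return abs(math.log(or_)) / se
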