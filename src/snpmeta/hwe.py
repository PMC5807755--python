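"""Hardy-Weinberg equilibrium screening of control genotype counts.

Departure of the control genotype distribution from Hardy-Weinberg
proportions (p^2, 2pq, q^2 at the sample allele frequency) flags
genotyping error or a non-representative control series, and is a
standard eligibility filter for case-control SNP meta-analysis.  The
test is the Pearson goodness-of-fit chi-square with one degree of
freedom (three genotype classes minus one, minus one estimated allele
frequency); no continuity correction is applied.

A monomorphic sample (allele frequency 0 or 1) carries no information
about equilibrium; by convention it gets chi2 = 0, p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2 as _chi2_dist

from .data_model import GenotypeCountRecord, ValidationError


@dataclass(frozen=True)
class HWEResult:
    """Chi-square HWE test outcome; ``passed`` is p_value > alpha."""

    chi2: float
    p_value: float
    passed: bool
    alpha: float = 0.05


def hwe_chi_square(hom_ref: int, het: int, hom_alt: int,
                   alpha: float = 0.05) -> HWEResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg proportions."""
    n = hom_ref + het + hom_alt
    if n <= 0:
        raise ValidationError("HWE test needs a positive genotype total")
    if not 0 <= alpha <= 1:
        raise ValidationError("alpha must be in [0, 1]")
    p_hat = (2 * hom_alt + het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HWEResult(0.0, 1.0, alpha < 1.0, alpha)
    q_hat = 1.0 - p_hat
    expected = (n * q_hat * q_hat, n * 2 * p_hat * q_hat, n * p_hat * p_hat)
    observed = (hom_ref, het, hom_alt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(_chi2_dist.sf(chi2, df=1))
    return HWEResult(chi2, p_value, p_value > alpha, alpha)


def filter_by_hwe(
    records: Sequence[GenotypeCountRecord], alpha: float = 0.05,
) -> tuple[list[GenotypeCountRecord],
           list[tuple[GenotypeCountRecord, HWEResult]]]:
    """Partition records by whether their *control* genotypes pass HWE.

    Returns ``(kept, dropped)`` where each dropped entry carries the
    failing study's test result, for the exclusion log.
    """
    kept, dropped = [], []
    for rec in records:
        result = hwe_chi_square(rec.ctrl_hom_ref, rec.ctrl_het,
                                rec.ctrl_hom_alt, alpha=alpha)
        if result.passed:
            kept.append(rec)
        else:
            dropped.append((rec, result))
    return kept, dropped
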