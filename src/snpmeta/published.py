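"""Published pooled results for the two CYP4F2 variants.

These are the pooled odds ratios, 95% confidence intervals and z
statistics printed by the published meta-analysis of CYP4F2 rs1558139
(T vs. C and derived genotype contrasts; 10 Asian case-control
studies) and rs2108622 (A vs. G; 17 studies).  The per-study genotype
counts behind them live in that analysis' supplementary material and
are not redistributed here; the rows serve as reference inputs for
internal-consistency checking (a printed z must be recoverable from
the printed OR and CI up to 2-decimal rounding, see
:func:`snpmeta.pooling.z_from_or_ci`).

Two printed rows are internally inconsistent beyond any rounding of
their own numbers (``consistent=False``): the rs2108622
hypertension/homozygote row, whose point estimate lies outside its own
CI, and the rs1558139 population-based/homozygote row, whose OR and CI
duplicate the hypertension row while z and p differ.  They are
excluded from consistency checks as typographic errors.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PublishedRow:
    snp_id: str
    model: str
    subgroup: str
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p_assoc: float
    k: int
    n_case: int
    n_ctrl: int
    i2_pct: float
    consistent: bool = True


def _r(snp, model, sub, or_, lo, hi, z, p, k, ncase, nctrl, i2, ok=True):
    return PublishedRow(snp, model, sub, or_, lo, hi, z, p, k, ncase,
                        nctrl, i2, ok)


#: All pooled rows of the two published summary tables.
PUBLISHED_ROWS: tuple[PublishedRow, ...] = (
    # rs1558139 (T vs. C), 10 studies, 3462 cases / 3547 controls
    _r("rs1558139", "allele", "overall", 0.92, 0.86, 0.99, 2.31, 0.021, 10, 3462, 3547, 0.0),
    _r("rs1558139", "allele", "hypertension", 0.89, 0.81, 0.98, 2.34, 0.019, 4, 1852, 1787, 0.0),
    _r("rs1558139", "allele", "CAD", 1.00, 0.87, 1.14, 0.05, 0.963, 3, 883, 914, 0.0),
    _r("rs1558139", "allele", "population", 0.91, 0.85, 0.98, 2.49, 0.013, 8, 2927, 3033, 0.0),
    _r("rs1558139", "homozygote", "overall", 0.87, 0.76, 1.00, 1.89, 0.058, 10, 3462, 3547, 0.0),
    _r("rs1558139", "homozygote", "hypertension", 0.85, 0.70, 1.04, 1.59, 0.111, 4, 1852, 1787, 0.0),
    _r("rs1558139", "homozygote", "CAD", 0.99, 0.76, 1.30, 0.05, 0.963, 3, 883, 914, 0.0),
    # OR/CI duplicate the hypertension row; z/p incompatible with them
    _r("rs1558139", "homozygote", "population", 0.85, 0.70, 1.04, 1.99, 0.047, 8, 2927, 3033, 0.0, ok=False),
    _r("rs1558139", "heterozygote", "overall", 0.89, 0.80, 0.98, 2.26, 0.024, 10, 3462, 3547, 0.0),
    _r("rs1558139", "heterozygote", "hypertension", 0.81, 0.70, 0.93, 2.95, 0.003, 4, 1852, 1787, 0.0),
    _r("rs1558139", "heterozygote", "CAD", 0.98, 0.79, 1.21, 0.18, 0.857, 3, 883, 914, 0.0),
    _r("rs1558139", "heterozygote", "population", 0.87, 0.78, 0.97, 2.46, 0.014, 8, 2927, 3033, 0.0),
    _r("rs1558139", "dominant", "overall", 0.88, 0.80, 0.97, 2.53, 0.012, 10, 3462, 3547, 0.0),
    _r("rs1558139", "dominant", "hypertension", 0.82, 0.71, 0.93, 2.95, 0.003, 4, 1852, 1787, 0.0),
    _r("rs1558139", "dominant", "CAD", 0.98, 0.80, 1.20, 0.16, 0.871, 3, 883, 914, 0.0),
    _r("rs1558139", "dominant", "population", 0.86, 0.78, 0.96, 2.71, 0.007, 8, 2927, 3033, 0.0),
    _r("rs1558139", "recessive", "overall", 0.93, 0.82, 1.06, 1.03, 0.303, 10, 3462, 3547, 0.0),
    _r("rs1558139", "recessive", "hypertension", 0.95, 0.80, 1.14, 0.52, 0.601, 4, 1852, 1787, 0.0),
    _r("rs1558139", "recessive", "CAD", 1.01, 0.80, 1.28, 0.11, 0.914, 3, 883, 914, 0.0),
    _r("rs1558139", "recessive", "population", 0.92, 0.80, 1.06, 1.14, 0.256, 8, 2927, 3033, 0.0),
    # rs2108622 (A vs. G), 17 studies, 10213 cases / 8033 controls
    _r("rs2108622", "allele", "overall", 0.95, 0.87, 1.04, 1.05, 0.295, 17, 10213, 8033, 69.9),
    _r("rs2108622", "allele", "Asian", 0.95, 0.87, 1.04, 1.16, 0.246, 15, 6352, 5867, 73.0),
    _r("rs2108622", "allele", "CAD", 0.78, 0.68, 0.90, 3.40, 0.001, 5, 1934, 1609, 38.9),
    _r("rs2108622", "allele", "IS", 0.93, 0.74, 1.18, 0.58, 0.564, 4, 1515, 1545, 78.0),
    _r("rs2108622", "allele", "hypertension", 1.07, 0.99, 1.15, 1.69, 0.090, 8, 6764, 4879, 21.8),
    _r("rs2108622", "allele", "population", 0.92, 0.81, 1.05, 1.26, 0.209, 12, 5203, 4584, 73.4),
    _r("rs2108622", "homozygote", "overall", 0.94, 0.76, 1.16, 0.58, 0.561, 17, 10213, 8033, 64.5),
    _r("rs2108622", "homozygote", "Asian", 0.90, 0.71, 1.16, 0.81, 0.418, 15, 6352, 5867, 67.9),
    _r("rs2108622", "homozygote", "CAD", 0.55, 0.39, 0.77, 3.44, 0.001, 5, 1934, 1609, 24.9),
    _r("rs2108622", "homozygote", "IS", 0.90, 0.56, 1.44, 0.45, 0.651, 4, 1515, 1545, 73.9),
    # point estimate printed outside its own CI
    _r("rs2108622", "homozygote", "hypertension", 0.90, 1.02, 1.37, 2.29, 0.022, 8, 6764, 4879, 0.0, ok=False),
    _r("rs2108622", "homozygote", "population", 0.91, 0.70, 1.19, 0.70, 0.487, 12, 5203, 4584, 64.3),
    _r("rs2108622", "heterozygote", "overall", 0.95, 0.89, 1.01, 1.69, 0.092, 17, 10213, 8033, 43.9),
    _r("rs2108622", "heterozygote", "Asian", 0.92, 0.85, 1.00, 2.06, 0.039, 15, 6352, 5867, 48.3),
    _r("rs2108622", "heterozygote", "CAD", 0.80, 0.69, 0.92, 3.14, 0.002, 5, 1934, 1609, 37.2),
    _r("rs2108622", "heterozygote", "IS", 0.94, 0.80, 1.09, 0.84, 0.400, 4, 1515, 1545, 47.8),
    _r("rs2108622", "heterozygote", "hypertension", 1.00, 0.93, 1.09, 0.09, 0.927, 8, 6764, 4879, 19.2),
    _r("rs2108622", "heterozygote", "population", 0.91, 0.83, 0.99, 2.15, 0.032, 12, 5203, 4584, 57.8),
    _r("rs2108622", "dominant", "overall", 0.93, 0.83, 1.03, 1.46, 0.145, 17, 10213, 8033, 59.3),
    _r("rs2108622", "dominant", "Asian", 0.91, 0.80, 1.03, 1.49, 0.135, 15, 6352, 5867, 62.9),
    _r("rs2108622", "dominant", "CAD", 0.77, 0.64, 0.92, 2.83, 0.005, 5, 1934, 1609, 43.3),
    _r("rs2108622", "dominant", "IS", 0.93, 0.71, 1.21, 0.57, 0.572, 4, 1515, 1545, 69.4),
    _r("rs2108622", "dominant", "hypertension", 1.03, 0.95, 1.12, 0.77, 0.442, 8, 6764, 4879, 6.0),
    _r("rs2108622", "dominant", "population", 0.89, 0.77, 1.03, 1.52, 0.130, 12, 5203, 4584, 68.5),
    _r("rs2108622", "recessive", "overall", 0.98, 0.82, 1.18, 0.22, 0.827, 17, 10213, 8033, 58.7),
    _r("rs2108622", "recessive", "Asian", 0.95, 0.77, 1.17, 0.49, 0.625, 15, 6352, 5867, 62.5),
    _r("rs2108622", "recessive", "CAD", 0.60, 0.44, 0.83, 3.06, 0.002, 5, 1934, 1609, 19.2),
    _r("rs2108622", "recessive", "IS", 0.93, 0.65, 1.33, 0.40, 0.692, 4, 1515, 1545, 58.8),
    _r("rs2108622", "recessive", "hypertension", 1.22, 1.05, 1.43, 2.52, 0.012, 8, 6764, 4879, 12.5),
    _r("rs2108622", "recessive", "population", 0.96, 0.77, 1.19, 0.39, 0.694, 12, 5203, 4584, 50.5),
)


def consistent_rows() -> tuple[PublishedRow, ...]:
    """Rows usable for z vs. OR/CI consistency checking."""
    return tuple(r for r in PUBLISHED_ROWS if r.consistent)
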