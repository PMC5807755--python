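"""Synthetic multi-study case-control genotype corpora.

The generator draws, per study, a control effect-allele frequency and a
study-level log odds ratio (optionally heterogeneous across studies),
converts the odds ratio to a case allele frequency via the odds
transform

    p_case = p * e^theta / (1 - p + p * e^theta),

and samples each arm's genotype counts multinomially from
Hardy-Weinberg proportions at that arm's allele frequency.  The effect
is therefore multiplicative per allele; genotype-level odds ratios are
induced by the allele model rather than configured separately.

An optional fraction of control arms is perturbed away from HWE by
excess homozygosity: pairs of heterozygotes are converted into one
homozygous-reference plus one homozygous-alternate subject, preserving
allele counts while inflating the HWE chi-square.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    ControlSource,
    Disease,
    Ethnicity,
    Gender,
    GenotypeCountRecord,
    ValidationError,
)
from .hwe import hwe_chi_square

_ETHNICITY_CYCLE = ("Asian", "Asian", "Caucasian")
_DISEASE_CYCLE = ("hypertension", "CAD", "IS", "hypertension", "other")
_SOURCE_CYCLE = ("population", "population", "hospital")
_GENDER_CYCLE = ("mixed",)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic corpus.

    Defaults emulate the shape of a typical published SNP
    meta-analysis corpus: 10-20 studies of a few hundred to ~1500
    subjects per arm, control effect-allele frequencies in the common
    range, allele odds ratios near 1, controls in HWE.
    """

    n_studies: int = 15
    n_case_range: tuple[int, int] = (100, 1500)
    n_ctrl_range: tuple[int, int] = (100, 1500)
    effect_allele_freq_range: tuple[float, float] = (0.15, 0.45)
    true_allele_or: float = 1.0
    tau: float = 0.0
    hwe_violation_rate: float = 0.0
    het_shift_fraction: float = 0.5
    subgroup_scheme: Optional[Mapping[int, Mapping[str, str]]] = None
    seed: int = 0
    snp_id: str = "rs0000001"
    effect_allele: str = "A"
    ref_allele: str = "G"

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValidationError("n_studies must be positive")
        for name in ("n_case_range", "n_ctrl_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < lo <= hi")
        lo, hi = self.effect_allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError(
                "effect_allele_freq_range must lie strictly inside (0, 1)")
        if self.true_allele_or <= 0:
            raise ValidationError("true_allele_or must be positive")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if not 0.0 <= self.hwe_violation_rate <= 1.0:
            raise ValidationError("hwe_violation_rate must be in [0, 1]")
        if not 0.0 <= self.het_shift_fraction <= 1.0:
            raise ValidationError("het_shift_fraction must be in [0, 1]")


def _hwe_proportions(p: float) -> tuple[float, float, float]:
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


def case_allele_frequency(p_ctrl: float, log_or: float) -> float:
    """Odds-transform of the control allele frequency by e^log_or."""
    odds = p_ctrl / (1.0 - p_ctrl) * math.exp(log_or)
    return odds / (1.0 + odds)


def _perturb_from_hwe(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Excess-homozygosity perturbation preserving allele counts."""
    hom_ref, het, hom_alt = (int(c) for c in counts)
    pairs = int(het * fraction) // 2
    return np.array([hom_ref + pairs, het - 2 * pairs, hom_alt + pairs])


def _subgroup_labels(config: SimulationConfig, index: int) -> dict[str, str]:
    if config.subgroup_scheme is not None and index in config.subgroup_scheme:
        given = dict(config.subgroup_scheme[index])
    else:
        given = {}
    return {
        "ethnicity": given.get("ethnicity",
                               _ETHNICITY_CYCLE[index % len(_ETHNICITY_CYCLE)]),
        "disease": given.get("disease",
                             _DISEASE_CYCLE[index % len(_DISEASE_CYCLE)]),
        "control_source": given.get("control_source",
                                    _SOURCE_CYCLE[index % len(_SOURCE_CYCLE)]),
        "gender": given.get("gender",
                            _GENDER_CYCLE[index % len(_GENDER_CYCLE)]),
    }


def simulate_studies(config: SimulationConfig) -> list[GenotypeCountRecord]:
    """Draw one corpus of per-study genotype count records."""
    rng = np.random.default_rng(config.seed)
    k = config.n_studies
    n_violate = int(round(config.hwe_violation_rate * k))
    violate = set(rng.choice(k, size=n_violate, replace=False)) if n_violate else set()

    records = []
    for i in range(k):
        n_case = int(rng.integers(config.n_case_range[0],
                                  config.n_case_range[1] + 1))
        n_ctrl = int(rng.integers(config.n_ctrl_range[0],
                                  config.n_ctrl_range[1] + 1))
        p_ctrl = float(rng.uniform(*config.effect_allele_freq_range))
        theta = math.log(config.true_allele_or)
        if config.tau > 0:
            theta += float(rng.normal(0.0, config.tau))
        p_case = case_allele_frequency(p_ctrl, theta)
        ctrl = rng.multinomial(n_ctrl, _hwe_proportions(p_ctrl))
        case = rng.multinomial(n_case, _hwe_proportions(p_case))
        if i in violate:
            ctrl = _perturb_from_hwe(ctrl, config.het_shift_fraction)
        labels = _subgroup_labels(config, i)
        records.append(GenotypeCountRecord(
            study_id=f"study{i + 1:02d}",
            snp_id=config.snp_id,
            effect_allele=config.effect_allele,
            ref_allele=config.ref_allele,
            ethnicity=labels["ethnicity"],
            disease=labels["disease"],
            control_source=labels["control_source"],
            gender=labels["gender"],
            case_hom_ref=int(case[0]), case_het=int(case[1]),
            case_hom_alt=int(case[2]),
            ctrl_hom_ref=int(ctrl[0]), ctrl_het=int(ctrl[1]),
            ctrl_hom_alt=int(ctrl[2]),
        ))
    return records


# --- frozen corpora shaped like the two published meta-analysis tables ---
#
# Per-study arm sizes are fixed partitions chosen so that the overall and
# every subgroup margin (study count, case total, control total) match
# the published table exactly; the genotype splits within each arm are
# synthetic seeded HWE draws (study-level counts claim no fidelity to
# any real study).
#
# layout rows: (disease, control_source, ethnicity, n_case, n_ctrl)
_FIXTURE_LAYOUTS: dict[str, dict] = {
    "rs1558139": {
        "seed": 1558139,
        "effect_allele": "T",
        "ref_allele": "C",
        "freq_range": (0.25, 0.40),
        "true_allele_or": 0.92,
        "tau": 0.0,
        "studies": [
            ("hypertension", "population", "Asian", 463, 447),
            ("hypertension", "population", "Asian", 463, 447),
            ("hypertension", "population", "Asian", 463, 447),
            ("hypertension", "population", "Asian", 463, 446),
            ("CAD", "hospital", "Asian", 294, 305),
            ("CAD", "population", "Asian", 294, 305),
            ("CAD", "population", "Asian", 295, 304),
            ("IS", "hospital", "Asian", 241, 209),
            ("IS", "population", "Asian", 242, 318),
            ("IS", "population", "Asian", 244, 319),
        ],
    },
    "rs2108622": {
        "seed": 2108622,
        "effect_allele": "A",
        "ref_allele": "G",
        "freq_range": (0.20, 0.40),
        "true_allele_or": 0.95,
        "tau": 0.12,
        "studies": [
            ("CAD", "population", "Asian", 387, 322),
            ("CAD", "population", "Asian", 387, 322),
            ("CAD", "population", "Asian", 387, 322),
            ("CAD", "population", "Asian", 387, 322),
            ("CAD", "population", "Asian", 386, 321),
            ("IS", "population", "Asian", 379, 386),
            ("IS", "population", "Asian", 379, 386),
            ("IS", "population", "Asian", 379, 387),
            ("IS", "population", "Asian", 378, 386),
            ("hypertension", "population", "Asian", 585, 477),
            ("hypertension", "population", "Asian", 585, 477),
            ("hypertension", "population", "Asian", 584, 476),
            ("hypertension", "hospital", "Asian", 383, 428),
            ("hypertension", "hospital", "Asian", 383, 428),
            ("hypertension", "hospital", "Asian", 383, 427),
            ("hypertension", "hospital", "Caucasian", 1931, 1083),
            ("hypertension", "hospital", "Caucasian", 1930, 1083),
        ],
    },
}


def _hwe_consistent_multinomial(rng: np.random.Generator, n: int,
                                p: float, min_p_value: float = 0.2,
                                max_tries: int = 200) -> np.ndarray:
    """Multinomial HWE draw re-drawn until comfortably within HWE."""
    draw = rng.multinomial(n, _hwe_proportions(p))
    for _ in range(max_tries):
        if hwe_chi_square(*map(int, draw)).p_value > min_p_value:
            return draw
        draw = rng.multinomial(n, _hwe_proportions(p))
    return draw


def paper_like_fixture(snp: str) -> list[GenotypeCountRecord]:
    """A frozen seeded corpus matching a published table's margins.

    ``rs1558139``: 10 Asian studies, 3462 cases / 3547 controls
    (hypertension, CAD and IS; 8 population-based).  ``rs2108622``:
    17 studies, 10213 cases / 8033 controls (CAD/IS/hypertension mix,
    15 Asian, 12 population-based, heterogeneous effects).  Control
    arms are HWE-consistent; regeneration is byte-identical.
    """
    if snp not in _FIXTURE_LAYOUTS:
        raise ValidationError(
            f"unknown fixture SNP {snp!r}; expected one of "
            f"{sorted(_FIXTURE_LAYOUTS)}")
    layout = _FIXTURE_LAYOUTS[snp]
    rng = np.random.default_rng(layout["seed"])
    records = []
    for i, (disease, source, ethnicity, n_case, n_ctrl) in enumerate(
            layout["studies"]):
        p_ctrl = float(rng.uniform(*layout["freq_range"]))
        theta = math.log(layout["true_allele_or"])
        if layout["tau"] > 0:
            theta += float(rng.normal(0.0, layout["tau"]))
        p_case = case_allele_frequency(p_ctrl, theta)
        ctrl = _hwe_consistent_multinomial(rng, n_ctrl, p_ctrl)
        case = rng.multinomial(n_case, _hwe_proportions(p_case))
        records.append(GenotypeCountRecord(
            study_id=f"{snp}_study{i + 1:02d}",
            snp_id=snp,
            effect_allele=layout["effect_allele"],
            ref_allele=layout["ref_allele"],
            ethnicity=ethnicity,
            disease=disease,
            control_source=source,
            gender="mixed",
            case_hom_ref=int(case[0]), case_het=int(case[1]),
            case_hom_alt=int(case[2]),
            ctrl_hom_ref=int(ctrl[0]), ctrl_het=int(ctrl[1]),
            ctrl_hom_alt=int(ctrl[2]),
        ))
    return records
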