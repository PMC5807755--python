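"""Full-pipeline driver and table-shaped report writers.

:func:`run_full_analysis` chains the stages for one SNP: HWE
eligibility screening, an overall meta-analysis per genetic model,
subgroup meta-analyses per requested grouping attribute, publication
bias tests (when at least three studies are available) and
leave-one-out sensitivity analysis.  The report can be serialized as a
TSV that mirrors the conventional meta-analysis table layout
(one row per model x subgroup) or as lossless round-trip JSON.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .bias import BiasTestResult, LeaveOneOutAnalysis, bias_tests, leave_one_out
from .data_model import (
    GeneticModel,
    GenotypeCountRecord,
    ValidationError,
    filter_by_snp,
    read_counts_csv,
)
from .hwe import filter_by_hwe
from .pooling import (
    MetaConfig,
    PooledResult,
    PoolingMethod,
    meta_analyze,
    study_effects,
)

logger = logging.getLogger("snpmeta")

GROUPING_ATTRIBUTES = ("ethnicity", "disease", "control_source", "gender")

DEFAULT_MODELS = tuple(GeneticModel)

#: TSV column order, mirroring the usual published table.
TSV_COLUMNS = [
    "snp_id", "model", "grouping", "subgroup", "or", "ci_low", "ci_high",
    "z", "p_assoc", "k", "n_case", "n_ctrl", "i2_pct", "p_het", "method",
    "tau2",
]


@dataclass(frozen=True)
class SubgroupResult:
    grouping: str
    label: str
    result: PooledResult


@dataclass(frozen=True)
class ModelAnalysis:
    """One genetic model's overall, subgroup, bias and sensitivity results."""

    model: GeneticModel
    overall: PooledResult
    subgroups: tuple[SubgroupResult, ...]
    bias: Optional[BiasTestResult]
    loo: Optional[LeaveOneOutAnalysis]


@dataclass(frozen=True)
class AnalysisReport:
    snp_id: str
    models: tuple[ModelAnalysis, ...]
    provenance: dict


def _group_records(records: Sequence[GenotypeCountRecord],
                   attribute: str) -> dict[str, list[GenotypeCountRecord]]:
    if attribute not in GROUPING_ATTRIBUTES:
        raise ValidationError(
            f"unknown grouping {attribute!r}; expected one of "
            f"{GROUPING_ATTRIBUTES}")
    groups: dict[str, list[GenotypeCountRecord]] = {}
    for rec in records:
        label = getattr(rec, attribute).value
        groups.setdefault(label, []).append(rec)
    return groups


def run_full_analysis(
    counts_path: Union[str, Path],
    snp: str,
    models: Optional[Sequence[Union[GeneticModel, str]]] = None,
    groupings: Optional[Sequence[str]] = None,
    config: Optional[MetaConfig] = None,
) -> AnalysisReport:
    """HWE screen, pool, subgroup, bias-test and leave-one-out one SNP."""
    config = config or MetaConfig()
    models = [GeneticModel(m) for m in (models or DEFAULT_MODELS)]
    groupings = list(groupings if groupings is not None else GROUPING_ATTRIBUTES)

    raw = Path(counts_path).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    records = read_counts_csv(counts_path)
    records = filter_by_snp(records, snp)
    if not records:
        raise ValidationError(f"no records for SNP {snp!r} in {counts_path}")

    t0 = time.perf_counter()
    kept, dropped = filter_by_hwe(records, alpha=config.hwe_alpha)
    logger.info("stage=hwe_filter k_in=%d k_kept=%d k_dropped=%d elapsed=%.3fs",
                len(records), len(kept), len(dropped),
                time.perf_counter() - t0)
    for rec, res in dropped:
        logger.warning("excluded study=%s (control HWE chi2=%.3f p=%.4f)",
                       rec.study_id, res.chi2, res.p_value)
    if not kept:
        raise ValidationError("no studies left after HWE screening")

    analyses = []
    for model in models:
        t0 = time.perf_counter()
        overall = meta_analyze(kept, model, config)
        subgroup_rows: list[SubgroupResult] = []
        for attribute in groupings:
            for label, group in sorted(_group_records(kept, attribute).items()):
                if not group:
                    logger.warning("subgroup %s=%s empty; omitted",
                                   attribute, label)
                    continue
                subgroup_rows.append(SubgroupResult(
                    grouping=attribute, label=label,
                    result=meta_analyze(group, model, config)))
        if len(kept) >= 3:
            bias = bias_tests(study_effects(kept, model, config))
        else:
            bias = None
            logger.warning("model=%s k=%d < 3: publication-bias tests skipped",
                           model.value, len(kept))
        if len(kept) >= 2:
            loo = leave_one_out(kept, model, config)
        else:
            loo = None
            logger.warning("model=%s k=%d < 2: leave-one-out skipped",
                           model.value, len(kept))
        logger.info("stage=model model=%s k=%d method=%s elapsed=%.3fs",
                    model.value, overall.k, overall.method.value,
                    time.perf_counter() - t0)
        analyses.append(ModelAnalysis(model=model, overall=overall,
                                      subgroups=tuple(subgroup_rows),
                                      bias=bias, loo=loo))

    provenance = {
        "input_path": str(counts_path),
        "input_sha256": digest,
        "snp_id": snp,
        "models": [m.value for m in models],
        "groupings": groupings,
        "config": asdict(config),
        "n_records_input": len(records),
        "n_records_after_hwe": len(kept),
        "dropped_studies": [rec.study_id for rec, _ in dropped],
    }
    return AnalysisReport(snp_id=snp, models=tuple(analyses),
                          provenance=provenance)


# --- serialization -------------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, enum.Enum):
        return obj.value
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_jsonable(getattr(obj, k))
                for k in obj.__dataclass_fields__}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    return obj


def report_to_dict(report: AnalysisReport) -> dict:
    return _to_jsonable(report)


def _pooled_from_dict(d: dict) -> PooledResult:
    d = dict(d)
    d["method"] = PoolingMethod(d["method"])
    return PooledResult(**d)


def report_from_dict(data: dict) -> AnalysisReport:
    models = []
    for m in data["models"]:
        subgroups = tuple(
            SubgroupResult(grouping=s["grouping"], label=s["label"],
                           result=_pooled_from_dict(s["result"]))
            for s in m["subgroups"])
        bias = BiasTestResult(**m["bias"]) if m["bias"] is not None else None
        if m["loo"] is not None:
            from .bias import LeaveOneOutResult
            results = tuple(
                LeaveOneOutResult(omitted_study_id=r["omitted_study_id"],
                                  result=_pooled_from_dict(r["result"]))
                for r in m["loo"]["results"])
            loo = LeaveOneOutAnalysis(results=results,
                                      or_min=m["loo"]["or_min"],
                                      or_max=m["loo"]["or_max"])
        else:
            loo = None
        models.append(ModelAnalysis(
            model=GeneticModel(m["model"]),
            overall=_pooled_from_dict(m["overall"]),
            subgroups=subgroups, bias=bias, loo=loo))
    return AnalysisReport(snp_id=data["snp_id"], models=tuple(models),
                          provenance=data["provenance"])


def _tsv_row(snp_id: str, model: GeneticModel, grouping: str, label: str,
             r: PooledResult) -> list[str]:
    return [
        snp_id, model.value, grouping, label,
        f"{r.or_:.2f}", f"{r.ci_low:.2f}", f"{r.ci_high:.2f}",
        f"{r.z:.2f}", f"{r.p_assoc:.3f}",
        str(r.k), str(r.n_case), str(r.n_ctrl),
        f"{r.i2_pct:.1f}", f"{r.p_het:.3f}", r.method.value,
        f"{r.tau2:.4f}",
    ]


def write_report(report: AnalysisReport, path: Union[str, Path],
                 format: str = "tsv") -> None:
    """Write the report as a Table-style TSV or lossless JSON."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
        return
    if format != "tsv":
        raise ValidationError(f"unknown report format {format!r}")
    lines = ["\t".join(TSV_COLUMNS)]
    for analysis in report.models:
        lines.append("\t".join(_tsv_row(report.snp_id, analysis.model,
                                        "overall", "overall",
                                        analysis.overall)))
        for sub in analysis.subgroups:
            lines.append("\t".join(_tsv_row(report.snp_id, analysis.model,
                                            sub.grouping, sub.label,
                                            sub.result)))
    path.write_text("\n".join(lines) + "\n")


def read_report_json(path: Union[str, Path]) -> AnalysisReport:
    return report_from_dict(json.loads(Path(path).read_text()))
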