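"""End-to-end orchestration: thresholds -> contrasts -> classifications ->
CT calls -> flowchart report, with a file-based wrapper used by the CLI.

:func:`run_screen` is the in-memory pipeline; :func:`run_pipeline` reads
the three input TSVs, runs the screen and writes every stage table plus a
run manifest (parameters, input checksums, percentile convention) so that
a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calls import CTCallTable, FlowchartReport, call_ct, flowchart_report
from .cancer import aggregate_cancer_flags, classify_cancer, write_cancer_records
from .errors import CTScreenError
from .io import (
    read_expression_matrix,
    read_probeset_annotation,
    read_sample_annotation,
)
from .model import (
    CANCER,
    NORMAL,
    TARGET,
    ExpressionMatrix,
    GlobalThresholds,
    ProbesetAnnotation,
    SampleAnnotation,
    compute_global_thresholds,
    group_summaries,
)
from .stats import ContrastResult, two_group_contrast
from .tissue import ClassifierParams, classify_tissue, summarize_class_distribution


@dataclass
class RunConfig:
    """Paths, threshold overrides and classifier parameters for one run."""

    matrix_path: str
    samples_path: str
    probesets_path: str
    out_dir: str
    bec: float | None = None
    q_low: float | None = None
    q_high: float | None = None
    params: ClassifierParams = field(default_factory=ClassifierParams)
    ct_list_path: str | None = None


@dataclass
class ScreenResult:
    """Every intermediate and final table of one screen."""

    thresholds: GlobalThresholds
    summaries: pd.DataFrame
    tissue_contrast: ContrastResult
    tissue_records: pd.DataFrame
    cancer_records: pd.DataFrame
    cancer_aggregate: pd.DataFrame
    calls: CTCallTable
    report: FlowchartReport


def resolve_thresholds(matrix: ExpressionMatrix, bec=None, q_low=None,
                       q_high=None) -> GlobalThresholds:
    """Recompute global thresholds, honoring any explicit overrides."""
    if None in (bec, q_low, q_high):
        computed = compute_global_thresholds(matrix)
        bec = computed.bec if bec is None else bec
        q_low = computed.q_low if q_low is None else q_low
        q_high = computed.q_high if q_high is None else q_high
    return GlobalThresholds(bec=float(bec), q_low=float(q_low), q_high=float(q_high))


def run_screen(
    matrix: ExpressionMatrix,
    annot: SampleAnnotation,
    probesets: ProbesetAnnotation,
    thresholds: GlobalThresholds | None = None,
    params: ClassifierParams = ClassifierParams(),
) -> ScreenResult:
    """Run the whole screen on in-memory inputs."""
    annot.validate_against(matrix)
    probesets.validate_against(matrix)
    if thresholds is None:
        thresholds = compute_global_thresholds(matrix)
    summaries = group_summaries(matrix, annot)

    target_samples = annot.samples_in_category(TARGET)
    normal_samples = annot.samples_in_category(NORMAL)
    idx = matrix.probeset_ids
    tissue_contrast = two_group_contrast(
        matrix.data[target_samples].to_numpy(),
        matrix.data[normal_samples].to_numpy(),
        index=idx,
    )
    tissue_records = classify_tissue(summaries, annot, thresholds, tissue_contrast, params)

    cancer_contrasts: dict[str, ContrastResult] = {}
    for cg in annot.groups_of(CANCER):
        a = matrix.data[annot.samples_in_group(cg)].to_numpy()
        b = matrix.data[annot.samples_in_group(annot.matched_normal(cg))].to_numpy()
        if min(a.shape[1], b.shape[1]) >= 2:
            cancer_contrasts[cg] = two_group_contrast(a, b, index=idx)
        else:
            # minimally replicated subtype: prior-only fallback, borrowing
            # the tissue contrast's variance prior
            cancer_contrasts[cg] = two_group_contrast(
                a, b, prior=tissue_contrast.prior, index=idx
            )
    cancer_records = classify_cancer(summaries, annot, thresholds, cancer_contrasts, params)
    cancer_aggregate = aggregate_cancer_flags(cancer_records)
    calls = call_ct(tissue_records, cancer_aggregate, probesets)
    report = flowchart_report(tissue_records, cancer_aggregate, calls, probesets)
    return ScreenResult(
        thresholds=thresholds,
        summaries=summaries,
        tissue_contrast=tissue_contrast,
        tissue_records=tissue_records,
        cancer_records=cancer_records,
        cancer_aggregate=cancer_aggregate,
        calls=calls,
        report=report,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> ScreenResult:
    """File-based pipeline run; writes all stage outputs to ``out_dir``."""
    matrix = read_expression_matrix(config.matrix_path)
    annot = read_sample_annotation(config.samples_path)
    probesets = read_probeset_annotation(config.probesets_path)
    thresholds = resolve_thresholds(matrix, config.bec, config.q_low, config.q_high)
    result = run_screen(matrix, annot, probesets, thresholds, config.params)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.Series(
        {"bec": thresholds.bec, "q_low": thresholds.q_low, "q_high": thresholds.q_high},
        name="value",
    ).rename_axis("threshold").to_csv(out / "thresholds.tsv", sep="\t", float_format="%.6g")
    result.summaries.rename_axis("probeset_id").to_csv(
        out / "group_summaries.tsv", sep="\t", float_format="%.4f"
    )
    result.tissue_contrast.to_tsv(out / "tissue_contrast.tsv")
    result.tissue_records.to_csv(out / "tissue_classes.tsv", sep="\t", float_format="%.6g")
    write_cancer_records(result.cancer_records, out / "cancer_flags.tsv")
    agg = result.cancer_aggregate.copy()
    agg["any_ucndh"] = agg["any_ucndh"].astype(int)
    agg.rename_axis("probeset_id").to_csv(out / "cancer_aggregate.tsv", sep="\t")
    result.calls.write(out / "ct_calls.tsv", out / "ct_genes.tsv")
    (out / "report.txt").write_text(result.report.to_text())
    (out / "report.kv").write_text(result.report.to_kv())
    if config.ct_list_path:
        ct_list = [
            line.strip()
            for line in Path(config.ct_list_path).read_text().splitlines()
            if line.strip()
        ]
        dist = summarize_class_distribution(result.tissue_records, subset=ct_list)
        dist.to_csv(out / "ct_list_distribution.tsv", sep="\t", float_format="%.6g")

    manifest = {
        "ctscreen_version": __version__,
        # basenames, not absolute paths: identical inputs must yield a
        # byte-identical manifest wherever they live
        "inputs": {
            "matrix": {"file": Path(config.matrix_path).name,
                       "sha256": _sha256(config.matrix_path)},
            "samples": {"file": Path(config.samples_path).name,
                        "sha256": _sha256(config.samples_path)},
            "probesets": {"file": Path(config.probesets_path).name,
                          "sha256": _sha256(config.probesets_path)},
        },
        "thresholds": {
            "bec": thresholds.bec,
            "q_low": thresholds.q_low,
            "q_high": thresholds.q_high,
            "percentile_convention": thresholds.convention,
            "recomputed": {
                "bec": config.bec is None,
                "q_low": config.q_low is None,
                "q_high": config.q_high is None,
            },
        },
        "params": {
            "fold_change": config.params.fold_change,
            "q_cutoff": config.params.q_cutoff,
            "exception_budget": config.params.exception_budget,
            "ie_min": config.params.ie_min,
            "ie_max": config.params.ie_max,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result
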