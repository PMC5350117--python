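"""End-to-end validation and cohort reports.

Assembles the stage outputs into a single validation report (depth summary,
provisional metric suite, confirmation-corrected metrics, replicate
variability ranges, low-coverage and SegDup locus counts) and a cohort
report (request distribution and per-panel result rates).  Reports render to
machine JSON at full precision and to human TSV with two-decimal metrics and
integer percentages; identical inputs produce byte-identical documents
(sorted keys, fixed float formatting).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from ._util import fmt_metric, round_half_up
from .concordance import (CallSet, MetricsBundle, build_confusion,
                          harmonize_sites, compute_metrics)
from .confirmation import ConfirmationRecord, corrected_metrics
from .coverage import (DEFAULT_DEPTH_THRESHOLD, DepthTrack,
                       build_backfill_manifest, coverage_summary,
                       extract_low_coverage_loci)
from .regions import RegionIndex, SegDupRegion, TargetRegion
from .triage import CaseReport, cohort_summary
from .variability import pairwise_metrics, summarize_ranges

logger = logging.getLogger(__name__)


def _metrics_block(metrics: MetricsBundle) -> dict:
    return metrics.as_dict(stringify_na=True)


def validate_panel(truth: CallSet,
                   replicates: list,
                   targets: list[TargetRegion],
                   depth: DepthTrack,
                   panel_name: str = "panel",
                   segdups: list[SegDupRegion] | None = None,
                   confirmations: list[ConfirmationRecord] | None = None,
                   threshold: int = DEFAULT_DEPTH_THRESHOLD,
                   snv_only: bool = True) -> dict:
    """Full validation report for one panel.

    `replicates` is a list of (ReplicateLabel, CallSet); the first replicate
    is the headline evaluation callset for the provisional/corrected metric
    blocks, and all replicates feed the variability grid (with `truth` as
    the secondary comparison set).
    """
    if not replicates:
        raise ValueError("at least one evaluation replicate required")
    index = RegionIndex(targets)
    segdups = segdups or []
    confirmations = confirmations or []

    cov = coverage_summary(depth, targets, threshold)
    loci = extract_low_coverage_loci(depth, targets, threshold)
    manifest = build_backfill_manifest(loci, segdups)
    logger.info("panel %s: %d low-coverage loci (%d bp) at <%dx",
                panel_name, len(loci), sum(l.length_bp for l in loci),
                threshold)

    _, eval_calls = replicates[0]
    joined = harmonize_sites(truth, eval_calls, index, snv_only=snv_only)
    provisional = compute_metrics(build_confusion(joined))
    corrected, audit = corrected_metrics(joined, confirmations, depth,
                                         threshold)
    logger.info("panel %s: %d joined sites, %d confirmations applied",
                panel_name, len(joined), len(confirmations))

    grid = pairwise_metrics(replicates, index, secondary=truth,
                            snv_only=snv_only) if len(replicates) >= 2 else []
    ranges = summarize_ranges(grid) if grid else {}

    segdup_rows = manifest[manifest["in_segdup"]]
    report = {
        "panel": panel_name,
        "threshold": threshold,
        "coverage": {
            "mean_depth": cov.mean_depth,
            "frac_bases_ge_t": cov.frac_bases_ge_t,
            "frac_regions_ge_t": cov.frac_regions_ge_t,
            "n_targeted_bases": cov.n_bases,
            "n_regions": cov.n_regions,
        },
        "low_coverage": {
            "n_loci": len(loci),
            "total_bp": int(sum(l.length_bp for l in loci)),
        },
        "segdup": {
            "n_loci": int(len(segdup_rows)),
            "total_bp": int(segdup_rows["length_bp"].sum()),
            "n_reportable": int(segdup_rows["reportable"].sum()),
            "reportable_bp": int(
                segdup_rows.loc[segdup_rows["reportable"],
                                "length_bp"].sum()),
        },
        "provisional_metrics": _metrics_block(provisional),
        "corrected_metrics": _metrics_block(corrected),
        "correction_audit": audit.as_dict(),
        "variability_ranges": {
            grouping: {k: (list(v) if isinstance(v, tuple) else
                           ("NA" if v is None else v))
                       for k, v in summary.items()}
            for grouping, summary in ranges.items()},
        "backfill_manifest": manifest.to_dict(orient="records"),
    }
    return report


def cohort_report(reports: list[CaseReport]) -> dict:
    """Cohort summary document (request shares and result rates)."""
    return cohort_summary(reports)


def write_json(document: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(document, indent=2, sort_keys=True, allow_nan=False)
        + "\n")


def validation_tsv(report: dict) -> str:
    """Human-readable two-column rendering of the headline numbers."""
    rows = [("panel", report["panel"]),
            ("mean_depth", f"{round_half_up(report['coverage']['mean_depth'], 2):.2f}"),
            (f"frac_bases_ge_{report['threshold']}x",
             fmt_metric(report["coverage"]["frac_bases_ge_t"])),
            ("low_coverage_loci", report["low_coverage"]["n_loci"]),
            ("low_coverage_bp", report["low_coverage"]["total_bp"]),
            ("segdup_loci", report["segdup"]["n_loci"]),
            ("segdup_bp", report["segdup"]["total_bp"])]
    for block in ("provisional_metrics", "corrected_metrics"):
        for name in ("sensitivity", "specificity", "fp_rate", "fn_rate",
                     "ogc", "nrs", "nrd", "nrgc", "precision"):
            value = report[block][name]
            rows.append((f"{block}.{name}",
                         value if value == "NA" else fmt_metric(value)))
    return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"
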