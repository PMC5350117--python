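"""Repeatability/reproducibility from pairwise replicate concordance.

The validation design repeats the same genomic DNA sample within a run
(intra-run), across runs (inter-run), across operators, reagent lots and
days.  For every ordered pair of replicates of a sample, the concordance
metric suite is computed treating one replicate as the comparison (truth
side) and the other as the evaluation set, and then again with the roles
swapped; summaries report the min-max range of each metric per grouping, the
form validation tables use.  Comparisons against an external genotype-known
reference reuse the same engine under the 'vs_secondary' grouping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._util import NA
from .concordance import CallSet, MetricsBundle, metrics_for_pair
from .regions import RegionIndex

logger = logging.getLogger(__name__)

GROUPINGS = ("intra_run", "inter_run", "inter_operator", "inter_lot",
             "inter_day", "vs_secondary")

#: Below this many truth-side non-reference sites a pair is too sparse for a
#: stable range and is summarized as NA instead.
MIN_INFORMATIVE_SITES = 10


@dataclass(frozen=True)
class ReplicateLabel:
    sample_id: str
    run_id: str
    operator: str = "A"
    reagent_lot: str = "lot1"
    day: str = "day1"
    plex: int = 1

    def __post_init__(self) -> None:
        if self.plex not in (1, 3):
            raise ValueError(f"plex must be 1 or 3, got {self.plex}")


class CrossSamplePairError(ValueError):
    """Replicate variability is defined within one sample only."""


def classify_pair(a: ReplicateLabel, b: ReplicateLabel) -> frozenset[str]:
    """Grouping tags for a replicate pair of the same sample.

    Same run -> {intra_run}; different runs -> {inter_run} plus
    inter_operator / inter_lot / inter_day for each differing factor.
    """
    if a.sample_id != b.sample_id:
        raise CrossSamplePairError(
            f"cross-sample pair {a.sample_id} vs {b.sample_id}")
    if a.run_id == b.run_id:
        return frozenset({"intra_run"})
    tags = {"inter_run"}
    if a.operator != b.operator:
        tags.add("inter_operator")
    if a.reagent_lot != b.reagent_lot:
        tags.add("inter_lot")
    if a.day != b.day:
        tags.add("inter_day")
    return frozenset(tags)


@dataclass(frozen=True)
class GridEntry:
    comparison: ReplicateLabel
    evaluation: ReplicateLabel
    groupings: frozenset[str]
    metrics: MetricsBundle

    @property
    def informative_sites(self) -> int:
        # truth-side non-reference sites available to the pair
        return self.metrics.tp + self.metrics.fn


def pairwise_metrics(replicates: list[tuple[ReplicateLabel, CallSet]],
                     targets: RegionIndex,
                     secondary: CallSet | None = None,
                     snv_only: bool = True) -> list[GridEntry]:
    """Metric grid over every ordered pair of same-sample replicates.

    Both orientations of each unordered pair are present (each replicate
    serves alternately as comparison and evaluation set).  When `secondary`
    is given, each replicate is additionally compared against it under the
    'vs_secondary' grouping (secondary as comparison set).
    """
    if len(replicates) < 2 and secondary is None:
        raise ValueError("need at least two replicates")
    grid: list[GridEntry] = []
    for i, (label_a, calls_a) in enumerate(replicates):
        for j, (label_b, calls_b) in enumerate(replicates):
            if i == j or label_a.sample_id != label_b.sample_id:
                continue
            grid.append(GridEntry(
                comparison=label_a, evaluation=label_b,
                groupings=classify_pair(label_a, label_b),
                metrics=metrics_for_pair(calls_a, calls_b, targets,
                                         snv_only=snv_only)))
    if secondary is not None:
        sec_label = ReplicateLabel(sample_id=secondary.sample_id,
                                   run_id="secondary")
        for label, calls in replicates:
            grid.append(GridEntry(
                comparison=sec_label, evaluation=label,
                groupings=frozenset({"vs_secondary"}),
                metrics=metrics_for_pair(secondary, calls, targets,
                                         snv_only=snv_only)))
    return grid


RANGE_METRICS = ("ogc", "nrs", "nrd", "nrgc", "precision",
                 "sensitivity", "specificity", "fp_rate", "fn_rate")


def summarize_ranges(grid: list[GridEntry],
                     min_informative_sites: int = MIN_INFORMATIVE_SITES,
                     ) -> dict[str, dict[str, tuple | None]]:
    """Per-grouping min-max range of each metric.

    Groupings whose pairs all fall below the informative-site floor are
    reported NA (a handful of variants cannot power a concordance range);
    undefined metric values are skipped, and an all-undefined metric within a
    grouping is NA as well.  Groupings with no pairs are absent, with a
    warning.
    """
    if not grid:
        raise ValueError("empty variability grid")
    out: dict[str, dict[str, tuple | None]] = {}
    for grouping in GROUPINGS:
        entries = [e for e in grid if grouping in e.groupings]
        if not entries:
            logger.warning("no replicate pairs for grouping %s", grouping)
            continue
        powered = [e for e in entries
                   if e.informative_sites >= min_informative_sites]
        summary: dict[str, tuple | None] = {}
        for metric in RANGE_METRICS:
            values = [getattr(e.metrics, metric) for e in powered]
            values = [v for v in values if v is not NA]
            summary[metric] = (min(values), max(values)) if values else NA
        summary["n_pairs"] = len(entries)
        summary["n_powered_pairs"] = len(powered)
        out[grouping] = summary
    return out
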