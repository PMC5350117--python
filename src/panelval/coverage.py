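"""Per-panel depth statistics, low-coverage gap extraction, Sanger backfill.

Reportable bases on a clinical panel must reach a depth floor (15x by
default, 10x "as needed"); contiguous runs of targeted bases strictly below
the floor are extracted as loci for orthogonal Sanger sequencing ("backfill").
Loci falling in segmental-duplication regions cannot be confirmed by
unique-locus PCR/Sanger and are flagged non-reportable unless the specific
locus was validated to amplify unambiguously.

Systematically low coverage tends to concentrate in first exons (high GC
affecting probe capture); first_exon_bias_report quantifies that signal by
exon index without needing reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import RegionIndex, SegDupRegion, TargetRegion

DEFAULT_DEPTH_THRESHOLD = 15
SECONDARY_DEPTH_THRESHOLD = 10


class DepthTrack:
    """Per-base read depth addressed by (chrom, 1-based pos); absent = 0."""

    def __init__(self) -> None:
        self._depth: dict[str, dict[int, int]] = {}

    def set(self, chrom: str, pos: int, depth: int) -> None:
        if pos < 1 or depth < 0:
            raise ValueError(f"bad depth record {chrom}:{pos}={depth}")
        self._depth.setdefault(chrom, {})[pos] = int(depth)

    def get(self, chrom: str, pos: int) -> int:
        return self._depth.get(chrom, {}).get(pos, 0)

    def region_depths(self, region: TargetRegion) -> np.ndarray:
        """Depth of every base of the region, in position order."""
        chrom_depth = self._depth.get(region.chrom, {})
        return np.array([chrom_depth.get(p, 0) for p in region.positions()],
                        dtype=np.int64)

    def records(self) -> Iterable[tuple[str, int, int]]:
        for chrom in sorted(self._depth):
            for pos in sorted(self._depth[chrom]):
                yield chrom, pos, self._depth[chrom][pos]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "DepthTrack":
        track = cls()
        for chrom, pos, depth in records:
            track.set(chrom, int(pos), int(depth))
        return track


@dataclass(frozen=True)
class CoverageSummary:
    """Depth summary over a target set at one threshold.

    frac_bases_ge_t: targeted bases at/above threshold (headline fraction).
    frac_regions_ge_t: regions whose *every* base is at/above threshold —
    the stricter per-region reading, reported alongside.
    """

    mean_depth: float
    frac_bases_ge_t: float
    frac_regions_ge_t: float
    threshold: int
    n_bases: int
    n_regions: int


@dataclass(frozen=True)
class LowCoverageLocus:
    """Maximal run of consecutive targeted bases below the depth floor."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    gene: str
    exon_index: int
    min_depth: int
    reason: str = "below_threshold"

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def coverage_summary(depth: DepthTrack, targets: Sequence[TargetRegion],
                     threshold: int = DEFAULT_DEPTH_THRESHOLD) -> CoverageSummary:
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    targets = list(targets)
    if not targets:
        raise ValueError("empty target set")
    total = 0
    ge_t = 0
    regions_ok = 0
    depth_sum = 0
    for region in targets:
        d = depth.region_depths(region)
        total += d.size
        depth_sum += int(d.sum())
        ge_t += int((d >= threshold).sum())
        if bool((d >= threshold).all()):
            regions_ok += 1
    return CoverageSummary(
        mean_depth=depth_sum / total,
        frac_bases_ge_t=ge_t / total,
        frac_regions_ge_t=regions_ok / len(targets),
        threshold=threshold,
        n_bases=total,
        n_regions=len(targets),
    )


def extract_low_coverage_loci(depth: DepthTrack,
                              targets: Sequence[TargetRegion],
                              threshold: int = DEFAULT_DEPTH_THRESHOLD,
                              ) -> list[LowCoverageLocus]:
    """Maximal sub-threshold runs within each region (no cross-region merge).

    A base belongs to a locus iff its depth is strictly below the threshold;
    runs are split by any single base at/above threshold.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    loci: list[LowCoverageLocus] = []
    for region in sorted(targets):
        d = depth.region_depths(region)
        below = d < threshold
        idx = 0
        n = d.size
        while idx < n:
            if below[idx]:
                run_start = idx
                while idx < n and below[idx]:
                    idx += 1
                loci.append(LowCoverageLocus(
                    chrom=region.chrom,
                    start=region.start + run_start,
                    end=region.start + idx,
                    gene=region.gene,
                    exon_index=region.exon_index,
                    min_depth=int(d[run_start:idx].min()),
                ))
            else:
                idx += 1
    return loci


def build_backfill_manifest(loci: Sequence[LowCoverageLocus],
                            segdups: Iterable[SegDupRegion] = (),
                            ) -> pd.DataFrame:
    """Sanger backfill manifest: one row per locus with a reportable flag.

    Loci overlapping an *unvalidated* SegDup cannot be resolved by Sanger and
    are flagged non-reportable (reason 'segdup'); loci inside SegDup regions
    validated to amplify unambiguously are emitted normally.
    """
    segdup_index = RegionIndex(segdups)
    rows = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.start, l.end)):
        hits = segdup_index.overlapping(locus.chrom, locus.start, locus.end)
        blocked = any(not s.validated_unambiguous for s in hits)
        rows.append({
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "gene": locus.gene,
            "exon": locus.exon_index,
            "length_bp": locus.length_bp,
            "min_depth": locus.min_depth,
            "in_segdup": bool(hits),
            "reportable": not blocked,
            "reason": "segdup" if blocked else locus.reason,
        })
    columns = ["chrom", "start", "end", "gene", "exon", "length_bp",
               "min_depth", "in_segdup", "reportable", "reason"]
    # explicit dtypes so an empty manifest still masks/sums correctly
    return pd.DataFrame(rows, columns=columns).astype(
        {"start": "int64", "end": "int64", "exon": "int64",
         "length_bp": "int64", "min_depth": "int64",
         "in_segdup": "bool", "reportable": "bool"})


def first_exon_bias_report(depth: DepthTrack,
                           targets: Sequence[TargetRegion],
                           flag_fraction: float = 0.6) -> pd.DataFrame:
    """Mean depth grouped by exon index, flagging depressed groups.

    A group is flagged when its mean depth falls below `flag_fraction` of the
    global targeted mean — the signature of systematic first-exon (GC-rich)
    capture loss.
    """
    records = []
    for region in targets:
        d = depth.region_depths(region)
        records.append((region.exon_index, int(d.sum()), d.size))
    df = pd.DataFrame(records, columns=["exon_index", "depth_sum", "n_bases"])
    grouped = df.groupby("exon_index", as_index=False).sum()
    grouped["mean_depth"] = grouped["depth_sum"] / grouped["n_bases"]
    global_mean = df["depth_sum"].sum() / df["n_bases"].sum()
    grouped["global_mean_depth"] = global_mean
    grouped["flagged"] = grouped["mean_depth"] < flag_fraction * global_mean
    return grouped[["exon_index", "n_bases", "mean_depth",
                    "global_mean_depth", "flagged"]]
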