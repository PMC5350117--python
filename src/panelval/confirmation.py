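"""Orthogonal (Sanger) confirmation of discordant calls and corrected metrics.

Provisional FP/FN calls from the truth-vs-evaluation comparison are re-tested
by BigDye/Sanger sequencing.  A confirmed-present FP becomes a true positive
(the reference set was wrong); a confirmed-absent FP is removed from the
reportable call set (the clinical workflow confirms before reporting, so the
artifactual call never reaches a report) while an audit trail preserves the
raw count; a confirmed-absent FN dissolves; a confirmed-present FN remains a
miss.  Failed reactions exclude the site with a warning.  Corrected metrics
are then recomputed over targeted bases that reached the reportable depth
floor — bases below it are handled by Sanger backfill, not by NGS metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .concordance import (CallSet, GenotypeClass, JoinedSites, MetricsBundle,
                          VariantKey, build_confusion, compute_metrics)
from .coverage import DEFAULT_DEPTH_THRESHOLD, DepthTrack

logger = logging.getLogger(__name__)

CONFIRMED_PRESENT = "confirmed_present"
CONFIRMED_ABSENT = "confirmed_absent"
FAILED = "failed"
_OUTCOMES = (CONFIRMED_PRESENT, CONFIRMED_ABSENT, FAILED)


@dataclass(frozen=True)
class ConfirmationRecord:
    key: VariantKey
    outcome: str
    method: str = "BigDye"

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"unknown confirmation outcome {self.outcome!r}")


class ContradictoryConfirmationError(ValueError):
    """Two records for one variant/method disagree on the outcome."""


@dataclass
class CorrectionAudit:
    """Site-level bookkeeping of what the confirmation step did."""

    fp_confirmed_present: int = 0
    fp_removed_confirmed_absent: int = 0
    fn_dissolved_confirmed_absent: int = 0
    fn_confirmed_present: int = 0
    failed_excluded: list[VariantKey] = field(default_factory=list)
    ignored_nondiscordant: list[VariantKey] = field(default_factory=list)
    depth_excluded: int = 0
    removed_keys: list[VariantKey] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "fp_confirmed_present": self.fp_confirmed_present,
            "fp_removed_confirmed_absent": self.fp_removed_confirmed_absent,
            "fn_dissolved_confirmed_absent": self.fn_dissolved_confirmed_absent,
            "fn_confirmed_present": self.fn_confirmed_present,
            "n_failed_excluded": len(self.failed_excluded),
            "n_ignored_nondiscordant": len(self.ignored_nondiscordant),
            "depth_excluded": self.depth_excluded,
        }


def _is_provisional_fp(t_gt: GenotypeClass, e_gt: GenotypeClass) -> bool:
    return e_gt.is_nonref and t_gt is GenotypeClass.HOM_REF


def _is_provisional_fn(t_gt: GenotypeClass, e_gt: GenotypeClass) -> bool:
    return t_gt.is_nonref and e_gt in (GenotypeClass.HOM_REF,
                                       GenotypeClass.MISSING)


def apply_confirmations(joined: JoinedSites,
                        confirmations: list[ConfirmationRecord],
                        ) -> tuple[JoinedSites, CorrectionAudit]:
    """Reclassify joined sites according to orthogonal confirmation outcomes.

    Returns the corrected joined table and an audit.  Records for sites that
    are not provisional FP/FN are warned about and ignored; contradictory
    duplicates raise.  An empty confirmation list returns the table unchanged.
    """
    by_key: dict[tuple[VariantKey, str], str] = {}
    for rec in confirmations:
        k = (rec.key, rec.method)
        if k in by_key and by_key[k] != rec.outcome:
            raise ContradictoryConfirmationError(
                f"contradictory outcomes for {rec.key} via {rec.method}")
        by_key[k] = rec.outcome

    corrected: JoinedSites = dict(joined)
    audit = CorrectionAudit()
    for (key, method), outcome in by_key.items():
        if key not in corrected:
            audit.ignored_nondiscordant.append(key)
            logger.warning("confirmation for unseen site %s ignored", key)
            continue
        t_gt, e_gt = corrected[key]
        if outcome == FAILED:
            audit.failed_excluded.append(key)
            del corrected[key]
            logger.warning("failed %s reaction at %s: site excluded",
                           method, key)
            continue
        if _is_provisional_fp(t_gt, e_gt):
            if outcome == CONFIRMED_PRESENT:
                # reference set lacked a real variant: becomes TP
                corrected[key] = (e_gt, e_gt)
                audit.fp_confirmed_present += 1
            else:
                # artifactual call: removed from the reportable call set
                del corrected[key]
                audit.fp_removed_confirmed_absent += 1
                audit.removed_keys.append(key)
        elif _is_provisional_fn(t_gt, e_gt):
            if outcome == CONFIRMED_ABSENT:
                # truth record was wrong: site is reference in reality
                corrected[key] = (GenotypeClass.HOM_REF, GenotypeClass.HOM_REF)
                audit.fn_dissolved_confirmed_absent += 1
            else:
                audit.fn_confirmed_present += 1  # remains a genuine miss
        else:
            audit.ignored_nondiscordant.append(key)
            logger.warning("confirmation for non-discordant site %s ignored",
                           key)
    return corrected, audit


def restrict_to_depth(joined: JoinedSites, depth: DepthTrack,
                      threshold: int = DEFAULT_DEPTH_THRESHOLD,
                      ) -> tuple[JoinedSites, int]:
    """Drop sites whose base depth is below the reportable floor."""
    kept = {k: v for k, v in joined.items()
            if depth.get(k.chrom, k.pos) >= threshold}
    return kept, len(joined) - len(kept)


def corrected_metrics(joined: JoinedSites,
                      confirmations: list[ConfirmationRecord],
                      depth: DepthTrack | None = None,
                      threshold: int = DEFAULT_DEPTH_THRESHOLD,
                      ) -> tuple[MetricsBundle, CorrectionAudit]:
    """Confirmation-corrected metric suite over adequately covered sites.

    With no confirmations and no depth track this reduces exactly to the
    provisional metrics.
    """
    corrected, audit = apply_confirmations(joined, confirmations)
    if depth is not None:
        corrected, n_dropped = restrict_to_depth(corrected, depth, threshold)
        audit.depth_excluded = n_dropped
    return compute_metrics(build_confusion(corrected)), audit


def confirm_all_in_eval_favor(joined: JoinedSites) -> list[ConfirmationRecord]:
    """Confirmation list asserting the evaluation callset is right at every
    provisional FP/FN — the best-case adjudication a validation can reach."""
    records = []
    for key, (t_gt, e_gt) in joined.items():
        if _is_provisional_fp(t_gt, e_gt):
            records.append(ConfirmationRecord(key, CONFIRMED_PRESENT))
        elif _is_provisional_fn(t_gt, e_gt):
            records.append(ConfirmationRecord(key, CONFIRMED_ABSENT))
    return records
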