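"""Genotype concordance between a truth callset and an evaluation callset.

The validation design compares per-sample genotype calls over panel targets
against a genotype-known reference (or another replicate).  Both callsets are
treated as complete over their assessed regions, so a site recorded in one
set but absent from the other — while inside the other's assessed regions —
is homozygous reference there; outside the assessed regions it is missing.

From the joined sites a 4x4 genotype confusion table (hom-ref / het /
hom-alt / missing, evaluation rows x truth columns) is built, and from it
the standard panel-validation metric suite:

  OGC   overall genotype concordance: identical genotype among co-called sites
  NRS   non-reference sensitivity: truth non-ref sites called non-ref at all
  NRD   non-reference discrepancy: discordant / co-called sites, ignoring
        concordant hom-ref pairs
  NRGC  non-reference genotype concordance: truth non-ref sites with the
        exact genotype reproduced
  TP/FP/FN and the derived precision, sensitivity (= 1 - FN rate) and
  call-level specificity (= 1 - FP rate)

Sites are variant-level: one biallelic (chrom, pos, ref, alt) key per site,
multi-allelic records having been decomposed upstream.  Metrics default to
SNVs only; indel detection capability is summarized separately by maximum
properly-detected indel length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from ._util import NA
from .regions import RegionIndex


class GenotypeClass(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_nonref(self) -> bool:
        return self in (GenotypeClass.HET, GenotypeClass.HOM_ALT)

    @property
    def is_called(self) -> bool:
        return self is not GenotypeClass.MISSING


# Fixed axis order of the confusion table.
GT_ORDER = (GenotypeClass.HOM_REF, GenotypeClass.HET,
            GenotypeClass.HOM_ALT, GenotypeClass.MISSING)
_GT_IDX = {g: i for i, g in enumerate(GT_ORDER)}

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class VariantKey:
    """Biallelic variant identity: chrom, 1-based pos, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(f"bad alleles {self.ref}>{self.alt}")
        if not (_VALID_BASES.issuperset(self.ref)
                and _VALID_BASES.issuperset(self.alt)):
            raise ValueError(f"alleles must be A/C/G/T strings: "
                             f"{self.ref}>{self.alt}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def left_trim(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Trim shared allele context: common suffix, then common prefix
    (advancing pos).  No realignment/left-shifting beyond the record itself.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class CallSet:
    """One sample's genotype calls over a set of assessed target regions.

    Absence of a key from `calls` means hom-ref inside `assessed_regions`
    and missing outside them.
    """

    sample_id: str
    calls: dict[VariantKey, GenotypeClass] = field(default_factory=dict)
    assessed_regions: RegionIndex = field(default_factory=RegionIndex)

    def genotype_at(self, key: VariantKey) -> GenotypeClass:
        gt = self.calls.get(key)
        if gt is not None:
            return gt
        if self.assessed_regions.contains(key.chrom, key.pos):
            return GenotypeClass.HOM_REF
        return GenotypeClass.MISSING

    def nonref_keys(self) -> list[VariantKey]:
        return sorted(k for k, g in self.calls.items() if g.is_nonref)


class RefMismatchError(ValueError):
    """Two callsets disagree on the reference allele at a shared locus."""


JoinedSites = dict[VariantKey, tuple[GenotypeClass, GenotypeClass]]


def harmonize_sites(truth: CallSet, eval_: CallSet, targets: RegionIndex,
                    snv_only: bool = True) -> JoinedSites:
    """Join the two callsets site-by-site over the panel targets.

    Returns VariantKey -> (truth genotype, evaluation genotype) for the union
    of recorded sites restricted to `targets`, applying the
    absence-means-hom-ref rule within each set's assessed regions.  Matching
    requires identical chrom, pos, ref and alt; a conflicting REF allele at
    the same chrom/pos across the two sets raises RefMismatchError.
    """
    if len(targets) == 0:
        raise ValueError("no target regions supplied")
    # Same locus (chrom, pos) with same-length REF must agree on REF;
    # different lengths are legitimate for decomposed indels.
    ref_seen: dict[tuple[str, int, int], str] = {}
    for cs in (truth, eval_):
        for key in cs.calls:
            locus = (key.chrom, key.pos, len(key.ref))
            prev = ref_seen.setdefault(locus, key.ref)
            if prev != key.ref:
                raise RefMismatchError(
                    f"inconsistent REF at {key.chrom}:{key.pos} "
                    f"({prev!r} vs {key.ref!r})")
    joined: JoinedSites = {}
    for key in set(truth.calls) | set(eval_.calls):
        if snv_only and not key.is_snv:
            continue
        if not targets.contains(key.chrom, key.pos):
            continue
        joined[key] = (truth.genotype_at(key), eval_.genotype_at(key))
    return joined


@dataclass
class ConcordanceTable:
    """4x4 genotype confusion counts: rows evaluation, columns truth."""

    counts: np.ndarray  # shape (4, 4), int
    n_sites: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ValueError("confusion table must be 4x4 non-negative")
        if int(self.counts.sum()) != self.n_sites:
            raise ValueError("confusion cells must sum to n_sites")

    def cell(self, eval_gt: GenotypeClass, truth_gt: GenotypeClass) -> int:
        return int(self.counts[_GT_IDX[eval_gt], _GT_IDX[truth_gt]])


def build_confusion(joined: JoinedSites) -> ConcordanceTable:
    counts = np.zeros((4, 4), dtype=np.int64)
    for t_gt, e_gt in joined.values():
        counts[_GT_IDX[e_gt], _GT_IDX[t_gt]] += 1
    return ConcordanceTable(counts=counts, n_sites=len(joined))


@dataclass
class MetricsBundle:
    """Variant-level validation metrics; None marks an undefined (0/0) value.

    `specificity` is the call-level 1 - FP rate the validation tables use;
    `specificity_tn` is the site-level true-negative-based alternative
    TN/(TN+FP) over the joined sites, emitted separately because the two
    definitions differ substantially on sparse variant tables.
    """

    tp: int
    fp: int
    fn: int
    n_sites: int
    ogc: float | None
    nrs: float | None
    nrd: float | None
    nrgc: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    specificity_tn: float | None
    fp_rate: float | None
    fn_rate: float | None

    _METRIC_FIELDS = ("ogc", "nrs", "nrd", "nrgc", "precision", "sensitivity",
                      "specificity", "specificity_tn", "fp_rate", "fn_rate")

    def as_dict(self, stringify_na: bool = False) -> dict:
        out: dict = {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                     "n_sites": self.n_sites}
        for name in self._METRIC_FIELDS:
            v = getattr(self, name)
            out[name] = "NA" if (v is NA and stringify_na) else v
        return out


def _ratio(num: int, den: int) -> float | None:
    return NA if den == 0 else float(Fraction(num, den))


def compute_metrics(table: ConcordanceTable) -> MetricsBundle:
    """Derive the full metric suite from a genotype confusion table.

    Zero denominators yield None (serialized "NA"), never an exception.
    """
    C = table.counts
    i = _GT_IDX
    called = [i[g] for g in GT_ORDER if g is not GenotypeClass.MISSING]
    nonref = [i[GenotypeClass.HET], i[GenotypeClass.HOM_ALT]]
    homref = i[GenotypeClass.HOM_REF]
    missing = i[GenotypeClass.MISSING]

    both_called = int(C[np.ix_(called, called)].sum())
    concordant_called = int(sum(C[j, j] for j in called))
    concordant_homref = int(C[homref, homref])

    truth_nonref = int(C[:, nonref].sum())
    nrs_num = int(C[np.ix_(nonref, nonref)].sum())
    nrgc_num = int(C[i[GenotypeClass.HET], i[GenotypeClass.HET]]
                   + C[i[GenotypeClass.HOM_ALT], i[GenotypeClass.HOM_ALT]])

    tp = nrs_num  # non-ref in both callsets
    fp = int(C[nonref, homref].sum())  # eval non-ref, truth hom-ref
    fn = int(C[homref, nonref].sum() + C[missing, nonref].sum())

    fp_rate = _ratio(fp, tp + fp)
    fn_rate = _ratio(fn, tp + fn)
    tn = concordant_homref
    return MetricsBundle(
        tp=tp, fp=fp, fn=fn, n_sites=table.n_sites,
        ogc=_ratio(concordant_called, both_called),
        nrs=_ratio(nrs_num, truth_nonref),
        nrd=_ratio(both_called - concordant_called,
                   both_called - concordant_homref),
        nrgc=_ratio(nrgc_num, truth_nonref),
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        # call-level specificity, 1 - fp_rate, computed as the exact
        # complementary ratio tp/(tp+fp)
        specificity=_ratio(tp, tp + fp),
        specificity_tn=_ratio(tn, tn + fp),
        fp_rate=fp_rate,
        fn_rate=fn_rate,
    )


def metrics_for_pair(truth: CallSet, eval_: CallSet, targets: RegionIndex,
                     snv_only: bool = True) -> MetricsBundle:
    """Convenience: harmonize, tally and compute in one call."""
    return compute_metrics(build_confusion(
        harmonize_sites(truth, eval_, targets, snv_only=snv_only)))


def indel_detection_summary(callset: CallSet) -> tuple[int, int]:
    """(max homozygous, max heterozygous) indel length properly detected.

    Length is |len(ref) - len(alt)|; 0 when the callset carries no indel in
    the given genotype state.
    """
    max_hom = max_het = 0
    for key, gt in callset.calls.items():
        if key.indel_length == 0:
            continue
        if gt is GenotypeClass.HOM_ALT:
            max_hom = max(max_hom, key.indel_length)
        elif gt is GenotypeClass.HET:
            max_het = max(max_het, key.indel_length)
    return max_hom, max_het
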