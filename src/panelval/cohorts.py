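"""Worked-example clinical cohort for the triage and cohort-reporting stages.

Builds a 12-month diagnostic caseload typical of a cardiovascular NGS
service: 33 patients, 35 panel requests (two patients reflexed to the
comprehensive cardiomyopathy panel after a negative sub-panel), with the
comprehensive panel making up about half of requests, the aortic-disease
panel next, no ARVC orders, and roughly one in five requests positive.

Every case carries concrete annotated variants engineered to classify into
the intended category under the default rules, so cohort percentages are
produced by running the real triage path end to end, not by assignment.
"""

from __future__ import annotations

from .concordance import VariantKey
from .registry import PanelRegistry, load_panels
from .triage import (AnnotatedVariant, CaseReport, RuleConfig,
                     build_case_report)

# (panel, positives, vus_only, negatives) per panel ordered for testing.
COHORT_COMPOSITION = (
    ("CMP", 5, 7, 6),
    ("TAAD", 1, 5, 4),
    ("HCM", 0, 0, 2),
    ("DCM_LVNC", 1, 2, 1),
    ("MFS_LDS", 0, 1, 0),
)

# A representative reported gene per panel (member of that panel).
_PANEL_GENE = {"CMP": "MYH7", "TAAD": "FBN1", "HCM": "MYBPC3",
               "DCM_LVNC": "LMNA", "MFS_LDS": "TGFBR2"}

# Patients with a second (reflex CMP) request after a negative first panel.
_REFLEXED_PATIENTS = ("P24", "P32")


def _pathogenic_variant(gene: str, pos: int) -> AnnotatedVariant:
    # database-known truncating allele, unobserved in population references
    return AnnotatedVariant(
        key=VariantKey("chr1", pos, "C", "T"), gene=gene,
        consequence="stop_gain", db_presence=True,
        insilico_scores={"SIFT": "D", "MutationTaster": "D"})


def _vus_variant(gene: str, pos: int) -> AnnotatedVariant:
    # rare missense with split in-silico evidence: no rule fires
    return AnnotatedVariant(
        key=VariantKey("chr1", pos, "G", "A"), gene=gene,
        consequence="non_synonymous", db_presence=False,
        af_1000g=0.0005,
        insilico_scores={"SIFT": "D", "PolyPhen": "benign"})


def _benign_variant(gene: str, pos: int) -> AnnotatedVariant:
    # common polymorphism
    return AnnotatedVariant(
        key=VariantKey("chr1", pos, "T", "C"), gene=gene,
        consequence="synonymous", db_presence=False, af_1000g=0.21)


def example_cohort(registry: PanelRegistry | None = None,
                   rules: RuleConfig | None = None) -> list[CaseReport]:
    """The 35-request worked-example caseload as fully triaged CaseReports."""
    registry = registry or load_panels()
    reports: list[CaseReport] = []
    patient_counter = 0
    reflex_iter = iter(_REFLEXED_PATIENTS)
    pos_counter = 1000

    def next_patient() -> str:
        nonlocal patient_counter
        patient_counter += 1
        return f"P{patient_counter:02d}"

    for panel_name, n_pos, n_vus, n_neg in COHORT_COMPOSITION:
        panel = registry[panel_name]
        gene = _PANEL_GENE[panel_name]
        for kind, count in (("positive", n_pos), ("vus_only", n_vus),
                            ("negative", n_neg)):
            for _ in range(count):
                pos_counter += 10
                if kind == "positive":
                    variants = [_pathogenic_variant(gene, pos_counter),
                                _vus_variant(gene, pos_counter + 1)]
                elif kind == "vus_only":
                    variants = [_vus_variant(gene, pos_counter),
                                _benign_variant(gene, pos_counter + 1)]
                else:
                    variants = [_benign_variant(gene, pos_counter)]
                # reflex-CMP requests belong to an existing patient
                if panel_name == "CMP" and kind != "positive":
                    reflexed = next(reflex_iter, None)
                else:
                    reflexed = None
                case_id = reflexed if reflexed else next_patient()
                reports.append(build_case_report(case_id, panel,
                                                 variants, rules))
    return reports
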