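"""Variant triage: panel restriction, database split, classification, case
results and cohort summaries.

Clinical reporting restricts the annotated variant table to the genes of the
requested panel, splits variants by presence in a curated disease-mutation
database (which pre-sorts the review queue), classifies each variant into
one of six categories (pathogenic, likely pathogenic, gene modifier, VUS,
likely benign, benign), and rolls the classified variants up into a per-case
result: positive (at least one pathogenic / likely pathogenic), VUS-only, or
negative.  Variants inside unvalidated segmental-duplication loci cannot be
orthogonally confirmed and are excluded from the reportable set.

Classification is a deterministic ordered-rule engine.  The ACMG-style
evidence combination is necessarily approximated here as explicit rules with
every threshold exposed in config; frequency ceilings default to relaxed
values fitting disorders where a non-trivial fraction of cases carry two or
more deleterious variants, and the fallback when no rule fires is VUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._util import pct_int
from .concordance import VariantKey
from .registry import PanelDefinition, PanelRegistry, canonical_panel_name

CATEGORIES = ("pathogenic", "likely_pathogenic", "gene_modifier", "VUS",
              "likely_benign", "benign")
RESULTS = ("positive", "vus_only", "negative")

TRUNCATING_CONSEQUENCES = frozenset(
    {"stop_gain", "stopgain", "frameshift", "frameshift_insertion",
     "frameshift_deletion", "splice_site", "splicing", "start_loss"})

#: In-silico tools whose calls feed the deleterious-consensus count.
INSILICO_TOOLS = ("SIFT", "PolyPhen", "LRT", "MutationTaster", "PhyloP",
                  "GERP++")

_DELETERIOUS_STRINGS = frozenset({"d", "damaging", "deleterious", "disease",
                                  "disease_causing", "conserved"})


@dataclass(frozen=True)
class AnnotatedVariant:
    """One reported variant with the annotation columns triage consumes."""

    key: VariantKey
    gene: str
    consequence: str = "non_synonymous"
    db_presence: bool = False
    af_1000g: float | None = None
    af_esp6500: float | None = None
    insilico_scores: dict = field(default_factory=dict)
    quality: dict = field(default_factory=dict)
    in_segdup: bool = False
    segdup_validated: bool = False

    def __post_init__(self) -> None:
        for af in (self.af_1000g, self.af_esp6500):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency out of [0,1]: {af}")

    @property
    def max_af(self) -> float | None:
        """Highest observed population allele frequency; None if unobserved."""
        observed = [af for af in (self.af_1000g, self.af_esp6500)
                    if af is not None]
        return max(observed) if observed else None

    @property
    def n_deleterious_calls(self) -> int:
        n = 0
        for value in self.insilico_scores.values():
            if isinstance(value, str):
                n += value.strip().lower() in _DELETERIOUS_STRINGS
            elif value is not None:
                n += float(value) >= 0.5
        return n

    @property
    def reportable(self) -> bool:
        return (not self.in_segdup) or self.segdup_validated


class RuleConfigError(ValueError):
    """Malformed classification rule configuration."""


_CONDITION_KEYS = frozenset({"db_presence", "consequence_in", "truncating",
                             "max_af_ge", "max_af_lt",
                             "insilico_deleterious_ge",
                             "insilico_deleterious_lt", "in_modifier_list"})

#: Default ordered rules.  First match wins; no match -> VUS.  Frequency
#: ceilings (0.05 benign / 0.01 likely benign / 1e-3 rare) are the relaxed,
#: cardio-adapted values and are meant to be overridden per deployment.
DEFAULT_RULES: list[dict] = [
    {"category": "benign", "when": {"max_af_ge": 0.05}},
    {"category": "likely_benign", "when": {"max_af_ge": 0.01}},
    {"category": "gene_modifier", "when": {"in_modifier_list": True}},
    {"category": "pathogenic",
     "when": {"db_presence": True, "truncating": True, "max_af_lt": 1e-3}},
    {"category": "likely_pathogenic",
     "when": {"db_presence": True, "insilico_deleterious_ge": 4,
              "max_af_lt": 1e-3}},
    {"category": "likely_pathogenic",
     "when": {"truncating": True, "max_af_lt": 1e-4}},
    {"category": "likely_benign",
     "when": {"consequence_in": ["synonymous"], "db_presence": False,
              "insilico_deleterious_lt": 2}},
]


@dataclass
class RuleConfig:
    rules: list[dict]
    modifier_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for rule in self.rules:
            if rule.get("category") not in CATEGORIES:
                raise RuleConfigError(f"unknown category in rule: {rule}")
            when = rule.get("when")
            if not isinstance(when, dict) or not when:
                raise RuleConfigError(f"rule without conditions: {rule}")
            unknown = set(when) - _CONDITION_KEYS
            if unknown:
                raise RuleConfigError(f"unknown condition keys {unknown}")

    @classmethod
    def default(cls) -> "RuleConfig":
        return cls(rules=[dict(r) for r in DEFAULT_RULES])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(rules=raw.get("rules", []),
                   modifier_genes=frozenset(
                       g.upper() for g in raw.get("modifier_genes", [])))


def _rule_matches(variant: AnnotatedVariant, when: dict,
                  config: RuleConfig) -> bool:
    af = variant.max_af
    for cond, expected in when.items():
        if cond == "db_presence":
            if variant.db_presence != bool(expected):
                return False
        elif cond == "consequence_in":
            if variant.consequence.lower() not in {c.lower() for c in expected}:
                return False
        elif cond == "truncating":
            is_trunc = variant.consequence.lower() in TRUNCATING_CONSEQUENCES
            if is_trunc != bool(expected):
                return False
        elif cond == "max_af_ge":
            if af is None or af < expected:
                return False
        elif cond == "max_af_lt":
            # an unobserved frequency satisfies any rarity ceiling
            if af is not None and af >= expected:
                return False
        elif cond == "insilico_deleterious_ge":
            if variant.n_deleterious_calls < expected:
                return False
        elif cond == "insilico_deleterious_lt":
            if variant.n_deleterious_calls >= expected:
                return False
        elif cond == "in_modifier_list":
            if (variant.gene.upper() in config.modifier_genes) != bool(expected):
                return False
    return True


def classify_variant(variant: AnnotatedVariant,
                     rules: RuleConfig | None = None) -> str:
    """Deterministic category from the ordered rule list; default VUS."""
    config = rules or RuleConfig.default()
    for rule in config.rules:
        if _rule_matches(variant, rule["when"], config):
            return rule["category"]
    return "VUS"


def restrict_to_panel(variants: list[AnnotatedVariant],
                      panel: PanelDefinition) -> list[AnnotatedVariant]:
    """Keep only variants in the requested panel's genes, order preserved."""
    return [v for v in variants if v.gene.upper() in panel.genes]


def split_by_database(variants: list[AnnotatedVariant],
                      ) -> tuple[list[AnnotatedVariant], list[AnnotatedVariant]]:
    """Partition into (known in the disease database, novel)."""
    in_db = [v for v in variants if v.db_presence]
    novel = [v for v in variants if not v.db_presence]
    return in_db, novel


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: AnnotatedVariant
    category: str
    confirmation_status: str = "not_required"


@dataclass(frozen=True)
class CaseReport:
    case_id: str
    panel: str
    variants: tuple[ClassifiedVariant, ...]
    result: str


def case_result(classified: list[ClassifiedVariant]) -> str:
    """positive / vus_only / negative from reportable classified variants."""
    reportable = [cv for cv in classified if cv.variant.reportable]
    cats = {cv.category for cv in reportable}
    if cats & {"pathogenic", "likely_pathogenic"}:
        return "positive"
    if "VUS" in cats:
        return "vus_only"
    return "negative"


def build_case_report(case_id: str, panel: PanelDefinition,
                      variants: list[AnnotatedVariant],
                      rules: RuleConfig | None = None) -> CaseReport:
    """Restrict, classify and summarize one case on one panel."""
    in_panel = restrict_to_panel(variants, panel)
    classified = []
    for variant in in_panel:
        category = classify_variant(variant, rules)
        needs_confirmation = category in ("pathogenic", "likely_pathogenic",
                                          "VUS")
        classified.append(ClassifiedVariant(
            variant=variant, category=category,
            confirmation_status=("pending" if needs_confirmation
                                 else "not_required")))
    return CaseReport(case_id=case_id, panel=panel.name,
                      variants=tuple(classified),
                      result=case_result(classified))


def cohort_summary(reports: list[CaseReport]) -> dict:
    """Request distribution and result rates, with display percentages.

    Display percentages are integers (half-up); raw counts are retained so
    every percentage is recomputable from the same document.
    """
    if not reports:
        raise ValueError("no case reports")
    total = len(reports)
    per_panel: dict[str, dict] = {}
    for report in reports:
        panel = canonical_panel_name(report.panel)
        entry = per_panel.setdefault(
            panel, {"requests": 0,
                    **{r: 0 for r in RESULTS}})
        entry["requests"] += 1
        entry[report.result] += 1
    for panel, entry in per_panel.items():
        entry["share_pct"] = pct_int(entry["requests"], total)
        for r in RESULTS:
            entry[f"{r}_pct"] = pct_int(entry[r], entry["requests"])
    overall = {r: sum(e[r] for e in per_panel.values()) for r in RESULTS}
    return {
        "n_requests": total,
        "n_patients": len({r.case_id for r in reports}),
        "per_panel": dict(sorted(per_panel.items())),
        "overall": {
            **overall,
            **{f"{r}_pct": pct_int(overall[r], total) for r in RESULTS},
        },
    }
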