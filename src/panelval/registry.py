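"""Panel registry: named gene panels, reflex ordering, actionable-gene overlap.

A diagnostic service carves a large capture (thousands of genes) into
phenotype-specific sub-panels; two of them (comprehensive cardiomyopathy and
the aortic-disease panel) can additionally be run as a "reflex" — analyzed
only after, and because, a first sub-panel came back negative, at the
ordering physician's request.  Gene identity is by HGNC symbol, uppercased
on ingest; transcripts and coordinates are metadata, not identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

CANONICAL_PANELS = ("CMP", "HCM", "DCM_LVNC", "ARVC", "MFS_LDS", "TAAD")

# Both spellings appear in clinical requisitions; canonicalized on load.
_PANEL_ALIASES = {
    "CMP": "CMP",
    "HCM": "HCM",
    "DCM": "DCM_LVNC",
    "DCM/LVNC": "DCM_LVNC",
    "DCM_LVNC": "DCM_LVNC",
    "ARVC": "ARVC",
    "MFS": "MFS_LDS",
    "MFLS": "MFS_LDS",
    "MFS/LDS": "MFS_LDS",
    "MFS_LDS": "MFS_LDS",
    "TAAD": "TAAD",
}


class PanelConfigError(ValueError):
    """Raised for malformed panel configuration files."""


def canonical_panel_name(name: str) -> str:
    key = str(name).strip().upper().replace("-", "_")
    for candidate in (key, key.replace("_", "/")):
        if candidate in _PANEL_ALIASES:
            return _PANEL_ALIASES[candidate]
    raise PanelConfigError(f"unknown panel name: {name!r}")


def normalize_symbol(symbol: str) -> str:
    s = str(symbol).strip().upper()
    if not s:
        raise PanelConfigError("empty gene symbol")
    return s


@dataclass(frozen=True)
class PanelDefinition:
    """A named gene set, optionally orderable as a reflex follow-up."""

    name: str
    genes: frozenset[str]
    reflex_available: bool = False
    description: str = ""

    def gene_count(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.genes


@dataclass(frozen=True)
class ActionableGeneList:
    """Union of the per-panel known/expected-pathogenic actionable genes."""

    genes: frozenset[str]


class PanelRegistry:
    """All configured panels, keyed by canonical name."""

    def __init__(self, panels: dict[str, PanelDefinition]):
        self.panels = panels

    def __getitem__(self, name: str) -> PanelDefinition:
        return self.panels[canonical_panel_name(name)]

    def __iter__(self):
        return iter(self.panels.values())

    def __len__(self) -> int:
        return len(self.panels)


def _packaged(name: str):
    return resources.files("panelval.data").joinpath(name)


def load_panels(config_path: str | Path | None = None) -> PanelRegistry:
    """Load panel definitions from YAML; default is the packaged config.

    The config is a mapping with a ``panels`` list; each entry has ``name``,
    ``genes`` (non-empty list) and optional ``reflex_available`` /
    ``description``.  Duplicate panel names and empty gene lists are errors.
    """
    if config_path is None:
        raw = yaml.safe_load(_packaged("panels.yaml").read_text())
    else:
        path = Path(config_path)
        if not path.exists():
            raise FileNotFoundError(f"panel config not found: {path}")
        raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "panels" not in raw:
        raise PanelConfigError("panel config must contain a 'panels' list")
    panels: dict[str, PanelDefinition] = {}
    for entry in raw["panels"]:
        name = canonical_panel_name(entry["name"])
        if name in panels:
            raise PanelConfigError(f"duplicate panel definition: {name}")
        genes = [normalize_symbol(g) for g in entry.get("genes", [])]
        if not genes:
            raise PanelConfigError(f"panel {name} lists no genes")
        panels[name] = PanelDefinition(
            name=name,
            genes=frozenset(genes),
            reflex_available=bool(entry.get("reflex_available", False)),
            description=str(entry.get("description", "")),
        )
    return PanelRegistry(panels)


def load_actionable(config_path: str | Path | None = None) -> ActionableGeneList:
    """Union of the per-panel KP/EP actionable gene lists."""
    if config_path is None:
        raw = yaml.safe_load(_packaged("actionable_genes.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(config_path).read_text())
    union: set[str] = set()
    for genes in raw["actionable"].values():
        union.update(normalize_symbol(g) for g in genes)
    return ActionableGeneList(genes=frozenset(union))


def panel_gene_count(panel: PanelDefinition) -> int:
    return panel.gene_count()


def actionable_intersection(panel: PanelDefinition,
                            actionable: ActionableGeneList) -> list[str]:
    """Sorted list of the panel's genes that carry actionable KP/EP variants."""
    return sorted(panel.genes & actionable.genes)


class ReflexError(ValueError):
    """Reflex requested for a panel with no configured reflex option."""


def resolve_reflex(registry: PanelRegistry, ordered_panel: str,
                   first_result: str, reflex_requested: bool = False,
                   reflex_panel: str = "CMP") -> list[str]:
    """Panels to analyze for one order.

    The reflex panel is appended only when the first panel's result is
    negative AND the physician requested the reflex AND the configured reflex
    panel actually offers reflex testing.  Positive or VUS-only first results
    never trigger a reflex.
    """
    ordered = canonical_panel_name(ordered_panel)
    if ordered not in registry.panels:
        raise KeyError(f"panel not configured: {ordered}")
    if not reflex_requested or first_result != "negative":
        return [ordered]
    reflex = canonical_panel_name(reflex_panel)
    target = registry.panels.get(reflex)
    if target is None or not target.reflex_available:
        raise ReflexError(f"no reflex option configured for {reflex}")
    return [ordered, reflex]
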