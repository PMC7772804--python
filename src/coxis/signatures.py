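"""Built-in COX-IS gene lists and alias-aware symbol resolution.

The COX-IS contrasts two COX-2-regulated inflammatory programs: a
cancer-promoting (CP) list of 9 genes (angiogenic / myeloid chemokines and
acute-phase cytokines such as VEGFA, CXCL1, IL6, IL1B) and a
cancer-inhibitory (CI) list of 15 genes (type-1 immunity effectors such as
CXCL9/10/11, IFNG, GZMA/B, PRF1 and the CD8 / NK lineage factors EOMES,
TBX21).  Legacy symbols in the lists (IL8) are bridged to current HGNC
symbols (CXCL8) through a small shipped alias table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from .datatypes import CoxisError, GeneSet, SignaturePair

__all__ = [
    "CP_GENES",
    "CI_GENES",
    "DEFAULT_ALIASES",
    "ResolutionReport",
    "builtin_coxis",
    "resolve_genes",
    "builtin_marker_sets",
    "MarkerRegistry",
]

# Cancer-promoting ("pos" / CP) program: 9 genes.
CP_GENES: tuple[str, ...] = (
    "VEGFA", "CCL2", "IL8", "CXCL1", "CXCL2", "CSF3", "IL6", "IL1B", "IL1A",
)

# Cancer-inhibitory ("neg" / CI) program: 15 genes.
CI_GENES: tuple[str, ...] = (
    "CCL5", "CXCL9", "CXCL10", "CXCL11", "IL12A", "IL12B", "IFNG",
    "CD8A", "CD8B", "GZMA", "GZMB", "EOMES", "PRF1", "STAT1", "TBX21",
)

# Minimal legacy-symbol bridge, extensible by config.  Bidirectional pairs
# are listed in both directions so resolution needs only one alias hop.
DEFAULT_ALIASES: dict[str, str] = {
    "IL8": "CXCL8",
    "CXCL8": "IL8",
    "GRO1": "CXCL1",
    "GROA": "CXCL1",
    "GRO2": "CXCL2",
    "GROB": "CXCL2",
    "MCP1": "CCL2",
    "SCYA2": "CCL2",
    "MIG": "CXCL9",
    "IP10": "CXCL10",
    "ITAC": "CXCL11",
    "RANTES": "CCL5",
    "SCYA5": "CCL5",
    "GCSF": "CSF3",
    "TBET": "TBX21",
}


def builtin_coxis() -> SignaturePair:
    """The built-in COX-IS signature pair (9 CP vs 15 CI genes)."""
    return SignaturePair(name="COX-IS", pos_genes=CP_GENES, neg_genes=CI_GENES)


@dataclass
class ResolutionReport:
    """Outcome of matching requested symbols against a matrix's gene ids."""

    requested: list[str]
    matched: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    alias_substitutions: dict[str, str] = field(default_factory=dict)

    @property
    def fraction_matched(self) -> float:
        return len(self.matched) / len(self.requested) if self.requested else 0.0


def resolve_genes(
    genes: Iterable[str],
    matrix_ids: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> ResolutionReport:
    """Match requested symbols against matrix gene ids, case-insensitively,
    allowing a single alias hop for legacy symbols.

    Deterministic and order-preserving: ``matched`` lists the matrix ids in
    the order the symbols were requested.
    """
    if aliases is None:
        aliases = DEFAULT_ALIASES
    alias_up = {k.upper(): v.upper() for k, v in aliases.items()}
    available = {g.upper(): g for g in matrix_ids}
    report = ResolutionReport(requested=[str(g) for g in genes])
    for symbol in report.requested:
        up = symbol.upper()
        if up in available:
            report.matched.append(available[up])
            continue
        alt = alias_up.get(up)
        if alt is not None and alt in available:
            report.matched.append(available[alt])
            report.alias_substitutions[symbol] = available[alt]
            continue
        report.unmatched.append(symbol)
    return report


# Comparator marker sets.  The NK / CD8 / IFN-gamma / TIS gene memberships
# below are plausible literature-style placeholders, NOT verbatim published
# lists; benchmarking against published signatures requires overriding them
# from a GMT file.
_DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "NK": ("NCR1", "KLRB1", "CD160"),
    "CD8": ("CD8A", "CD8B", "GZMK", "GZMM", "FLT3LG"),
    "IFN_GAMMA": ("IFNG", "STAT1", "IDO1", "CXCL9", "CXCL10", "HLA-DRA"),
    "TIS": (
        "CCL5", "CD27", "CD274", "CD276", "CD8A", "CMKLR1", "CXCL9",
        "CXCR6", "HLA-DQA1", "HLA-DRB1", "HLA-E", "IDO1", "LAG3",
        "NKG7", "PDCD1LG2", "PSMB10", "STAT1", "TIGIT",
    ),
}


@dataclass
class MarkerRegistry:
    """Named comparator gene sets, overridable from user GMT files."""

    sets: dict[str, GeneSet] = field(default_factory=dict)
    user_configurable: bool = True

    def get(self, name: str) -> GeneSet:
        if name not in self.sets:
            raise CoxisError(
                f"unknown marker set {name!r}; available: {sorted(self.sets)}"
            )
        return self.sets[name]

    def override(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.name] = gene_set

    def override_from_gmt(self, path) -> None:
        from .io import read_gmt

        for gs in read_gmt(path):
            self.override(gs)

    def names(self) -> list[str]:
        return sorted(self.sets)


def builtin_marker_sets() -> MarkerRegistry:
    """Registry of default comparator sets (NK, CD8, IFN_GAMMA, TIS).

    The defaults are placeholders for interface testing; override from GMT
    for any comparison that must match a published signature.
    """
    reg = MarkerRegistry()
    for name, genes in _DEFAULT_MARKERS.items():
        reg.override(GeneSet(name=name, genes=genes))
    return reg


def bundled_gmt_path(which: str) -> str:
    """Path to a bundled signature GMT ('coxis_pos' or 'coxis_neg')."""
    ref = resources.files("coxis").joinpath("data", f"{which}.gmt")
    return str(ref)
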