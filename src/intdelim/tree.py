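"""Candidate-species discovery from a rooted gene tree.

A taxon is a candidate species when its haplotypes form an exclusive
clade (monophyly on the tree as rooted), optionally additionally
requiring a minimum support value on that clade's node.  This mirrors
the discovery step of integrative delimitation, where mtDNA clades
nominate the units that morphology and niche evidence then validate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .datatypes import TaxonTree, ValidationError

__all__ = ["CandidateEntry", "CandidateReport", "is_monophyletic", "discover_candidates"]


@dataclass(frozen=True)
class CandidateEntry:
    taxon: str
    monophyletic: bool
    support: Optional[float]  # proportion in [0, 1] when available
    tip_count: int
    single_tip: bool

    def is_candidate(self, min_support: Optional[float]) -> bool:
        if not self.monophyletic:
            return False
        if min_support is None:
            return True
        return self.support is not None and self.support >= min_support


@dataclass
class CandidateReport:
    entries: dict  # taxon -> CandidateEntry
    min_support: Optional[float]

    @property
    def candidates(self) -> list[str]:
        return sorted(
            t for t, e in self.entries.items() if e.is_candidate(self.min_support)
        )


def _taxon_mrca(ttree: TaxonTree, taxon: str):
    """The smallest clade (node) containing all the taxon's tips."""
    tips = set(ttree.tips_of(taxon))
    if not tips:
        raise ValidationError(f"unknown taxon {taxon!r}")
    node = ttree.tree.mrca(taxon_labels=sorted(tips))
    return node, tips


def is_monophyletic(ttree: TaxonTree, taxon: str) -> bool:
    """True iff the smallest rooted clade holding all of the taxon's tips
    contains no tip of any other taxon."""
    node, tips = _taxon_mrca(ttree, taxon)
    clade_tips = {leaf.taxon.label for leaf in node.leaf_iter()}
    return clade_tips == tips


def _parse_support(label: Optional[str]) -> Optional[float]:
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def discover_candidates(ttree: TaxonTree, min_support: Optional[float] = None) -> CandidateReport:
    """Per-taxon monophyly report with optional support filtering.

    Node labels are read as clade support; values are auto-detected as
    proportions (0-1) or percentages (0-100, when any value exceeds 1)
    and reported as proportions.  Single-tip taxa are trivially
    monophyletic and flagged as such.
    """
    raw: dict[str, tuple[bool, Optional[float], int]] = {}
    for taxon in ttree.taxa:
        node, tips = _taxon_mrca(ttree, taxon)
        clade_tips = {leaf.taxon.label for leaf in node.leaf_iter()}
        mono = clade_tips == tips
        support = _parse_support(getattr(node, "label", None)) if mono else None
        raw[taxon] = (mono, support, len(tips))
    values = [s for _, s, _ in raw.values() if s is not None]
    scale = 100.0 if any(s > 1.0 for s in values) else 1.0
    entries = {
        t: CandidateEntry(
            taxon=t,
            monophyletic=mono,
            support=(s / scale if s is not None else None),
            tip_count=k,
            single_tip=k == 1,
        )
        for t, (mono, s, k) in raw.items()
    }
    return CandidateReport(entries=entries, min_support=min_support)
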