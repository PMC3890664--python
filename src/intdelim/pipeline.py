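"""Evidence assembly and the delimitation decision rule.

For every unordered pair of taxa the pipeline collects up to three
corroborating lines of evidence — (1) at least one fixed discrete
character difference, (2) at least one gap between continuous-character
tolerance intervals, (3) rejection of niche identity — plus monophyly
flags from the gene tree.  The verdict is *delimited* when monophyly
holds for both taxa (or is not assessed / not required) and the number
of corroborating lines reaches a configurable minimum; *insufficient*
when no line could be assessed at all.

Discrete fixation is judged on the observed samples; the binomial caveat
bound is reported alongside but never vetoes a verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import pandas as pd

from .datatypes import (
    CharacterMatrix,
    ClimateStack,
    ContinuousSummary,
    OccurrenceSet,
    TaxonTree,
    ToleranceConfig,
    ValidationError,
)
from .niche import identity_test, range_map, ranges_disjoint, ClimateEnvelope, extract_climate
from .tolerance import detect_gap, diagnose_discrete, normal_ti
from .tree import discover_candidates

__all__ = ["DecisionConfig", "EvidenceRow", "EvidenceTable", "build_evidence", "decide", "render_report"]

VERDICTS = ("delimited", "not-delimited", "insufficient")


@dataclass(frozen=True)
class DecisionConfig:
    require_monophyly: bool = True
    min_corroborating_lines: int = 1
    alpha_identity: float = 0.05
    report_caveats: bool = True
    min_support: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_corroborating_lines <= 3:
            raise ValidationError("min_corroborating_lines must be in 1..3")
        if not 0 < self.alpha_identity < 1:
            raise ValidationError("alpha_identity must be in (0,1)")


@dataclass
class FixedDifference:
    character: str
    state_a: float
    state_b: float
    alt_state_bound_a: float
    alt_state_bound_b: float


@dataclass
class ContinuousGap:
    character: str
    interval_a: tuple
    interval_b: tuple


@dataclass
class NicheEvidence:
    D: float
    p_identity: float
    ranges_disjoint: bool


@dataclass
class EvidenceRow:
    taxon_a: str
    taxon_b: str
    monophyly_a: Optional[bool] = None  # None = not assessed
    monophyly_b: Optional[bool] = None
    discrete_assessed: bool = False
    fixed_discrete: list = field(default_factory=list)
    gaps_assessed: bool = False
    continuous_gaps: list = field(default_factory=list)
    niche: Optional[NicheEvidence] = None
    verdict: str = "insufficient"


@dataclass
class EvidenceTable:
    rows: list
    decision: DecisionConfig
    seed: int = 0

    def row(self, taxon_a: str, taxon_b: str) -> EvidenceRow:
        key = frozenset((taxon_a, taxon_b))
        for r in self.rows:
            if frozenset((r.taxon_a, r.taxon_b)) == key:
                return r
        raise KeyError(f"no evidence row for pair ({taxon_a}, {taxon_b})")

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "taxon_a": r.taxon_a,
                    "taxon_b": r.taxon_b,
                    "monophyly_a": _fmt_flag(r.monophyly_a),
                    "monophyly_b": _fmt_flag(r.monophyly_b),
                    "fixed_differences": ";".join(f.character for f in r.fixed_discrete)
                    if r.discrete_assessed
                    else "not-assessed",
                    "continuous_gaps": ";".join(g.character for g in r.continuous_gaps)
                    if r.gaps_assessed
                    else "not-assessed",
                    "D": f"{r.niche.D:.4f}" if r.niche else "not-assessed",
                    "p_identity": f"{r.niche.p_identity:.4f}" if r.niche else "not-assessed",
                    "ranges_disjoint": _fmt_flag(r.niche.ranges_disjoint if r.niche else None),
                    "verdict": r.verdict,
                }
            )
        return pd.DataFrame(recs)


def _fmt_flag(v: Optional[bool]) -> str:
    return "not-assessed" if v is None else ("yes" if v else "no")


def decide(row: EvidenceRow, config: DecisionConfig) -> str:
    """Apply the candidate-plus-corroboration rule to one evidence row."""
    lines_assessed = [row.discrete_assessed, row.gaps_assessed, row.niche is not None]
    if not any(lines_assessed):
        return "insufficient"
    corroborating = 0
    if row.discrete_assessed and len(row.fixed_discrete) > 0:
        corroborating += 1
    if row.gaps_assessed and len(row.continuous_gaps) > 0:
        corroborating += 1
    if row.niche is not None and row.niche.p_identity <= config.alpha_identity:
        corroborating += 1
    if config.require_monophyly:
        for flag in (row.monophyly_a, row.monophyly_b):
            if flag is False:
                return "not-delimited"
    if corroborating >= config.min_corroborating_lines:
        return "delimited"
    return "not-delimited"


def build_evidence(
    matrix: Optional[CharacterMatrix] = None,
    summaries: Optional[list] = None,
    tolerance: Optional[ToleranceConfig] = None,
    occurrences: Optional[list] = None,
    stack: Optional[ClimateStack] = None,
    taxon_tree: Optional[TaxonTree] = None,
    decision: Optional[DecisionConfig] = None,
    seed: int = 0,
    identity_reps: int = 100,
    envelope_q: tuple = (0.05, 0.95),
) -> EvidenceTable:
    """Assemble all supplied lines of evidence into an EvidenceTable.

    Any evidence source may be absent; the corresponding fields are
    marked not-assessed.  Taxa are the union of taxa over sources; pairs
    are all unordered pairs of those taxa.  Deterministic given
    (inputs, seed).
    """
    decision = decision or DecisionConfig()
    tolerance = tolerance or ToleranceConfig()
    sources = [matrix is not None, summaries, occurrences and stack is not None, taxon_tree]
    if not any(bool(s) for s in sources):
        raise ValidationError("no evidence source supplied")

    taxa: set[str] = set()
    if matrix is not None:
        taxa |= set(matrix.taxa)
    if summaries:
        taxa |= {s.taxon for s in summaries}
    if occurrences and stack is not None:
        taxa |= {o.taxon for o in occurrences}
    if taxon_tree is not None:
        taxa |= set(taxon_tree.taxa)
    if len(taxa) < 2:
        raise ValidationError("need at least two taxa across evidence sources")

    mono: dict[str, Optional[bool]] = {t: None for t in taxa}
    if taxon_tree is not None:
        report = discover_candidates(taxon_tree, decision.min_support)
        for t, entry in report.entries.items():
            mono[t] = entry.is_candidate(decision.min_support)

    tis: dict[str, dict[str, object]] = {}
    if summaries:
        for s in summaries:
            tis.setdefault(s.taxon, {})[s.character] = normal_ti(s, tolerance)

    occ_by_taxon = {o.taxon: o for o in occurrences} if occurrences else {}
    niche_cache: dict[str, object] = {}
    if occ_by_taxon and stack is not None:
        for t, occ in occ_by_taxon.items():
            model = ClimateEnvelope(q_lower=envelope_q[0], q_upper=envelope_q[1]).fit(
                extract_climate(occ, stack)
            )
            niche_cache[t] = (model, range_map(model, stack, occ))

    rows = []
    pair_seed = {}
    for i, (a, b) in enumerate(combinations(sorted(taxa), 2)):
        pair_seed[(a, b)] = (seed * 10007 + i) % (2**31)
    for (a, b), s in pair_seed.items():
        row = EvidenceRow(taxon_a=a, taxon_b=b, monophyly_a=mono[a], monophyly_b=mono[b])
        if matrix is not None and a in matrix.taxa and b in matrix.taxa:
            for ch in matrix.characters:
                diag = diagnose_discrete(matrix, a, b, ch, tolerance)
                if diag.fixed_difference is None:
                    continue
                row.discrete_assessed = True
                if diag.fixed_difference:
                    row.fixed_discrete.append(
                        FixedDifference(
                            character=ch,
                            state_a=sorted(diag.state_sets[a])[0],
                            state_b=sorted(diag.state_sets[b])[0],
                            alt_state_bound_a=diag.caveat_bounds[a],
                            alt_state_bound_b=diag.caveat_bounds[b],
                        )
                    )
        if a in tis and b in tis:
            row.gaps_assessed = True
            for ch in sorted(set(tis[a]) & set(tis[b])):
                ta, tb = tis[a][ch], tis[b][ch]
                if detect_gap(ta, tb):
                    row.continuous_gaps.append(
                        ContinuousGap(ch, (ta.lower, ta.upper), (tb.lower, tb.upper))
                    )
        if a in niche_cache and b in niche_cache:
            result = identity_test(
                occ_by_taxon[a], occ_by_taxon[b], stack,
                reps=identity_reps, seed=s, q=envelope_q,
            )
            row.niche = NicheEvidence(
                D=result.D_obs,
                p_identity=result.p_value,
                ranges_disjoint=ranges_disjoint(niche_cache[a][1], niche_cache[b][1]),
            )
        row.verdict = decide(row, decision)
        rows.append(row)
    return EvidenceTable(rows=rows, decision=decision, seed=seed)


def render_report(table: EvidenceTable, fmt: str = "tsv") -> str:
    """Render the evidence table as TSV or a markdown summary."""
    df = table.to_frame()
    if fmt == "tsv":
        return df.to_csv(sep="\t", index=False)
    if fmt != "markdown":
        raise ValidationError(f"unknown report format {fmt!r}")
    lines = ["# Delimitation evidence", ""]
    for r in table.rows:
        lines.append(f"## {r.taxon_a} vs {r.taxon_b}: **{r.verdict}**")
        lines.append(f"- monophyly: {r.taxon_a} {_fmt_flag(r.monophyly_a)}, "
                     f"{r.taxon_b} {_fmt_flag(r.monophyly_b)}")
        if r.discrete_assessed:
            if r.fixed_discrete:
                for f in r.fixed_discrete:
                    caveat = ""
                    if table.decision.report_caveats:
                        caveat = (f" (alternative state possible in up to "
                                  f"{100 * f.alt_state_bound_a:.0f}% / "
                                  f"{100 * f.alt_state_bound_b:.0f}% of future samples)")
                    lines.append(f"- fixed difference: {f.character}{caveat}")
            else:
                lines.append("- fixed differences: none")
        else:
            lines.append("- discrete characters: not assessed")
        if r.gaps_assessed:
            if r.continuous_gaps:
                for g in r.continuous_gaps:
                    lines.append(
                        f"- gap in {g.character}: "
                        f"({g.interval_a[0]:.1f}, {g.interval_a[1]:.1f}) vs "
                        f"({g.interval_b[0]:.1f}, {g.interval_b[1]:.1f})"
                    )
            else:
                lines.append("- continuous gaps: none")
        else:
            lines.append("- continuous characters: not assessed")
        if r.niche is not None:
            lines.append(
                f"- niche: D = {r.niche.D:.4f}, identity-test p = {r.niche.p_identity:.4f}, "
                f"ranges {'disjoint' if r.niche.ranges_disjoint else 'overlapping'}"
            )
        else:
            lines.append("- niche: not assessed")
        lines.append("")
    return "\n".join(lines)
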