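"""Panel-level statistics ("stat"), cross-annotation comparison, and the
orchestrating "all" pipeline.

An "affected gene" is a target gene with at least one off-target call
surviving the active filters (protein-coding-only and/or read-through
exclusion). Cross-annotation joins use uppercased gene names since gene ids
differ across annotation sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .aligner import AlignerConfig, build_index, find_hits
from .annotation import AnnotationSet, BIOTYPES
from .orient import FlipReport, flip_panel
from .panel_io import ProbePanel, SynonymTable
from .tracker import (
    BindingCall,
    GeneSummary,
    call_bindings,
    filter_protein_coding,
    summarize_panel,
)

__all__ = [
    "PanelStats",
    "CrossAnnotationReport",
    "AllResult",
    "affected_gene_names",
    "panel_stats",
    "compare_annotations",
    "run_all",
]


@dataclass
class PanelStats:
    source: str
    n_probes_total: int
    n_probes_offtarget: int
    n_genes_affected: int
    n_offtarget_genes_matched: int
    biotype_breakdown: Dict[str, int] = field(default_factory=dict)


@dataclass
class CrossAnnotationReport:
    affected: Dict[str, Set[str]]  # source -> affected target gene names
    affected_pc: Dict[str, Set[str]]  # protein-coding-only view
    union: Set[str]
    intersection: Set[str]
    union_pc: Set[str]
    intersection_pc: Set[str]
    presence: pd.DataFrame  # genes x sources boolean matrix (full view)


@dataclass
class AllResult:
    """Outputs of the flip -> track -> stat pipeline per annotation source."""

    panel: ProbePanel  # oriented panel (from the first source)
    flip_reports: Dict[str, FlipReport] = field(default_factory=dict)
    calls: Dict[str, List[BindingCall]] = field(default_factory=dict)
    summaries: Dict[str, List[GeneSummary]] = field(default_factory=dict)
    stats: Dict[str, PanelStats] = field(default_factory=dict)
    comparison: Optional[CrossAnnotationReport] = None


def _target_key(summary: GeneSummary) -> str:
    name = summary.target_gene_name or summary.target_gene_id
    return name.upper()


def affected_gene_names(
    summaries: Iterable[GeneSummary],
    protein_coding_only: bool = False,
    exclude_readthrough: bool = False,
) -> Set[str]:
    """Target gene names (uppercased) with >= 1 surviving off-target entry."""
    if protein_coding_only:
        summaries = filter_protein_coding(list(summaries))
    out = set()
    for s in summaries:
        if s.offtargets_surviving(exclude_readthrough=exclude_readthrough):
            out.add(_target_key(s))
    return out


def panel_stats(
    summaries: Iterable[GeneSummary],
    panel: ProbePanel,
    source: str,
    calls: Optional[Iterable[BindingCall]] = None,
    exclude_readthrough: bool = False,
) -> PanelStats:
    """Compile summary statistics for one annotation source.

    A probe is off-target if it has >= 1 off-target call; the biotype
    breakdown counts distinct off-target genes per canonical biotype.
    """
    summaries = list(summaries)
    offtarget_genes: Dict[Tuple[str, str], str] = {}
    offtarget_probes: Set[str] = set()
    for s in summaries:
        for p in s.offtargets_surviving(exclude_readthrough=exclude_readthrough):
            offtarget_genes[(p.gene_id, p.gene_name)] = p.biotype
    if calls is not None:
        for c in calls:
            if not c.on_target:
                if exclude_readthrough and (
                    (c.bound_gene_id, c.bound_gene_name) not in offtarget_genes
                ):
                    continue
                offtarget_probes.add(c.accession)
    else:
        # without probe-level calls, fall back to summing summary counts
        for s in summaries:
            for p in s.offtargets_surviving(exclude_readthrough=exclude_readthrough):
                offtarget_probes.add(f"{s.target_gene_id}::{p.gene_id}")
    breakdown = {b: 0 for b in BIOTYPES}
    for biotype in offtarget_genes.values():
        breakdown[biotype] = breakdown.get(biotype, 0) + 1
    breakdown = {b: n for b, n in breakdown.items() if n}
    return PanelStats(
        source=source,
        n_probes_total=len(panel),
        n_probes_offtarget=len(offtarget_probes),
        n_genes_affected=len(
            affected_gene_names(summaries, exclude_readthrough=exclude_readthrough)
        ),
        n_offtarget_genes_matched=len(offtarget_genes),
        biotype_breakdown=breakdown,
    )


def compare_annotations(
    runs: Sequence[Tuple[str, Iterable[GeneSummary]]],
    exclude_readthrough: bool = False,
) -> CrossAnnotationReport:
    """Reconcile affected-gene sets across >= 2 annotation sources."""
    labels = [label for label, _ in runs]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate annotation source labels")
    if len(runs) < 2:
        raise ValueError("compare_annotations requires >= 2 sources")
    affected: Dict[str, Set[str]] = {}
    affected_pc: Dict[str, Set[str]] = {}
    for label, summaries in runs:
        summaries = list(summaries)
        affected[label] = affected_gene_names(
            summaries, exclude_readthrough=exclude_readthrough
        )
        affected_pc[label] = affected_gene_names(
            summaries,
            protein_coding_only=True,
            exclude_readthrough=exclude_readthrough,
        )
    union = set().union(*affected.values())
    intersection = set.intersection(*affected.values()) if affected else set()
    union_pc = set().union(*affected_pc.values())
    intersection_pc = set.intersection(*affected_pc.values()) if affected_pc else set()
    genes = sorted(union)
    presence = pd.DataFrame(
        {label: [g in affected[label] for g in genes] for label in labels},
        index=genes,
    )
    return CrossAnnotationReport(
        affected=affected,
        affected_pc=affected_pc,
        union=union,
        intersection=intersection,
        union_pc=union_pc,
        intersection_pc=intersection_pc,
        presence=presence,
    )


def run_all(
    panel: ProbePanel,
    annotations: Sequence[AnnotationSet],
    config: Optional[AlignerConfig] = None,
    synonyms: Optional[SynonymTable] = None,
    exclude_readthrough: bool = False,
) -> AllResult:
    """Run flip -> align -> track -> stat against each annotation source, then
    reconcile across sources when more than one is given.

    Each source gets its own flip (orientation is decided against that
    source's transcripts). The returned panel is the oriented panel from the
    first source.
    """
    if not annotations:
        raise ValueError("run_all requires >= 1 annotation")
    config = config or AlignerConfig()
    result = AllResult(panel=panel)
    for ann in annotations:
        if not ann.source:
            raise ValueError("annotation sources must be labelled")
        oriented, flip_report = flip_panel(panel, ann, synonyms)
        core_lens = {p.length - 2 * config.pl for p in oriented}
        if min(core_lens) <= 0:
            raise ValueError("pad length too large for panel probes")
        w = config.word_length(min(core_lens))
        index = build_index(ann, w)
        hits = []
        for probe in oriented:
            hits.extend(find_hits(probe, index, config))
        calls = call_bindings(hits, ann, synonyms, oriented)
        summaries = summarize_panel(calls, oriented, synonyms)
        stats = panel_stats(
            summaries,
            oriented,
            ann.source,
            calls=calls,
            exclude_readthrough=exclude_readthrough,
        )
        if not result.flip_reports:
            result.panel = oriented
        result.flip_reports[ann.source] = flip_report
        result.calls[ann.source] = calls
        result.summaries[ann.source] = summaries
        result.stats[ann.source] = stats
    if len(annotations) > 1:
        result.comparison = compare_annotations(
            [(ann.source, result.summaries[ann.source]) for ann in annotations],
            exclude_readthrough=exclude_readthrough,
        )
    return result
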