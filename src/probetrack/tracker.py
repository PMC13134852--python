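"""Lift alignment hits to gene-level binding predictions ("track").

Hits are collapsed probe -> gene (each probe counted once per bound gene
regardless of how many isoforms it hits), classified on/off-target with
synonym resolution, annotated with canonical biotypes, and shaped into
per-target-gene summaries with read-through flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .aligner import AlignmentHit
from .annotation import AnnotationSet, AnnotationError
from .panel_io import ProbePanel, SynonymTable

__all__ = [
    "BindingCall",
    "PredictedGene",
    "GeneSummary",
    "call_bindings",
    "is_on_target",
    "summarize_gene",
    "summarize_panel",
    "flag_readthrough",
    "filter_protein_coding",
]


@dataclass(frozen=True)
class BindingCall:
    """One probe predicted to bind one gene."""

    accession: str
    target_gene_id: str
    target_gene_name: str
    bound_gene_id: str
    bound_gene_name: str
    biotype: str
    on_target: bool
    n_transcripts_hit: int
    mode: str
    pl: int


@dataclass(frozen=True)
class PredictedGene:
    gene_id: str
    gene_name: str
    n_probes_aligned: int
    biotype: str
    on_target: bool
    readthrough: bool


@dataclass
class GeneSummary:
    """Per-target-gene report: target, probe count, predicted binding genes."""

    target_gene_id: str
    target_gene_name: str
    n_probes: int
    predicted: List[PredictedGene] = field(default_factory=list)

    @property
    def offtargets(self) -> List[PredictedGene]:
        return [p for p in self.predicted if not p.on_target]

    def offtargets_surviving(self, exclude_readthrough: bool = False) -> List[PredictedGene]:
        return [
            p
            for p in self.offtargets
            if not (exclude_readthrough and p.readthrough)
        ]


def is_on_target(
    target_id: str,
    target_name: str,
    bound_id: str,
    bound_name: str,
    synonyms: Optional[SynonymTable] = None,
) -> bool:
    """True iff the bound gene IS the target: equal ids, equal names, or the
    bound name is a synonym of any declared target symbol (';'-separated
    multi-symbol targets accept any of their symbols)."""
    if target_id and target_id == bound_id:
        return True
    names = [s.strip() for s in target_name.split(";") if s.strip()]
    for name in names:
        if name == bound_name:
            return True
        if synonyms is not None and synonyms.are_synonyms(name, bound_name):
            return True
    return False


def flag_readthrough(
    bound_name: str, target_name: str, synonyms: Optional[SynonymTable] = None
) -> bool:
    """True iff the bound symbol looks like a read-through gene containing the
    target: it splits on '-' into >= 2 symbols, one of which equals the target
    (or a synonym). A flag only — read-throughs are never dropped silently."""
    parts = bound_name.split("-")
    if len(parts) < 2:
        return False
    targets = {s.strip() for s in target_name.split(";") if s.strip()}
    if synonyms is not None:
        for t in list(targets):
            targets |= synonyms.synonyms(t)
    return any(part in targets for part in parts)


def call_bindings(
    hits: Iterable[AlignmentHit],
    annotation: AnnotationSet,
    synonyms: Optional[SynonymTable],
    panel: ProbePanel,
) -> List[BindingCall]:
    """Group hits by (probe, bound gene) into one BindingCall each."""
    probes = {p.accession: p for p in panel}
    grouped: Dict[Tuple[str, str], List[AlignmentHit]] = {}
    mode_pl: Tuple[str, int] = ("strict", 0)
    for hit in hits:
        t = annotation.transcripts.get(hit.transcript_id)
        if t is None:
            raise AnnotationError(
                f"hit references unknown transcript {hit.transcript_id!r}"
            )
        grouped.setdefault((hit.accession, t.gene_id), []).append(hit)
        mode_pl = (hit.mode, hit.pl)
    calls: List[BindingCall] = []
    for (accession, gene_id), group in sorted(grouped.items()):
        probe = probes.get(accession)
        if probe is None:
            raise KeyError(f"hit for unknown probe accession {accession!r}")
        info = annotation.gene_index[gene_id]
        calls.append(
            BindingCall(
                accession=accession,
                target_gene_id=probe.gene_id,
                target_gene_name=probe.gene_name,
                bound_gene_id=gene_id,
                bound_gene_name=info.gene_name,
                biotype=info.biotype,
                on_target=is_on_target(
                    probe.gene_id, probe.gene_name, gene_id, info.gene_name, synonyms
                ),
                n_transcripts_hit=len({h.transcript_id for h in group}),
                mode=mode_pl[0],
                pl=mode_pl[1],
            )
        )
    return calls


def summarize_gene(
    calls: Iterable[BindingCall],
    panel: ProbePanel,
    synonyms: Optional[SynonymTable] = None,
) -> GeneSummary:
    """Summarise all calls for ONE target gene into a report row.

    Predicted genes are ordered by descending probe count, then name. Each
    probe counts once per bound gene.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("summarize_gene requires at least one call")
    targets = {(c.target_gene_id, c.target_gene_name) for c in calls}
    if len(targets) != 1:
        raise ValueError(f"calls span multiple target genes: {sorted(targets)}")
    target_id, target_name = calls[0].target_gene_id, calls[0].target_gene_name
    n_probes = sum(
        1 for p in panel if (p.gene_id, p.gene_name) == (target_id, target_name)
    )
    per_gene: Dict[Tuple[str, str], List[BindingCall]] = {}
    for c in calls:
        per_gene.setdefault((c.bound_gene_id, c.bound_gene_name), []).append(c)
    predicted = []
    for (gid, gname), group in per_gene.items():
        n_aligned = len({c.accession for c in group})
        predicted.append(
            PredictedGene(
                gene_id=gid,
                gene_name=gname,
                n_probes_aligned=n_aligned,
                biotype=group[0].biotype,
                on_target=group[0].on_target,
                readthrough=flag_readthrough(gname, target_name, synonyms),
            )
        )
    predicted.sort(key=lambda p: (-p.n_probes_aligned, p.gene_name, p.gene_id))
    return GeneSummary(
        target_gene_id=target_id,
        target_gene_name=target_name,
        n_probes=n_probes,
        predicted=predicted,
    )


def summarize_panel(
    calls: Iterable[BindingCall],
    panel: ProbePanel,
    synonyms: Optional[SynonymTable] = None,
) -> List[GeneSummary]:
    """One GeneSummary per target gene that has >= 1 call, in panel order."""
    by_target: Dict[Tuple[str, str], List[BindingCall]] = {}
    for c in calls:
        by_target.setdefault((c.target_gene_id, c.target_gene_name), []).append(c)
    summaries = []
    for key in panel.target_genes():
        if key in by_target:
            summaries.append(summarize_gene(by_target[key], panel, synonyms))
    return summaries


def filter_protein_coding(items):
    """Restrict off-target entries to protein-coding bound genes.

    Accepts a list of BindingCall or of GeneSummary and returns the same
    type. On-target entries are kept regardless of biotype; off-target
    entries with any other biotype are dropped. Target genes left with no
    off-target entry drop out of the affected-gene set downstream but remain
    in the list.
    """
    items = list(items)
    if items and isinstance(items[0], BindingCall):
        return [c for c in items if c.on_target or c.biotype == "protein_coding"]
    out = []
    for s in items:
        kept = [p for p in s.predicted if p.on_target or p.biotype == "protein_coding"]
        out.append(
            GeneSummary(
                target_gene_id=s.target_gene_id,
                target_gene_name=s.target_gene_name,
                n_probes=s.n_probes,
                predicted=kept,
            )
        )
    return out
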