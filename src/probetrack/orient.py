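"""Probe orientation correction ("flip").

Probe target sequences are expected to align to the forward strand of their
target gene's transcripts before off-target tracking. Panels are frequently
delivered antisense: each probe is checked for an exact occurrence of its
sequence — and of its reverse complement — in the transcripts of its own
declared target gene, and reverse-complemented when only the antisense
orientation matches. Orientation is decided against the probe's own target
gene only; hits elsewhere in the transcriptome never drive a flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Dict, List, Optional, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import AnnotationSet
    from .panel_io import ProbePanel, SynonymTable

__all__ = [
    "reverse_complement",
    "flip_panel",
    "FlipReport",
    "ProbeDisposition",
    "KEPT",
    "FLIPPED",
    "UNMATCHED",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

KEPT = "kept"
FLIPPED = "flipped"
UNMATCHED = "unmatched"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ProbeDisposition:
    accession: str
    disposition: str  # kept | flipped | unmatched
    reason: str = ""  # e.g. "gene_absent", "no_occurrence", "both_orientations"


@dataclass
class FlipReport:
    n_total: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_unmatched: int = 0
    dispositions: Dict[str, ProbeDisposition] = field(default_factory=dict)

    def record(self, disp: ProbeDisposition) -> None:
        self.dispositions[disp.accession] = disp
        self.n_total += 1
        if disp.disposition == KEPT:
            self.n_kept += 1
        elif disp.disposition == FLIPPED:
            self.n_flipped += 1
        else:
            self.n_unmatched += 1


def _target_transcript_seqs(
    probe, annotation: "AnnotationSet", synonyms: Optional["SynonymTable"]
) -> List[str]:
    """Sequences of all transcripts belonging to the probe's declared target."""
    accepted_names = set(probe.target_names())
    if synonyms is not None:
        for name in probe.target_names():
            accepted_names |= synonyms.synonyms(name)
    seqs: List[str] = []
    for t in annotation.transcripts.values():
        if t.sequence is None:
            continue
        if t.gene_id == probe.gene_id or t.gene_name in accepted_names:
            seqs.append(t.sequence)
    return seqs


def flip_panel(
    panel: "ProbePanel",
    annotation: "AnnotationSet",
    synonyms: Optional["SynonymTable"] = None,
) -> Tuple["ProbePanel", FlipReport]:
    """Orient every probe to the forward strand of its target gene's transcripts.

    For each probe the target gene's transcript sequences are searched for an
    exact occurrence of the probe sequence and of its reverse complement:

    * forward occurs (alone or in both orientations) -> kept;
    * only the reverse complement occurs -> sequence replaced by its reverse
      complement, ``flipped=True``;
    * neither occurs -> unmatched, sequence unchanged (reason ``gene_absent``
      when the annotation has no transcript for the target at all).

    Returns a new panel; the input is not mutated. Idempotent: flipping a
    flipped panel changes nothing.
    """
    from .panel_io import ProbePanel  # deferred to avoid import cycle

    report = FlipReport()
    new_probes = []
    for probe in panel:
        seqs = _target_transcript_seqs(probe, annotation, synonyms)
        if not seqs:
            report.record(
                ProbeDisposition(probe.accession, UNMATCHED, reason="gene_absent")
            )
            new_probes.append(replace(probe))
            continue
        fwd = probe.sequence
        rev = reverse_complement(fwd)
        fwd_hit = any(fwd in s for s in seqs)
        rev_hit = any(rev in s for s in seqs)
        if fwd_hit and rev_hit:
            disp = ProbeDisposition(probe.accession, KEPT, reason="both_orientations")
            new_probes.append(replace(probe))
        elif fwd_hit:
            disp = ProbeDisposition(probe.accession, KEPT)
            new_probes.append(replace(probe))
        elif rev_hit:
            disp = ProbeDisposition(probe.accession, FLIPPED)
            new_probes.append(replace(probe, sequence=rev, flipped=True))
        else:
            disp = ProbeDisposition(probe.accession, UNMATCHED, reason="no_occurrence")
            new_probes.append(replace(probe))
        report.record(disp)
    return ProbePanel(probes=new_probes, name=panel.name), report
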