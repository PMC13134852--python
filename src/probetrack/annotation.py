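"""Annotation ingest: GFF3/GTF parsing, transcript extraction, source rules.

GENCODE-, RefSeq- and CHESS-style annotations differ in feature types,
attribute keys and biotype vocabularies. This module flattens any of them
into a uniform :class:`AnnotationSet` of spliced transcripts with canonical
biotypes, applying per-source normalisation rules (VDJ-segment renaming,
pseudogene-transcript removal, alternative-scaffold filtering).

Internal coordinates are 0-based half-open; the GFF/GTF 1-based closed
convention is converted at the parser boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import gffutils

from .orient import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptRecord",
    "GeneInfo",
    "AnnotationSet",
    "SourceRules",
    "AnnotationError",
    "BIOTYPES",
    "parse_annotation",
    "apply_source_rules",
    "extract_transcript_sequences",
    "normalize_biotype",
    "read_transcript_fasta",
    "is_alt_scaffold",
    "REFSEQ_RULES",
    "DEFAULT_RULES",
]

#: Canonical biotype vocabulary.
BIOTYPES = ("protein_coding", "pseudogene", "lncRNA", "NMD", "miRNA", "other")

# Feature types treated as transcript-level containers of exons.
_TRANSCRIPT_TYPES = {
    "transcript",
    "mRNA",
    "lnc_RNA",
    "lncRNA",
    "ncRNA",
    "miRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "rRNA",
    "tRNA",
    "primary_transcript",
    "antisense_RNA",
    "pseudogenic_transcript",
    "unconfirmed_transcript",
}

#: RefSeq VD(J) segment feature types renamed to transcripts by the refseq rules.
VDJ_SEGMENT_TYPES = {
    "V_gene_segment",
    "D_gene_segment",
    "J_gene_segment",
    "C_gene_segment",
}

_GENE_TYPES = {"gene", "pseudogene", "ncRNA_gene"}

_ALT_SCAFFOLD_RE = re.compile(r"(_alt$|_random$|_fix$|hap\d+|^HSCHR|^chrUn_.*_decoy$)")


class AnnotationError(ValueError):
    """Raised for structurally broken annotation inputs."""


def is_alt_scaffold(contig: str) -> bool:
    """Heuristic for GRCh38 alternative/patch scaffolds.

    Primary chromosomes and unplaced (``chrUn_``) contigs are kept; ``_alt``,
    ``_random``, ``_fix`` and haplotype scaffolds are flagged.
    """
    return bool(_ALT_SCAFFOLD_RE.search(contig))


@dataclass
class TranscriptRecord:
    """One spliced transcript with gene identity and canonical biotype."""

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    source: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    feature_type: str = "transcript"
    raw_biotype: str = ""
    sequence: Optional[str] = None

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneInfo:
    gene_id: str
    gene_name: str
    biotype: str
    transcript_ids: List[str] = field(default_factory=list)


@dataclass
class AnnotationSet:
    """A uniform view of one annotation source."""

    transcripts: Dict[str, TranscriptRecord] = field(default_factory=dict)
    gene_index: Dict[str, GeneInfo] = field(default_factory=dict)
    source: str = ""
    genome_build: str = ""
    dropped: Dict[str, int] = field(default_factory=dict)  # reason -> count

    def add(self, t: TranscriptRecord, gene_biotype: Optional[str] = None) -> None:
        self.transcripts[t.transcript_id] = t
        info = self.gene_index.get(t.gene_id)
        if info is None:
            info = GeneInfo(t.gene_id, t.gene_name, gene_biotype or t.biotype)
            self.gene_index[t.gene_id] = info
        info.transcript_ids.append(t.transcript_id)

    def gene_of(self, transcript_id: str) -> GeneInfo:
        t = self.transcripts.get(transcript_id)
        if t is None:
            raise AnnotationError(f"unknown transcript {transcript_id!r}")
        return self.gene_index[t.gene_id]

    def count_dropped(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    def rebuild_gene_index(self) -> None:
        """Recompute the gene index from the current transcript set."""
        old = self.gene_index
        self.gene_index = {}
        for t in self.transcripts.values():
            info = self.gene_index.get(t.gene_id)
            if info is None:
                prev = old.get(t.gene_id)
                biotype = prev.biotype if prev is not None else t.biotype
                info = GeneInfo(t.gene_id, t.gene_name, biotype)
                self.gene_index[t.gene_id] = info
            info.transcript_ids.append(t.transcript_id)


@dataclass(frozen=True)
class SourceRules:
    """Per-source normalisation switches applied after parsing."""

    vdj_rename: bool = False
    drop_pseudogene_transcripts: bool = False
    drop_alt_scaffolds: bool = True
    contig_allowlist: Optional[frozenset] = None


DEFAULT_RULES = SourceRules()
REFSEQ_RULES = SourceRules(vdj_rename=True, drop_pseudogene_transcripts=True)

# -- biotype normalisation ---------------------------------------------------

_LNCRNA_RAW = {
    "lncrna",
    "lnc_rna",
    "lincrna",
    "antisense",
    "antisense_rna",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncrna",
}

_NMD_RAW = {"nonsense_mediated_decay", "nmd", "nmd_transcript_variant"}


def normalize_biotype(raw: str, source: str = "") -> str:
    """Map a source biotype label onto the canonical six-label vocabulary.

    Unknown labels map to ``other``; ``source`` is accepted for symmetry with
    source-specific vocabularies but the mapping is currently source-free.
    """
    label = (raw or "").strip().lower()
    if label in ("protein_coding", "mrna", "protein coding"):
        return "protein_coding"
    if "pseudogene" in label:
        return "pseudogene"
    if label in _LNCRNA_RAW:
        return "lncRNA"
    if label in _NMD_RAW:
        return "NMD"
    if label == "mirna":
        return "miRNA"
    return "other"


# -- GFF3 / GTF parsing ------------------------------------------------------

_BIOTYPE_KEYS_TX = ("transcript_biotype", "transcript_type", "biotype", "gbkey")
_BIOTYPE_KEYS_GENE = ("gene_biotype", "gene_type", "biotype")
_NAME_KEYS = ("gene_name", "gene", "Name")


def _attr(feature, *keys: str) -> str:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return ""


def _gene_id_of(feature, db) -> Tuple[str, str, str]:
    """Resolve (gene_id, gene_name, raw gene biotype) for a transcript feature."""
    gid = _attr(feature, "gene_id")
    gname = _attr(feature, *_NAME_KEYS)
    gbio = _attr(feature, *_BIOTYPE_KEYS_GENE)
    for parent in db.parents(feature, level=1):
        if parent.featuretype in _GENE_TYPES:
            gid = _attr(parent, "gene_id") or parent.id
            gname = _attr(parent, *_NAME_KEYS) or gname
            gbio = _attr(parent, *_BIOTYPE_KEYS_GENE) or gbio
            if parent.featuretype == "pseudogene" and not gbio:
                gbio = "pseudogene"
            break
    return gid, gname, gbio


def parse_annotation(
    path: str | Path,
    dialect: str,
    source_label: str,
    rules: Optional[SourceRules] = None,
    genome_build: str = "",
) -> AnnotationSet:
    """Parse a GFF3 or GTF annotation into an AnnotationSet (sequences unset).

    ``dialect`` is ``"gff3"`` or ``"gtf"``. Gene/transcript/exon hierarchy is
    resolved via Parent/ID (GFF3) or gene_id/transcript_id attributes (GTF).
    Transcripts without exons are skipped with a logged warning and counted in
    ``dropped``. When ``rules`` is given it is applied before returning.
    """
    if dialect not in ("gff3", "gtf"):
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    ann = AnnotationSet(source=source_label, genome_build=genome_build)
    tx_types = _TRANSCRIPT_TYPES | VDJ_SEGMENT_TYPES
    for feature in db.all_features(order_by=("seqid", "start")):
        if feature.featuretype not in tx_types:
            continue
        tid = _attr(feature, "transcript_id") or feature.id
        exons = sorted(
            ((e.start - 1, e.end) for e in db.children(feature, featuretype="exon")),
        )
        if not exons:
            if feature.featuretype in VDJ_SEGMENT_TYPES:
                # segment features often carry no exon children; the feature
                # span itself is the transcribed interval
                exons = [(feature.start - 1, feature.end)]
            else:
                logger.warning("transcript %s has no exons; skipped", tid)
                ann.count_dropped("no_exons")
                continue
        gid, gname, gene_bio = _gene_id_of(feature, db)
        raw_bio = _attr(feature, *_BIOTYPE_KEYS_TX) or gene_bio
        ann.add(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid or tid,
                gene_name=gname or gid or tid,
                biotype=normalize_biotype(raw_bio, source_label),
                source=source_label,
                contig=feature.seqid,
                strand=feature.strand or "+",
                exons=exons,
                feature_type=feature.featuretype,
                raw_biotype=raw_bio,
            ),
            gene_biotype=normalize_biotype(gene_bio or raw_bio, source_label),
        )
    if rules is not None:
        ann = apply_source_rules(ann, rules)
    return ann


def apply_source_rules(annotation: AnnotationSet, rules: SourceRules) -> AnnotationSet:
    """Apply per-source filters/renames; returns a new AnnotationSet.

    * ``vdj_rename``: VD(J) segment features become ordinary transcripts.
    * ``drop_pseudogene_transcripts``: transcripts whose raw gene biotype is
      exactly ``pseudogene`` are removed (RefSeq annotates transcripts for a
      small, erroneous subset of plain pseudogenes; ``transcribed_pseudogene``
      features are unaffected).
    * ``drop_alt_scaffolds``: transcripts on alternative/patch scaffolds are
      removed; with ``contig_allowlist`` set, anything off-list is removed.
    """
    out = AnnotationSet(
        source=annotation.source,
        genome_build=annotation.genome_build,
        dropped=dict(annotation.dropped),
    )
    for t in annotation.transcripts.values():
        if rules.contig_allowlist is not None:
            if t.contig not in rules.contig_allowlist:
                out.count_dropped("alt_scaffold")
                continue
        elif rules.drop_alt_scaffolds and is_alt_scaffold(t.contig):
            out.count_dropped("alt_scaffold")
            continue
        if rules.drop_pseudogene_transcripts:
            if (t.raw_biotype or "").lower() == "pseudogene":
                out.count_dropped("pseudogene_transcript")
                continue
        new_t = replace(t)
        if rules.vdj_rename and t.feature_type in VDJ_SEGMENT_TYPES:
            new_t.feature_type = "transcript"
        out.add(new_t, gene_biotype=annotation.gene_index[t.gene_id].biotype)
    return out


def extract_transcript_sequences(annotation: AnnotationSet, genome) -> AnnotationSet:
    """Fill in spliced transcript sequences from a genome.

    Exon substrings are concatenated in coordinate order and minus-strand
    transcripts reverse-complemented so every sequence is the mRNA sense
    strand. ``genome`` is a ``pyfaidx.Fasta`` or ``{contig: sequence}`` dict.
    Soft-masked (lowercase) genome bases are uppercased.
    """
    out = AnnotationSet(
        source=annotation.source,
        genome_build=annotation.genome_build,
        dropped=dict(annotation.dropped),
    )
    for t in annotation.transcripts.values():
        parts = []
        for start, end in sorted(t.exons):
            parts.append(_genome_slice(genome, t.contig, start, end))
        seq = "".join(parts)
        if t.strand == "-":
            seq = reverse_complement(seq)
        out.add(
            replace(t, sequence=seq),
            gene_biotype=annotation.gene_index[t.gene_id].biotype,
        )
    return out


def _genome_slice(genome, contig: str, start: int, end: int) -> str:
    if isinstance(genome, dict):
        if contig not in genome:
            raise AnnotationError(f"contig {contig!r} missing from genome")
        seq = genome[contig]
        if end > len(seq) or start < 0:
            raise AnnotationError(
                f"exon {contig}:{start}-{end} out of range (contig length {len(seq)})"
            )
        return seq[start:end].upper()
    if contig not in genome:
        raise AnnotationError(f"contig {contig!r} missing from genome")
    rec = genome[contig]
    if end > len(rec) or start < 0:
        raise AnnotationError(
            f"exon {contig}:{start}-{end} out of range (contig length {len(rec)})"
        )
    return str(rec[start:end]).upper()


def read_transcript_fasta(
    path: str | Path, source_label: str, header_format: str = "pipe"
) -> AnnotationSet:
    """Load a pre-extracted transcript FASTA as an AnnotationSet.

    ``header_format="pipe"`` expects ``transcript_id|gene_id|gene_name|biotype``
    headers (biotype optional, defaults to ``other``).
    """
    from Bio import SeqIO

    ann = AnnotationSet(source=source_label)
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split("|")
        tid = parts[0]
        gid = parts[1] if len(parts) > 1 else tid
        gname = parts[2] if len(parts) > 2 else gid
        raw_bio = parts[3] if len(parts) > 3 else ""
        seq = str(rec.seq).upper()
        ann.add(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname,
                biotype=normalize_biotype(raw_bio),
                source=source_label,
                contig="",
                strand="+",
                exons=[(0, len(seq))],
                raw_biotype=raw_bio,
                sequence=seq,
            )
        )
    return ann
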