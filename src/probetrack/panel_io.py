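"""Probe panel and synonym-table I/O.

Probe panels arrive either as FASTA files whose headers follow the
``gene_id|gene_name|accession`` convention, or as BED intervals that are
resolved against a genome FASTA. Synonym tables are two-column TSVs of
gene-symbol pairs; the loaded table is symmetric but deliberately NOT
transitively closed (chaining unrelated gene families through hub symbols
produces spurious on-target calls).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

from Bio import SeqIO

from .orient import reverse_complement

__all__ = [
    "ProbeRecord",
    "ProbePanel",
    "SynonymTable",
    "PanelError",
    "MalformedHeaderError",
    "parse_probe_id",
    "read_probe_fasta",
    "write_probe_fasta",
    "probes_from_bed",
    "load_synonyms",
]

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


class PanelError(ValueError):
    """Raised for malformed probe panel inputs."""


class MalformedHeaderError(PanelError):
    """Raised when a probe FASTA header cannot be split into its three fields."""


@dataclass
class ProbeRecord:
    """A single probe target sequence with its declared target gene."""

    probe_id: str
    gene_id: str
    gene_name: str
    accession: str
    sequence: str
    flipped: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise PanelError(f"probe {self.probe_id!r} has an empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise PanelError(
                f"probe {self.probe_id!r} contains non-nucleotide characters {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def target_names(self) -> Tuple[str, ...]:
        """Declared target symbols; multi-symbol targets are ';'-separated."""
        return tuple(s.strip() for s in self.gene_name.split(";") if s.strip())


@dataclass
class ProbePanel:
    """An ordered collection of probes, unique by accession."""

    probes: List[ProbeRecord] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for p in self.probes:
            if p.accession in seen:
                raise PanelError(f"duplicate probe accession {p.accession!r}")
            seen.add(p.accession)

    def __iter__(self) -> Iterator[ProbeRecord]:
        return iter(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def get(self, accession: str) -> ProbeRecord:
        for p in self.probes:
            if p.accession == accession:
                return p
        raise KeyError(accession)

    def by_gene(self) -> Dict[Tuple[str, str], List[ProbeRecord]]:
        """Group probes by (gene_id, gene_name), preserving panel order."""
        out: Dict[Tuple[str, str], List[ProbeRecord]] = {}
        for p in self.probes:
            out.setdefault((p.gene_id, p.gene_name), []).append(p)
        return out

    def target_genes(self) -> List[Tuple[str, str]]:
        return list(self.by_gene())


class SynonymTable:
    """Symmetric (non-transitive) gene-symbol equivalences.

    ``synonyms(x)`` always contains ``x`` itself. Pairs loaded from a table
    are applied symmetrically, but rows (A,B) and (B,C) do NOT make A and C
    synonyms.
    """

    def __init__(self, pairs: Iterable[Tuple[str, str]] = ()) -> None:
        self._entries: Dict[str, Set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        a, b = a.strip(), b.strip()
        if not a or not b:
            return
        self._entries.setdefault(a, set()).add(b)
        self._entries.setdefault(b, set()).add(a)

    def synonyms(self, symbol: str) -> Set[str]:
        return self._entries.get(symbol, set()) | {symbol}

    def are_synonyms(self, a: str, b: str) -> bool:
        return b in self.synonyms(a)

    def __len__(self) -> int:
        return len(self._entries)


def parse_probe_id(header: str) -> Tuple[str, str, str]:
    """Split a probe header into (gene_id, gene_name, accession).

    The split is on the first two pipe characters only; any further pipes
    remain part of the accession.
    """
    parts = header.split("|", 2)
    if len(parts) < 3:
        raise MalformedHeaderError(
            f"probe header {header!r} does not match gene_id|gene_name|accession"
        )
    return parts[0], parts[1], parts[2]


def read_probe_fasta(path: str | Path, name: Optional[str] = None) -> ProbePanel:
    """Read a probe panel from FASTA with ``gene_id|gene_name|accession`` headers."""
    path = Path(path)
    probes: List[ProbeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description if rec.description else rec.id
        gene_id, gene_name, accession = parse_probe_id(header)
        probes.append(
            ProbeRecord(
                probe_id=header,
                gene_id=gene_id,
                gene_name=gene_name,
                accession=accession,
                sequence=str(rec.seq),
            )
        )
    if not probes:
        raise PanelError(f"no probe records found in {path}")
    return ProbePanel(probes=probes, name=name or path.stem)


def write_probe_fasta(panel: ProbePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in panel:
            fh.write(f">{p.probe_id}\n{p.sequence}\n")


def _fetch(genome, contig: str, start: int, end: int) -> str:
    """Substring [start, end) of a contig from a pyfaidx.Fasta or a plain dict."""
    if isinstance(genome, dict):
        if contig not in genome:
            raise PanelError(f"contig {contig!r} not present in genome")
        seq = genome[contig]
        if end > len(seq):
            raise PanelError(
                f"interval {contig}:{start}-{end} beyond contig end ({len(seq)})"
            )
        return seq[start:end].upper()
    if contig not in genome:
        raise PanelError(f"contig {contig!r} not present in genome")
    record = genome[contig]
    if end > len(record):
        raise PanelError(
            f"interval {contig}:{start}-{end} beyond contig end ({len(record)})"
        )
    return str(record[start:end]).upper()


def probes_from_bed(
    bed_path: str | Path,
    genome,
    name_format: str = "gene_name",
    panel_name: Optional[str] = None,
) -> ProbePanel:
    """Extract probe sequences from BED intervals against a genome.

    BED is 0-based half-open; minus-strand intervals are reverse-complemented.
    ``genome`` is a ``pyfaidx.Fasta`` or a plain ``{contig: sequence}`` dict.

    ``name_format`` controls how the BED name column maps onto probe identity:
    ``"gene_name"`` (default) treats the whole name as the gene symbol;
    ``"gene_id|gene_name"`` splits on the first pipe.
    """
    bed_path = Path(bed_path)
    probes: List[ProbeRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            contig, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise PanelError(
                    f"{bed_path}:{lineno}: zero-length or inverted interval"
                )
            bed_name = fields[3] if len(fields) > 3 else f"probe{lineno}"
            strand = fields[5] if len(fields) > 5 else "+"
            seq = _fetch(genome, contig, start, end)
            if strand == "-":
                seq = reverse_complement(seq)
            if name_format == "gene_id|gene_name" and "|" in bed_name:
                gene_id, gene_name = bed_name.split("|", 1)
            else:
                gene_id = gene_name = bed_name
            accession = f"{contig}:{start}-{end}({strand})"
            probes.append(
                ProbeRecord(
                    probe_id=f"{gene_id}|{gene_name}|{accession}",
                    gene_id=gene_id,
                    gene_name=gene_name,
                    accession=accession,
                    sequence=seq,
                )
            )
    if not probes:
        raise PanelError(f"no intervals found in {bed_path}")
    return ProbePanel(probes=probes, name=panel_name or bed_path.stem)


def load_synonyms(tsv_path: str | Path) -> SynonymTable:
    """Load a two-column TSV of symbol pairs into a symmetric SynonymTable."""
    table = SynonymTable()
    with open(tsv_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            table.add(parts[0], parts[1])
    return table


def copy_panel(panel: ProbePanel) -> ProbePanel:
    return ProbePanel(probes=[replace(p) for p in panel], name=panel.name)
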