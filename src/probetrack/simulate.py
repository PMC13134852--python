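"""Synthetic fixture generation with a machine-readable truth table.

Generates a toy genome, per-source GFF3 annotations, a probe panel and
two-platform expression matrices in which every off-target scenario is
planted deliberately:

* ``perfect``       — a paralog gene sharing a probe's full sequence;
* ``core``          — a paralog sharing only the central core, with
                      substitutions planted exactly ``d`` bases from each
                      probe end (detected iff pad length >= d);
* ``pseudogene``    — a perfect copy hosted by a pseudogene;
* ``source_specific`` — a perfect-copy paralog present in only the first
                      annotation source;
* ``antisense``     — the panel stores the probe reverse-complemented, so it
                      must be flipped before tracking;
* ``retired``       — a probe whose sequence occurs in no transcript at all.

A global k-mer registry (k = the shortest core length under the maximum
supported pad) is maintained by rejection sampling, so no sequence homology
exists beyond what is planted; exact-count assertions against the truth
table are therefore valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, TranscriptRecord, normalize_biotype
from .impact import ExpressionMatrix
from .orient import reverse_complement
from .panel_io import ProbePanel, ProbeRecord

__all__ = [
    "SimulationConfig",
    "ExpressionConfig",
    "PlantedOfftarget",
    "ProbeTruth",
    "PanelTruth",
    "SyntheticData",
    "generate_panel",
    "generate_expression",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 8
    probes_per_gene: int = 4
    probe_length: int = 40
    n_sources: int = 2
    n_perfect: int = 3
    core_flank_distances: Tuple[int, ...] = (5, 10)
    n_pseudogene: int = 2
    n_source_specific: int = 1
    n_antisense: int = 4
    n_retired: int = 2
    max_pl: int = 10  # largest pad length the fixture guarantees truth for
    flank_length: int = 30
    spacer_length: int = 10
    max_rejection_tries: int = 500

    def __post_init__(self) -> None:
        n_special = (
            self.n_perfect
            + len(self.core_flank_distances)
            + self.n_pseudogene
            + self.n_source_specific
            + self.n_antisense
            + self.n_retired
        )
        if n_special > self.n_genes * self.probes_per_gene:
            raise ValueError("more planted scenarios than probes")
        if self.probe_length <= 2 * self.max_pl:
            raise ValueError("probe length must exceed twice the max pad length")
        for d in self.core_flank_distances:
            if not 1 <= d <= self.max_pl:
                raise ValueError("flank distances must lie in [1, max_pl]")

    @property
    def kmer_length(self) -> int:
        return self.probe_length - 2 * self.max_pl


@dataclass(frozen=True)
class PlantedOfftarget:
    gene_id: str
    gene_name: str
    biotype: str
    mode: str  # "perfect" | "core"
    d: Optional[int]  # flank mismatch distance, core mode only
    sources: Tuple[str, ...]  # annotation sources containing the paralog

    def detected_at(self, pl: int) -> bool:
        return self.mode == "perfect" or (self.d is not None and pl >= self.d)


@dataclass
class ProbeTruth:
    accession: str
    gene_id: str
    gene_name: str
    orientation: str = "sense"  # "sense" | "antisense"
    retired: bool = False
    planted: List[PlantedOfftarget] = field(default_factory=list)


@dataclass
class PanelTruth:
    probes: Dict[str, ProbeTruth] = field(default_factory=dict)
    gene_biotypes: Dict[str, str] = field(default_factory=dict)
    sources: List[str] = field(default_factory=list)

    def expected_offtarget_calls(self, source: str, pl: int) -> Set[Tuple[str, str]]:
        """(probe accession, off-target gene_id) pairs expected at this pl."""
        out = set()
        for truth in self.probes.values():
            for planted in truth.planted:
                if source in planted.sources and planted.detected_at(pl):
                    out.add((truth.accession, planted.gene_id))
        return out

    def expected_flipped(self) -> Set[str]:
        return {
            t.accession
            for t in self.probes.values()
            if t.orientation == "antisense" and not t.retired
        }

    def expected_unmatched(self) -> Set[str]:
        return {t.accession for t in self.probes.values() if t.retired}

    def to_json(self) -> str:
        payload = {
            "sources": self.sources,
            "gene_biotypes": self.gene_biotypes,
            "probes": {acc: asdict(t) for acc, t in self.probes.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class _Gene:
    gene_id: str
    gene_name: str
    biotype: str
    sequence: str
    sources: Tuple[str, ...]
    contig: str = "ctgA"
    start: int = 0  # genome offset, filled at layout time

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class SyntheticData:
    """In-memory fixture plus writers for on-disk standard formats."""

    config: SimulationConfig
    genome: Dict[str, str]
    genes: List[_Gene]
    panel: ProbePanel
    truth: PanelTruth

    def annotation_sets(self, with_sequences: bool = True) -> List[AnnotationSet]:
        out = []
        for source in self.truth.sources:
            ann = AnnotationSet(source=source, genome_build="synthetic")
            for g in self.genes:
                if source not in g.sources:
                    continue
                tid = f"{g.gene_id}.t1"
                ann.add(
                    TranscriptRecord(
                        transcript_id=tid,
                        gene_id=g.gene_id,
                        gene_name=g.gene_name,
                        biotype=normalize_biotype(g.biotype),
                        source=source,
                        contig=g.contig,
                        strand="+",
                        exons=[(g.start, g.end)],
                        raw_biotype=g.biotype,
                        sequence=g.sequence if with_sequences else None,
                    )
                )
            out.append(ann)
        return out

    def write_genome_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig, seq in self.genome.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gff3(self, source: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                if source not in g.sources:
                    continue
                start1, end1 = g.start + 1, g.end  # 1-based closed
                gid, tid = g.gene_id, f"{g.gene_id}.t1"
                fh.write(
                    f"{g.contig}\tprobesim\tgene\t{start1}\t{end1}\t.\t+\t.\t"
                    f"ID=gene:{gid};gene_id={gid};gene_name={g.gene_name};"
                    f"gene_type={g.biotype}\n"
                )
                fh.write(
                    f"{g.contig}\tprobesim\ttranscript\t{start1}\t{end1}\t.\t+\t.\t"
                    f"ID=tx:{tid};Parent=gene:{gid};transcript_id={tid};"
                    f"gene_id={gid};gene_name={g.gene_name};"
                    f"transcript_type={g.biotype}\n"
                )
                fh.write(
                    f"{g.contig}\tprobesim\texon\t{start1}\t{end1}\t.\t+\t.\t"
                    f"ID=exon:{tid}.1;Parent=tx:{tid}\n"
                )

    def write_all(self, outdir: str | Path) -> Dict[str, Path]:
        from .panel_io import write_probe_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": outdir / "genome.fa", "probes": outdir / "probes.fa"}
        self.write_genome_fasta(paths["genome"])
        write_probe_fasta(self.panel, paths["probes"])
        for source in self.truth.sources:
            p = outdir / f"annotation_{source}.gff3"
            self.write_gff3(source, p)
            paths[f"annotation_{source}"] = p
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(self.truth.to_json())
        return paths


class _KmerRegistry:
    """Global registry enforcing k-mer uniqueness across the transcriptome."""

    def __init__(self, k: int) -> None:
        self.k = k
        self._seen: Set[str] = set()

    def kmers(self, seq: str) -> Set[str]:
        k = self.k
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    def conflicts(self, seq: str, exempt: Set[str] = frozenset()) -> bool:
        kmers = self.kmers(seq) | self.kmers(reverse_complement(seq))
        return bool((kmers - exempt) & self._seen)

    def register(self, seq: str) -> None:
        self._seen |= self.kmers(seq) | self.kmers(reverse_complement(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _sample_unique(
    rng: np.random.Generator,
    length: int,
    registry: _KmerRegistry,
    config: SimulationConfig,
    exempt: Set[str] = frozenset(),
    template: Optional[str] = None,
) -> str:
    """Rejection-sample a sequence whose non-exempt k-mers are globally new.

    With ``template``, only the flanks around it are resampled; the template
    itself (a planted homology) is kept verbatim and its k-mers exempted.
    """
    for _ in range(config.max_rejection_tries):
        if template is None:
            seq = _random_seq(rng, length)
        else:
            left = _random_seq(rng, config.flank_length)
            right = _random_seq(rng, config.flank_length)
            seq = left + template + right
        if not registry.conflicts(seq, exempt=exempt):
            registry.register(seq)
            return seq
    raise RuntimeError(
        "could not satisfy k-mer uniqueness; simulation config infeasible"
    )


def _mutate(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    new = rng.choice([b for b in "ACGT" if b != old])
    return seq[:pos] + str(new) + seq[pos + 1 :]


def generate_panel(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> SyntheticData:
    """Build the synthetic genome, annotations, panel and truth table.

    Deterministic for a fixed (config, seed): all randomness flows from one
    seeded generator.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    registry = _KmerRegistry(config.kmer_length)
    sources = tuple(f"src{i}" for i in range(config.n_sources))
    L = config.probe_length

    genes: List[_Gene] = []
    gene_len = config.probes_per_gene * L + 2 * config.spacer_length
    for i in range(config.n_genes):
        seq = _sample_unique(rng, gene_len, registry, config)
        genes.append(
            _Gene(
                gene_id=f"SYN{i:05d}",
                gene_name=f"GENE{i:03d}",
                biotype="protein_coding",
                sequence=seq,
                sources=sources,
            )
        )

    # scenario tokens assigned to probes in panel order
    tokens: List[Tuple[str, Optional[int]]] = (
        [("perfect", None)] * config.n_perfect
        + [("core", d) for d in config.core_flank_distances]
        + [("pseudogene", None)] * config.n_pseudogene
        + [("source_specific", None)] * config.n_source_specific
        + [("antisense", None)] * config.n_antisense
        + [("retired", None)] * config.n_retired
    )
    tokens += [("plain", None)] * (
        config.n_genes * config.probes_per_gene - len(tokens)
    )

    truth = PanelTruth(sources=list(sources))
    probes: List[ProbeRecord] = []
    paralogs: List[_Gene] = []
    paralog_counter = 0
    probe_index = 0
    for gi, gene in enumerate(list(genes)):
        for pj in range(config.probes_per_gene):
            token, d = tokens[probe_index]
            probe_index += 1
            accession = f"p{gi:03d}_{pj}"
            offset = config.spacer_length + pj * L
            probe_seq = gene.sequence[offset : offset + L]
            probe_truth = ProbeTruth(
                accession=accession, gene_id=gene.gene_id, gene_name=gene.gene_name
            )
            if token == "retired":
                # a probe designed on sequence absent from every transcript
                probe_seq = _sample_unique(rng, L, registry, config)
                probe_truth.retired = True
            elif token == "antisense":
                probe_seq = reverse_complement(probe_seq)
                probe_truth.orientation = "antisense"
            elif token in ("perfect", "pseudogene", "source_specific", "core"):
                paralog_counter += 1
                biotype = "pseudogene" if token == "pseudogene" else "protein_coding"
                para_sources = (sources[0],) if token == "source_specific" else sources
                planted_seq = probe_seq
                mode = "perfect"
                if token == "core":
                    planted_seq = _mutate(probe_seq, d - 1, rng)
                    planted_seq = _mutate(planted_seq, L - d, rng)
                    mode = "core"
                exempt = registry.kmers(planted_seq) | registry.kmers(
                    reverse_complement(planted_seq)
                )
                para_seq = _sample_unique(
                    rng,
                    0,
                    registry,
                    config,
                    exempt=exempt,
                    template=planted_seq,
                )
                para = _Gene(
                    gene_id=f"PARA{paralog_counter:05d}",
                    gene_name=f"{gene.gene_name}L{paralog_counter}",
                    biotype=biotype,
                    sequence=para_seq,
                    sources=para_sources,
                )
                paralogs.append(para)
                probe_truth.planted.append(
                    PlantedOfftarget(
                        gene_id=para.gene_id,
                        gene_name=para.gene_name,
                        biotype=normalize_biotype(biotype),
                        mode=mode,
                        d=d,
                        sources=para_sources,
                    )
                )
            probes.append(
                ProbeRecord(
                    probe_id=f"{gene.gene_id}|{gene.gene_name}|{accession}",
                    gene_id=gene.gene_id,
                    gene_name=gene.gene_name,
                    accession=accession,
                    sequence=probe_seq,
                )
            )
            truth.probes[accession] = probe_truth

    genes = genes + paralogs
    for g in genes:
        truth.gene_biotypes[g.gene_id] = normalize_biotype(g.biotype)

    # lay genes end-to-end on one contig with neutral spacers
    pos = 0
    parts: List[str] = []
    spacer = "T" * config.spacer_length
    for g in genes:
        g.start = pos
        parts.append(g.sequence)
        pos += len(g.sequence)
        parts.append(spacer)
        pos += len(spacer)
    genome = {"ctgA": "".join(parts)}

    panel = ProbePanel(probes=probes, name=f"synthetic_seed{seed}")
    return SyntheticData(
        config=config, genome=genome, genes=genes, panel=panel, truth=truth
    )


# -- two-platform expression simulation --------------------------------------


@dataclass(frozen=True)
class ExpressionConfig:
    n_observations: int = 120
    n_groups: int = 4
    mean_low: float = 0.5
    mean_high: float = 40.0
    dispersion: float = 2.0  # negative-binomial size parameter
    n_silent_targets: int = 1  # targets with planted off-targets forced to zero
    background_genes: int = 5  # extra genes padding the library size


def _nb_draw(
    rng: np.random.Generator, mean: float, size: int, dispersion: float
) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_expression(
    truth: PanelTruth,
    config: Optional[ExpressionConfig] = None,
    seed: int = 0,
) -> Tuple[ExpressionMatrix, ExpressionMatrix, pd.Series]:
    """Simulate two platforms sharing latent per-gene, per-group means.

    Platform Y (sequencing-like) records every gene separately. Platform X
    (probe-based) records, for each panel target gene, the SUM of the latent
    counts of the target and all its planted off-target genes — modelling
    probe cross-hybridisation. The first ``n_silent_targets`` target genes
    that have planted off-targets get zero own-expression (so the target-only
    cross-platform comparison degenerates while the aggregated one does not).

    Returns (platform_x, platform_y, group_labels); observation ids are
    shared between platforms.
    """
    config = config or ExpressionConfig()
    rng = np.random.default_rng(seed)

    target_genes: List[str] = []
    offtargets_of: Dict[str, Set[str]] = {}
    for t in truth.probes.values():
        if t.gene_name not in target_genes:
            target_genes.append(t.gene_name)
            offtargets_of[t.gene_name] = set()
        for planted in t.planted:
            offtargets_of[t.gene_name].add(planted.gene_name)
    paralog_genes = sorted(set().union(*offtargets_of.values()) - set(target_genes))
    background = [f"BG{i:03d}" for i in range(config.background_genes)]
    all_genes = target_genes + paralog_genes + background

    silent: Set[str] = set()
    for g in target_genes:
        if offtargets_of[g] and len(silent) < config.n_silent_targets:
            silent.add(g)

    means = {
        g: np.exp(
            rng.uniform(
                np.log(config.mean_low), np.log(config.mean_high), config.n_groups
            )
        )
        for g in all_genes
    }
    for g in silent:
        means[g] = np.zeros(config.n_groups)

    labels = pd.Series(
        [f"g{i % config.n_groups}" for i in range(config.n_observations)],
        index=[f"obs{i:04d}" for i in range(config.n_observations)],
        name="group",
    )
    group_of = labels.map(lambda s: int(s[1:])).to_numpy()

    latent = {}
    for g in all_genes:
        mu = means[g][group_of]
        latent[g] = np.array(
            [
                _nb_draw(rng, m, 1, config.dispersion)[0]
                for m in mu
            ]
        )

    y_counts = pd.DataFrame(latent, index=labels.index)[all_genes]

    x_cols = {}
    for g in target_genes:
        total = latent[g].copy()
        for ot in sorted(offtargets_of[g]):
            # independent re-draw of the off-target signal captured by probes
            mu = means[ot][group_of]
            total = total + np.array(
                [_nb_draw(rng, m, 1, config.dispersion)[0] for m in mu]
            )
        x_cols[g] = total
    x_counts = pd.DataFrame(x_cols, index=labels.index)[target_genes]

    return ExpressionMatrix(x_counts), ExpressionMatrix(y_counts), labels
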