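# probetrack

Predicts off-target binding of in situ hybridization probe panels (e.g.
40-bp padlock-probe target sequences) by exact alignment against annotated
transcriptomes, reconciles predictions across annotation sources, and
quantifies the expression-level impact of predicted off-targets.

## What it does

- **panel I/O** — probe panels as FASTA (`gene_id|gene_name|accession`
  headers) or BED + genome FASTA; symmetric (non-transitive) gene-synonym
  tables as TSV.
- **annotation ingest** — GFF3/GTF parsing (GENCODE/RefSeq/CHESS-style),
  spliced transcript extraction from a genome, canonical biotype
  normalisation, per-source rules (VDJ-segment renaming, plain-pseudogene
  transcript removal, alternative-scaffold filtering).
- **flip** — detects probes stored antisense to their target gene's
  transcripts and reverse-complements them.
- **strict / pad alignment** — strict mode requires a full-length perfect
  match; pad mode (`--pl N`) exempts N bases at each probe end, requiring
  only the central core to match exactly. Implemented with a w-mer index
  plus an independent brute-force oracle used in the tests.
- **track / stat** — gene-level binding calls with synonym resolution,
  per-target-gene summaries, read-through flags, protein-coding-only
  filtering, panel statistics, and multi-annotation union/intersection
  reports.
- **impact** — CPM + log1p normalisation, target+off-target aggregation,
  RMSE vs the identity line, Pearson with an explicit nan contract,
  cluster-mean comparison with a minimum group size, and an off-target
  expression screen against a reference profile.
- **simulate** — synthetic genomes/annotations/panels/expression matrices
  with a machine-readable truth table covering every off-target scenario
  (perfect paralog, core-only homology with planted flank-mismatch
  distances, pseudogene copies, antisense probes, probes from retired
  exons, source-specific paralogs, two-platform cross-hybridisation).

## CLI

```bash
# generate a synthetic fixture set (genome, GFF3 per source, probes, truth)
probetrack simulate --out fixtures --seed 1

# full pipeline: flip -> track -> stat (-> compare with >1 annotation)
probetrack all \
    --probes fixtures/probes.fa \
    --annotation src0:gff3:fixtures/annotation_src0.gff3 \
    --annotation src1:gff3:fixtures/annotation_src1.gff3 \
    --genome fixtures/genome.fa \
    --pl 10 --out run

# individual stages
probetrack flip  --probes probes.fa --annotation lbl:gff3:ann.gff3 --genome g.fa --out flip_out
probetrack track --probes flip_out/probes_oriented.fa --annotation lbl:gff3:ann.gff3 --genome g.fa --out track_out
probetrack stat  --probes probes.fa --calls track_out/calls_lbl.tsv --out stats.tsv
probetrack compare --probes probes.fa --calls a:calls_a.tsv --calls b:calls_b.tsv --out cmp.tsv

# expression screen of predicted off-targets
probetrack impact --probes probes.fa --calls calls.tsv \
    --matrix counts.tsv --out impact.tsv
```

Annotations are given as `label:dialect:path` with dialect `gff3`, `gtf`, or
`fasta` (pre-extracted transcripts, headers
`transcript_id|gene_id|gene_name|biotype`). `--refseq-rules` enables the
RefSeq ingest rules. All outputs are deterministic TSVs.

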