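"""Deterministic TSV serialisation of reports.

Column orders are fixed and rows are stably sorted so identical inputs and
configuration always produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List

import pandas as pd

from .orient import FlipReport
from .reporter import CrossAnnotationReport, PanelStats
from .tracker import BindingCall, GeneSummary

__all__ = [
    "flip_report_frame",
    "calls_frame",
    "summaries_frame",
    "stats_frame",
    "comparison_frame",
    "write_tsv",
    "read_calls_tsv",
]

CALL_COLUMNS = [
    "accession",
    "target_gene_id",
    "target_gene_name",
    "bound_gene_id",
    "bound_gene_name",
    "biotype",
    "on_target",
    "n_transcripts_hit",
    "mode",
    "pl",
]


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def flip_report_frame(report: FlipReport) -> pd.DataFrame:
    rows = [
        {"accession": d.accession, "disposition": d.disposition, "reason": d.reason}
        for d in report.dispositions.values()
    ]
    frame = pd.DataFrame(rows, columns=["accession", "disposition", "reason"])
    return frame.sort_values("accession").reset_index(drop=True)


def calls_frame(calls: Iterable[BindingCall]) -> pd.DataFrame:
    rows = [
        {col: getattr(c, col) for col in CALL_COLUMNS}
        for c in calls
    ]
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return frame.sort_values(["accession", "bound_gene_id"]).reset_index(drop=True)


def read_calls_tsv(path: str | Path) -> List[BindingCall]:
    frame = pd.read_csv(path, sep="\t", dtype={"pl": int, "n_transcripts_hit": int})
    calls = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        d["on_target"] = bool(d["on_target"])
        calls.append(BindingCall(**d))
    return calls


def summaries_frame(summaries: Iterable[GeneSummary]) -> pd.DataFrame:
    """Report-table shape: target gene, probe count, predicted genes with
    aligned-probe counts and biotypes (comma-joined, summary order)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "target_gene": s.target_gene_name or s.target_gene_id,
                "target_gene_id": s.target_gene_id,
                "n_probes": s.n_probes,
                "predicted_genes": ", ".join(
                    p.gene_name or p.gene_id for p in s.predicted
                ),
                "n_probes_aligned": ", ".join(
                    str(p.n_probes_aligned) for p in s.predicted
                ),
                "gene_types": ", ".join(p.biotype for p in s.predicted),
                "readthrough_flags": ", ".join(
                    p.gene_name for p in s.predicted if p.readthrough
                ),
            }
        )
    columns = [
        "target_gene",
        "target_gene_id",
        "n_probes",
        "predicted_genes",
        "n_probes_aligned",
        "gene_types",
        "readthrough_flags",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame.sort_values("target_gene").reset_index(drop=True)


def stats_frame(stats: Iterable[PanelStats]) -> pd.DataFrame:
    rows = []
    for st in stats:
        row = {
            "source": st.source,
            "n_probes_total": st.n_probes_total,
            "n_probes_offtarget": st.n_probes_offtarget,
            "n_genes_affected": st.n_genes_affected,
            "n_offtarget_genes_matched": st.n_offtarget_genes_matched,
        }
        for biotype, n in sorted(st.biotype_breakdown.items()):
            row[f"offtarget_{biotype}"] = n
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def comparison_frame(report: CrossAnnotationReport) -> pd.DataFrame:
    frame = report.presence.copy()
    frame.index.name = "target_gene"
    frame["in_all"] = frame.all(axis=1)
    return frame.sort_index()
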