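"""Expression-level impact of predicted off-target binding.

Implements the concordance statistics used to substantiate off-target
predictions across platforms: CPM + pseudo-log normalisation, aggregation of
a target gene with its predicted off-targets, RMSE relative to the identity
line, Pearson correlation with an explicit missing-value (nan) contract on
zero-variance input, cluster-mean reduction with a minimum group size, and a
mean-expression screen of predicted off-targets in a reference profile.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .tracker import GeneSummary

__all__ = [
    "ExpressionMatrix",
    "read_counts_matrix",
    "ImpactConfig",
    "ConcordanceResult",
    "cpm_normalize",
    "pseudolog",
    "aggregate_with_offtargets",
    "concordance",
    "group_means",
    "offtarget_expression_screen",
    "strip_id_suffix",
]


@dataclass
class ImpactConfig:
    pseudocount: float = 1.0
    min_group_size: int = 10

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")


class ExpressionMatrix:
    """Raw counts, observations x genes, with per-observation library sizes.

    Library sizes default to row sums and are intended to cover ALL features
    of the source matrix, so CPM stays on one scale even when the matrix is
    later subset to a panel.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Optional[pd.Series] = None,
    ) -> None:
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if library_sizes is None:
            library_sizes = counts.sum(axis=1)
        self.library_sizes = library_sizes.reindex(counts.index)
        if (self.library_sizes < counts.max(axis=1)).any():
            raise ValueError("library sizes smaller than per-feature counts")

    @property
    def genes(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def observations(self) -> List[str]:
        return list(self.counts.index)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.counts.columns]
        return ExpressionMatrix(self.counts[present], self.library_sizes)


def read_counts_matrix(
    path,
    features_path=None,
    barcodes_path=None,
) -> ExpressionMatrix:
    """Load raw counts from MTX (features x barcodes, with sidecar label
    files) or a delimited matrix (observations x genes, first column = ids).
    """
    from pathlib import Path as _Path

    path = _Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if features_path is None or barcodes_path is None:
            raise ValueError("MTX input requires features and barcodes sidecars")
        features = [
            line.split("\t")[0].strip()
            for line in _Path(features_path).read_text().splitlines()
            if line.strip()
        ]
        barcodes = [
            line.strip()
            for line in _Path(barcodes_path).read_text().splitlines()
            if line.strip()
        ]
        dense = mmread(str(path)).toarray()  # features x barcodes, 10x-style
        counts = pd.DataFrame(dense.T, index=barcodes, columns=features)
        return ExpressionMatrix(counts)
    counts = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return ExpressionMatrix(counts)


def cpm_normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6 per observation.

    Observations with zero library size are dropped with a warning.
    """
    lib = matrix.library_sizes
    zero = lib[lib == 0].index
    if len(zero):
        warnings.warn(
            f"dropping {len(zero)} observation(s) with zero library size",
            stacklevel=2,
        )
    keep = lib[lib > 0].index
    counts = matrix.counts.loc[keep]
    return counts.div(lib.loc[keep], axis=0) * 1e6


def pseudolog(values, pseudocount: float = 1.0):
    """Natural log(x + pseudocount); monotone, 0 -> 0 at the default."""
    return np.log(np.asarray(values, dtype=float) + pseudocount) if not isinstance(
        values, (pd.DataFrame, pd.Series)
    ) else np.log(values + pseudocount)


def normalized_expression(
    matrix: ExpressionMatrix, config: Optional[ImpactConfig] = None
) -> pd.DataFrame:
    """CPM followed by pseudo-log, the standard per-gene pipeline."""
    config = config or ImpactConfig()
    return pseudolog(cpm_normalize(matrix), config.pseudocount)


def aggregate_with_offtargets(
    matrix: ExpressionMatrix,
    target: str,
    offtargets: Sequence[str],
    config: Optional[ImpactConfig] = None,
) -> pd.Series:
    """Normalized per-observation expression of target + its off-targets.

    Raw counts of the target and every off-target present in the matrix are
    summed per observation, re-normalized by the ORIGINAL library sizes
    (CPM), then pseudo-logged. Off-targets absent from the matrix are
    skipped. With no off-target present, this equals the target-only
    pipeline.
    """
    config = config or ImpactConfig()
    if target not in matrix.counts.columns:
        raise KeyError(f"target gene {target!r} absent from expression matrix")
    present = [g for g in offtargets if g in matrix.counts.columns and g != target]
    summed = matrix.counts[[target] + present].sum(axis=1)
    lib = matrix.library_sizes
    keep = lib[lib > 0].index
    cpm = summed.loc[keep] / lib.loc[keep] * 1e6
    return pseudolog(cpm, config.pseudocount)


@dataclass(frozen=True)
class ConcordanceResult:
    """RMSE vs the identity line plus Pearson r for one pair of vectors."""

    rmse: float
    pearson: float  # nan when either vector has zero variance
    n_observations: int

    @property
    def pearson_missing(self) -> bool:
        return math.isnan(self.pearson)


def concordance(vec_a, vec_b) -> ConcordanceResult:
    """RMSE relative to y = x, and Pearson correlation.

    Pearson is nan (explicitly missing, never coerced to 0) when either
    vector has zero variance. Vectors must have equal length >= 2.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or a.size < 2:
        raise ValueError("concordance requires 1-d vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.std(a) == 0 or np.std(b) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(a, b)[0, 1])
    return ConcordanceResult(rmse=rmse, pearson=pearson, n_observations=a.size)


def group_means(
    values: pd.DataFrame,
    labels: Sequence,
    min_size: int = 10,
    modality_labels: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-group means of normalized values, groups x genes.

    ``labels`` assigns each observation (row of ``values``) to a group.
    When ``modality_labels`` is given, a group must contain at least
    ``min_size`` observations from EVERY modality to be retained; otherwise
    the total group size is tested. Raises when every group is dropped.
    """
    labels = pd.Series(list(labels), index=values.index, name="group")
    if modality_labels is not None:
        modality = pd.Series(list(modality_labels), index=values.index)
        sizes = pd.crosstab(labels, modality)
        keep = sizes.index[(sizes >= min_size).all(axis=1)]
    else:
        sizes = labels.value_counts()
        keep = sizes.index[sizes >= min_size]
    if len(keep) == 0:
        raise ValueError("all groups fall below the minimum size")
    means = values.groupby(labels, sort=True).mean()
    return means.loc[sorted(keep, key=str)]


def strip_id_suffix(gene_id: str) -> str:
    """Drop a trailing version suffix (``ENSG000001.5`` -> ``ENSG000001``)."""
    return re.sub(r"\.\d+$", "", gene_id)


def offtarget_expression_screen(
    summaries: Iterable[GeneSummary],
    reference: ExpressionMatrix,
    config: Optional[ImpactConfig] = None,
) -> pd.DataFrame:
    """Screen predicted off-targets against a reference expression profile.

    The reference matrix is reduced to a bulk-like profile: CPM per
    observation, averaged across observations, then log1p. For each target
    gene with predicted off-targets, rows report every off-target gene
    ordered by decreasing log1p mean CPM; off-targets not detected in the
    matrix are flagged and placed after the ordered ones. Version suffixes
    are trimmed from gene identifiers before matching.
    """
    config = config or ImpactConfig()
    cpm = cpm_normalize(reference)
    profile = pseudolog(cpm.mean(axis=0), config.pseudocount)
    profile.index = [strip_id_suffix(g) for g in profile.index]
    profile = profile.groupby(level=0).max()
    rows = []
    for s in summaries:
        for ot in s.offtargets:
            keys = [strip_id_suffix(ot.gene_name), strip_id_suffix(ot.gene_id)]
            value = next((profile[k] for k in keys if k in profile.index), None)
            rows.append(
                {
                    "target_gene": s.target_gene_name or s.target_gene_id,
                    "offtarget_gene": ot.gene_name or ot.gene_id,
                    "detected": value is not None,
                    "log1p_mean_cpm": float(value) if value is not None else float("nan"),
                    "biotype": ot.biotype,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["target_gene", "offtarget_gene", "detected", "log1p_mean_cpm", "biotype"],
    )
    if len(table):
        table = table.sort_values(
            ["target_gene", "detected", "log1p_mean_cpm", "offtarget_gene"],
            ascending=[True, False, False, True],
        ).reset_index(drop=True)
    return table
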