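"""RPKM quantification and gene-level expression filters.

RPKM_ij = count_ij / ((L_i / 1e3) * (N_j / 1e6)) — reads per kilobase of
transcript per million mapped reads.  Library size N_j defaults to the
column sum but may be supplied externally (total mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FilterConfig", "compute_rpkm", "apply_filters"]


@dataclass
class FilterConfig:
    """Gene-inclusion thresholds applied before downstream analyses.

    All comparisons are inclusive (>=).  ``synthesis_fdr_max`` and
    ``fold_change_min`` belong to the differential-synthesis selection and
    are consumed there, not by :func:`apply_filters`.
    """

    min_mean_rpkm: float = 0.5
    min_length_bp: int = 300
    synthesis_fdr_max: float = 0.1
    fold_change_min: float = 1.5

    def validate(self) -> None:
        if self.min_mean_rpkm <= 0 or self.min_length_bp <= 0:
            raise ValueError("filter thresholds must be positive")
        if not 0 < self.synthesis_fdr_max <= 1:
            raise ValueError("synthesis_fdr_max must be in (0, 1]")
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must be > 1")


def compute_rpkm(
    counts: pd.DataFrame,
    gene_models: pd.DataFrame,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Convert a count matrix to RPKM.

    Parameters
    ----------
    counts
        genes x libraries integer matrix (gene_id index).
    gene_models
        gene_id-indexed frame with a ``length_bp`` column covering every
        gene in ``counts``.
    library_sizes
        Optional per-library total mapped reads; column sums when absent.
    """
    missing = counts.index.difference(gene_models.index)
    if len(missing):
        raise ValueError(f"gene(s) without a length: {list(missing[:5])}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
        if library_sizes.isna().any():
            lib = library_sizes.index[library_sizes.isna()][0]
            raise ValueError(f"missing library size for {lib!r}")
    if (library_sizes <= 0).any():
        lib = library_sizes.index[library_sizes <= 0][0]
        raise ValueError(f"library {lib!r} has zero mapped reads")
    lengths_kb = gene_models.loc[counts.index, "length_bp"].astype(float) / 1e3
    per_million = library_sizes.astype(float) / 1e6
    rpkm = counts.astype(float).div(lengths_kb, axis=0).div(per_million, axis=1)
    return rpkm


def apply_filters(
    expression: pd.DataFrame,
    gene_models: pd.DataFrame,
    config: FilterConfig,
    libraries: list[str],
) -> pd.Index:
    """Genes with mean RPKM >= threshold over ``libraries`` and length >= minimum.

    The FDR / fold-change criteria of the differential-synthesis selection
    are applied downstream, not here.  Idempotent by construction.
    """
    config.validate()
    if not libraries:
        raise ValueError("empty library list")
    missing = [lib for lib in libraries if lib not in expression.columns]
    if missing:
        raise ValueError(f"library(ies) not in expression table: {missing}")
    mean_rpkm = expression[libraries].mean(axis=1)
    lengths = gene_models.loc[expression.index, "length_bp"]
    keep = (mean_rpkm >= config.min_mean_rpkm) & (lengths >= config.min_length_bp)
    return expression.index[np.asarray(keep)]
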