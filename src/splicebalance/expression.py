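"""Probe-level expression handling and the splicing index.

The central quantity is the splicing index (SI) of an exon probe: the
fraction of a gene's total linear-scale intensity contributed by that probe
in one sample.  Because it is a ratio within (gene, sample), the SI is
invariant to overall gene expression: doubling every probe of a gene in a
sample leaves its SI vector untouched, so differences in SI between sample
groups isolate shifts in the internal exon balance of a gene (differential
splicing) from whole-gene up/down-regulation.

Expression matrices are pandas DataFrames of log2 intensities, features in
rows (index = probe or gene identifiers), samples in columns.  Probe
annotations are DataFrames indexed by probe_id with columns
``gene_id, exon_index, chrom, start, end, strand`` (0-based, half-open
coordinates).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ANNOTATION_COLUMNS = ["gene_id", "exon_index", "chrom", "start", "end", "strand"]


def read_expression(matrix_path, annotation_path):
    """Load a probe-level expression matrix and its probe annotation.

    Parameters
    ----------
    matrix_path : str or Path
        TSV with first column ``probe_id`` and one column per sample;
        values are log2 intensities.
    annotation_path : str or Path
        TSV with columns ``probe_id`` plus :data:`ANNOTATION_COLUMNS`.

    Returns
    -------
    (DataFrame, DataFrame)
        ``(matrix, annotation)``, the annotation restricted and ordered to
        the matrix rows.

    Raises
    ------
    DataError
        If a probe in the matrix is missing from the annotation, or a
        probe_id is duplicated in either table.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)

    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated probe_id rows in expression matrix: {dups}")
    if annotation.index.duplicated().any():
        dups = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise DataError(f"duplicated probe_id rows in annotation: {dups}")

    missing = matrix.index.difference(annotation.index)
    if len(missing) > 0:
        raise DataError(
            "probes present in matrix but missing from annotation: "
            + ", ".join(map(str, missing[:20]))
            + ("..." if len(missing) > 20 else "")
        )
    if not np.isfinite(matrix.to_numpy()).all():
        raise DataError("expression matrix contains missing or non-finite values")

    annotation = annotation.loc[matrix.index]
    return matrix, annotation


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples so every column shares one distribution.

    The target distribution is the row-wise mean of the sorted columns;
    each value is replaced by the mean-quantile at its within-column rank.
    Tied values receive the mean of the mean-quantiles spanned by their
    average rank, which preserves column sums under ties.  Rank order
    within each sample is preserved, and the transform is idempotent.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    mean_quantiles = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()
    # average ranks may be half-integers under ties; interpolate between
    # the two neighbouring mean-quantiles
    normalized = np.interp(ranks, np.arange(1, n + 1), mean_quantiles)
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)


def _median_polish(block: np.ndarray, max_iter: int = 20, tol: float = 1e-10):
    """Tukey median polish of a 2-D array.

    Returns ``(overall, row_effects, col_effects)`` from iterative
    alternating subtraction of row and column medians of the residuals.
    """
    resid = block.astype(float).copy()
    overall = 0.0
    row_eff = np.zeros(resid.shape[0])
    col_eff = np.zeros(resid.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row_eff += rmed
        resid -= rmed[:, None]
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cmed = np.median(resid, axis=0)
        col_eff += cmed
        resid -= cmed[None, :]
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        if np.abs(rmed).sum() + np.abs(cmed).sum() < tol:
            break
    return overall, row_eff, col_eff


def summarize_gene_expression(
    probe_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str = "median_polish",
) -> pd.DataFrame:
    """Summarize probe-level log2 intensities to one row per gene.

    ``method="median_polish"`` fits the RMA-style additive model
    probe + sample via Tukey median polish and reports overall + sample
    effects; ``method="mean"`` averages the gene's probe rows;
    ``method="linear_sum"`` reports log2 of the summed linear-scale
    probe intensities — the total expression over all isoforms, which is
    by construction blind to pure exon-proportion shifts (a log-scale
    summary such as median polish converts part of a proportion shift
    into an apparent gene-level change).
    """
    if method not in ("median_polish", "mean", "linear_sum"):
        raise ConfigurationError(
            f"unknown summarization method {method!r}; "
            "use 'median_polish', 'mean' or 'linear_sum'"
        )
    gene_of = annotation.loc[probe_matrix.index, "gene_id"]
    if method == "linear_sum":
        lin = np.power(2.0, probe_matrix.to_numpy(dtype=float))
        lin_df = pd.DataFrame(lin, index=probe_matrix.index, columns=probe_matrix.columns)
        out = np.log2(lin_df.groupby(gene_of.to_numpy()).sum())
        out.index.name = "gene_id"
        return out.sort_index()
    rows = {}
    for gene, idx in probe_matrix.groupby(gene_of, sort=True).groups.items():
        block = probe_matrix.loc[idx].to_numpy(dtype=float)
        if method == "mean":
            rows[gene] = block.mean(axis=0)
        else:
            overall, _, col_eff = _median_polish(block)
            rows[gene] = overall + col_eff
    out = pd.DataFrame.from_dict(rows, orient="index", columns=probe_matrix.columns)
    out.index.name = "gene_id"
    return out.sort_index()


def compute_splicing_index(
    probe_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    scale: str = "linear",
) -> pd.DataFrame:
    """Compute the per-probe splicing index matrix.

    For each (gene, sample), SI_p = lin_p / sum over the gene's probes of
    lin_q, with lin = 2**log2-value.  Rows of a gene therefore sum to 1 in
    every sample and single-probe genes have SI identically 1.

    ``scale="log2"`` is offered for sensitivity analysis only: it divides
    the log2 values directly, which is neither normalized to 1 nor
    scale-invariant.
    """
    if scale not in ("linear", "log2"):
        raise ConfigurationError(f"unknown scale {scale!r}; use 'linear' or 'log2'")
    values = probe_matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError("probe matrix contains non-finite values")
    lin = np.power(2.0, values) if scale == "linear" else values
    gene_of = annotation.loc[probe_matrix.index, "gene_id"].to_numpy()
    lin_df = pd.DataFrame(lin, index=probe_matrix.index, columns=probe_matrix.columns)
    totals = lin_df.groupby(gene_of).transform("sum")
    if (totals.to_numpy() <= 0).any():
        raise DataError("non-positive gene total encountered in SI computation")
    return lin_df / totals
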