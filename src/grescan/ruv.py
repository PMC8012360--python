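"""Unwanted-variation estimation for RNA-seq count matrices.

Implements the RNA-seq preprocessing track: a low-count gene filter,
median-of-ratios size factors, and a modified RUVg estimator.  RUVg
estimates factors of unwanted variation (batch, library preparation) by
SVD of the centered log expression of empirical control genes; the
variant here exposes *which* singular components form the k-factor
matrix W, defaulting to ranks (1, 4) - the configuration that skips the
middle components presumed to carry wanted treatment variation.

Count matrices are pandas DataFrames with genes as rows and samples as
columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class UnwantedFactors:
    """Samples x k factor matrix from the modified RUVg SVD."""

    W: pd.DataFrame  # samples x k, columns "W1".."Wk" by requested rank order
    component_indices: tuple[int, ...]
    control_gene_ids: tuple[str, ...]
    singular_values: np.ndarray


def filter_low_counts(
    matrix: pd.DataFrame, min_count: int = 15, min_samples: int = 2
) -> pd.DataFrame:
    """Keep genes with count strictly greater than ``min_count`` in at
    least ``min_samples`` samples.  Idempotent."""
    keep = (matrix > min_count).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors.

    Per-gene geometric means are taken over samples (genes containing any
    zero are excluded from the reference); each sample's factor is the
    median over genes of count / geometric mean.
    """
    counts = matrix.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with all-positive counts")
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1)
    sf = np.exp(np.median(logc - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=matrix.columns, name="size_factor")


def normalized_log_counts(
    matrix: pd.DataFrame, sf: pd.Series | None = None
) -> pd.DataFrame:
    """ln(size-factor-normalized count + 1)."""
    if sf is None:
        sf = size_factors(matrix)
    norm = matrix.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log1p(norm), index=matrix.index, columns=matrix.columns)


def estimate_unwanted(
    matrix: pd.DataFrame,
    control_gene_ids: Sequence[str] | None = None,
    component_indices: tuple[int, ...] = (1, 4),
    scale_by_singular_values: bool = False,
) -> UnwantedFactors:
    """Modified RUVg: SVD factors of unwanted variation at chosen ranks.

    ``Z`` is the per-gene-centered ln(normalized count + 1) restricted to
    the control genes; its SVD ``Z = U S V^T`` yields sample-space
    singular vectors (columns of V).  ``W`` collects the vectors at the
    requested singular-value ranks (1-based, ordered as given).  Signs
    are fixed so each column's largest-magnitude entry is positive, making
    the result reproducible across SVD backends.  Columns can optionally
    be scaled by their singular values.
    """
    if control_gene_ids is None:
        control_gene_ids = list(matrix.index)
    missing = set(control_gene_ids) - set(matrix.index)
    if missing:
        raise KeyError(f"control genes absent from matrix: {sorted(missing)[:5]}")
    if min(component_indices) < 1:
        raise ValueError("component indices are 1-based ranks")
    if matrix.shape[1] < max(component_indices):
        raise ValueError(
            f"need >= {max(component_indices)} samples for requested components"
        )
    logz = normalized_log_counts(matrix).loc[list(control_gene_ids)]
    Z = logz.to_numpy() - logz.to_numpy().mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max() * max(Z.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank < max(component_indices):
        raise np.linalg.LinAlgError(
            f"matrix rank {rank} below requested component {max(component_indices)}"
        )
    cols = {}
    for out_i, comp in enumerate(component_indices, start=1):
        v = Vt[comp - 1]
        v = v * np.sign(v[np.argmax(np.abs(v))])
        if scale_by_singular_values:
            v = v * S[comp - 1]
        cols[f"W{out_i}"] = v
    W = pd.DataFrame(cols, index=matrix.columns)
    return UnwantedFactors(
        W=W,
        component_indices=tuple(component_indices),
        control_gene_ids=tuple(control_gene_ids),
        singular_values=S,
    )


def export_design(
    W: pd.DataFrame | None, condition_labels: Sequence[str]
) -> pd.DataFrame:
    """Design table (intercept, condition indicator, W columns) for an
    external DE fit.  Warns, with the condition number, when the design is
    rank deficient (e.g. W collinear with condition)."""
    cond = pd.Series(condition_labels)
    levels = list(dict.fromkeys(cond))  # first-appearing level is reference
    if len(levels) > 2:
        raise ValueError("expected a two-level condition")
    design = pd.DataFrame(
        {
            "intercept": np.ones(len(cond)),
            "condition": (cond == levels[-1]).astype(float).to_numpy()
            if len(levels) == 2
            else np.zeros(len(cond)),
        }
    )
    if W is not None:
        if len(W) != len(cond):
            raise ValueError("W rows must align with samples")
        design.index = W.index
        for c in W.columns:
            design[c] = W[c].to_numpy()
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "design is rank deficient (condition number "
            f"{np.linalg.cond(X):.3g}); W may be collinear with condition",
            stacklevel=2,
        )
    return design


def adjust_log_counts(matrix: pd.DataFrame, W: pd.DataFrame | None) -> pd.DataFrame:
    """Residualize centered log expression on W (for PCA/visualization).

    Each gene's centered ln(normalized + 1) profile is regressed on the W
    columns by least squares; the residual matrix is returned.  With no W
    columns this is just the centered log expression.
    """
    logz = normalized_log_counts(matrix)
    Y = logz.to_numpy() - logz.to_numpy().mean(axis=1, keepdims=True)
    if W is None or W.shape[1] == 0:
        return pd.DataFrame(Y, index=matrix.index, columns=matrix.columns)
    X = W.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def read_count_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")
    return df


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")
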