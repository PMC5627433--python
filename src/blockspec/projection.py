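"""Principal component analysis of the protease x block-entropy matrix.

PCA on the 8x8 Pearson correlation matrix of the block entropies exposes
which blocks co-vary across proteases and hence which successive-subsite
combinations carry the specificity signal.  Components with eigenvalue > 1
are retained (Kaiser criterion); since the trace of a correlation matrix is
8, each retained component explains more variance than a single original
block.  Loadings are eigenvectors scaled by sqrt(eigenvalue), i.e. the
correlations between blocks and components.  No rotation is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .blocks import ENTROPY_LABELS, EntropyProfile

__all__ = ["PCAResult", "entropy_matrix", "pca_correlation"]

log = logging.getLogger(__name__)

_N_BLOCKS = len(ENTROPY_LABELS)


@dataclass
class PCAResult:
    """Correlation-PCA decomposition of an entropy matrix.

    Attributes
    ----------
    eigenvalues:
        All 8 eigenvalues, descending; they sum to 8.
    variance_explained:
        ``eigenvalue / 8 * 100`` per component; sums to 100 over all 8.
    n_retained:
        Number of eigenvalues > 1 (Kaiser criterion).
    loadings:
        (8, n_retained) block-component correlations.
    scores:
        (n_rows, n_retained) component scores of each protease; columns are
        mutually uncorrelated with variance equal to the eigenvalue.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # full (8, 8), columns match eigenvalues
    variance_explained: np.ndarray
    n_retained: int
    loadings: np.ndarray
    scores: np.ndarray
    column_labels: tuple[str, ...]
    row_labels: tuple[str, ...]


def entropy_matrix(profiles: Sequence[EntropyProfile]) -> pd.DataFrame:
    """Stack profiles into a proteases x 8 DataFrame (rows in input order)."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    df = pd.DataFrame(
        [p.as_array() for p in profiles],
        index=[p.protease_id for p in profiles],
        columns=list(ENTROPY_LABELS),
    )
    constant = [c for c in df.columns if df[c].nunique() == 1]
    if constant:
        log.warning("zero-variance entropy column(s): %s", ", ".join(constant))
    return df


def pca_correlation(matrix: Union[pd.DataFrame, np.ndarray]) -> PCAResult:
    """Eigendecomposition of the columns' Pearson correlation matrix.

    Components are sorted by descending eigenvalue; each eigenvector's sign
    is fixed so its largest-magnitude entry is positive (eigenvectors are
    otherwise sign-ambiguous).  Raises on a zero-variance column, since its
    correlations are undefined.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = tuple(str(c) for c in matrix.columns)
        rows = tuple(str(i) for i in matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = tuple(ENTROPY_LABELS[: X.shape[1]]) if X.shape[1] == _N_BLOCKS \
            else tuple(f"col{i}" for i in range(X.shape[1]))
        rows = tuple(str(i) for i in range(X.shape[0]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    n, k = X.shape
    if n < 9:
        warnings.warn(f"only {n} rows; correlation PCA is unstable below ~9",
                      stacklevel=2)
    std = X.std(axis=0, ddof=1)
    dead = np.nonzero(std == 0)[0]
    if dead.size:
        names = ", ".join(labels[i] for i in dead)
        raise ValueError(f"zero-variance column(s): {names}")

    corr = np.corrcoef(X, rowvar=False)
    eigenvalues, eigenvectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(eigenvectors[:, j])))
        if eigenvectors[i, j] < 0:
            eigenvectors[:, j] = -eigenvectors[:, j]

    n_retained = int((eigenvalues > 1.0).sum())
    retained = eigenvectors[:, :n_retained]
    loadings = retained * np.sqrt(eigenvalues[:n_retained])
    Z = (X - X.mean(axis=0)) / std
    scores = Z @ retained
    return PCAResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        variance_explained=eigenvalues / k * 100.0,
        n_retained=n_retained,
        loadings=loadings,
        scores=scores,
        column_labels=labels,
        row_labels=rows,
    )
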