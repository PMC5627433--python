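"""Euclidean distances between block-entropy profiles.

Two proteases are compared through their eight-block entropy vectors:

    d(P, Q) = sqrt( sum_k [E_k(P) - E_k(Q)]^2 + sum_k [E_k'(P) - E_k'(Q)]^2 )

which is the ordinary Euclidean distance in the 8-dimensional entropy
space.  The all-pairs matrix is symmetric with a zero diagonal and obeys
the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .blocks import EntropyProfile

__all__ = ["DistanceMatrix", "profile_distance", "distance_matrix", "write_matrix"]


@dataclass
class DistanceMatrix:
    """Symmetric inter-protease distance matrix with labelled axes."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match "
                             f"{n} labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def profile_distance(p: EntropyProfile, q: EntropyProfile) -> float:
    """Euclidean distance between two eight-block entropy profiles."""
    diff = p.as_array() - q.as_array()
    return float(np.sqrt(np.dot(diff, diff)))


def distance_matrix(profiles: Sequence[EntropyProfile]) -> DistanceMatrix:
    """All-pairs profile distances; label order follows the input order."""
    if not profiles:
        raise ValueError("need at least one profile")
    labels = tuple(p.protease_id for p in profiles)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate protease_id(s): {dupes}")
    mat = np.stack([p.as_array() for p in profiles])
    diff = mat[:, None, :] - mat[None, :, :]
    values = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


def write_matrix(m: DistanceMatrix, sink: TextIO, format: str = "csv") -> None:
    """Write the matrix as labelled CSV or square PHYLIP, 3 decimal places."""
    if format == "csv":
        sink.write("," + ",".join(m.labels) + "\n")
        for label, row in zip(m.labels, m.values):
            sink.write(label + "," + ",".join(f"{v:.3f}" for v in row) + "\n")
    elif format == "phylip":
        sink.write(f"{len(m.labels)}\n")
        for label, row in zip(m.labels, m.values):
            name = label[:10].ljust(10)
            sink.write(name + " ".join(f"{v:.3f}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'phylip'")
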