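"""Entropies, mutual-information rates and the normalized adjacency matrix.

The pairwise similarity between two encoded proteins is the maximum,
over all alignments of the shorter series against windows of the longer,
of the plug-in mutual information between the paired positions:

    I(X; Y_i) = sum_{a,b} p(a,b) log [ p(a,b) / (p(a) p(b)) ]
    I_max(X, Y) = max_i I(X; Y_i)

The summation is position-free — it runs over state combinations, so the
quantity depends only on state frequencies within the compared windows,
never on an alignment of residues, which is what makes the method
alignment-free.  I(X; Y_i) <= min(H(X), H(Y_i)), so dividing the matrix
by the largest per-protein entropy yields entries in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import DiscreteSeries

logger = logging.getLogger("infonet")

#: CSV output precision (significant digits).
CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class EntropyVector:
    """Per-protein Shannon entropies, aligned with the dataset record order."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.ids):
            raise ValueError("entropy vector and id list length mismatch")


@dataclass
class AdjacencyMatrix:
    """Symmetric pairwise max-MI matrix with zero diagonal.

    The diagonal is fixed to 0: self-similarity is never used by the
    classification, and a nonzero diagonal would dominate the mutative
    threshold (which is a multiple of the maximum entry).  ``clipped``
    counts normalized entries that exceeded 1 by empirical window-entropy
    fluctuation and were clipped (expected 0 in practice).
    """

    values: np.ndarray
    ids: list[str]
    normalized: bool = False
    clipped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("adjacency matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=0.0):
            raise ValueError("adjacency matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def max_offdiag(self) -> float:
        if self.n < 2:
            return 0.0
        off = self.values[~np.eye(self.n, dtype=bool)]
        return float(off.max())


# --------------------------------------------------------------------------
# entropy and mutual information
# --------------------------------------------------------------------------

def _as_values(series) -> np.ndarray:
    if isinstance(series, DiscreteSeries):
        return series.values
    return np.asarray(series, dtype=np.int64)


def _entropy_from_counts(counts: np.ndarray, base: float) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def shannon_entropy(series, base: float = 2.0) -> float:
    """Plug-in Shannon entropy of a discrete series (0 log 0 := 0)."""
    values = _as_values(series)
    if len(values) == 0:
        raise ValueError("cannot compute entropy of an empty series")
    counts = np.bincount(values)
    return _entropy_from_counts(counts, base)


def mutual_information(x, y, base: float = 2.0) -> float:
    """Plug-in mutual information between two equal-length series.

    The joint distribution is estimated from position-paired
    co-occurrence counts; computed as H(X) + H(Y) - H(X, Y), which equals
    the sum over state combinations of p(a,b) log[p(a,b)/(p(a)p(b))].
    Clamped at 0 against floating round-off.
    """
    xv, yv = _as_values(x), _as_values(y)
    if len(xv) != len(yv):
        raise ValueError("mutual information requires equal-length series")
    if len(xv) == 0:
        raise ValueError("cannot compute mutual information of empty series")
    ky = int(yv.max()) + 1
    joint = np.bincount(xv * ky + yv)
    hx = _entropy_from_counts(np.bincount(xv), base)
    hy = _entropy_from_counts(np.bincount(yv), base)
    hxy = _entropy_from_counts(joint, base)
    return max(0.0, hx + hy - hxy)


def max_mutual_information(x, y, base: float = 2.0) -> tuple[float, int]:
    """Maximum MI over all windows of the longer series (and its offset).

    The shorter series (length M) is slid along the longer (length N);
    the value is the maximum over the N - M + 1 windows and the offset is
    the smallest 1-based maximizing window start.  Sliding the shorter
    along the longer makes the operation symmetric in its arguments.
    """
    xv, yv = _as_values(x), _as_values(y)
    if len(xv) == 0 or len(yv) == 0:
        raise ValueError("cannot compare empty series")
    shorter, longer = (xv, yv) if len(xv) <= len(yv) else (yv, xv)
    m, n = len(shorter), len(longer)
    best, best_offset = -1.0, 1
    for i in range(n - m + 1):
        value = mutual_information(shorter, longer[i:i + m], base=base)
        if value > best:
            best, best_offset = value, i + 1
    return best, best_offset


# --------------------------------------------------------------------------
# adjacency construction
# --------------------------------------------------------------------------

def build_adjacency(
    dataset: list[DiscreteSeries], base: float = 2.0
) -> tuple[AdjacencyMatrix, EntropyVector]:
    """Pairwise max-MI matrix and per-protein entropies for a dataset.

    a_ij = max-MI(series_i, series_j) for i != j, computed once per
    unordered pair and mirrored, so symmetry is exact; the diagonal is 0.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 series to build an adjacency matrix")
    ids = [s.source_id or f"series_{q}" for q, s in enumerate(dataset)]
    if len(set(ids)) != n:
        raise ValueError("series ids must be unique")
    entropies = np.array([shannon_entropy(s, base=base) for s in dataset])
    if entropies.max() == 0.0:
        raise ValueError("degenerate dataset: every series is constant")
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            value, _ = max_mutual_information(dataset[i], dataset[j], base=base)
            a[i, j] = a[j, i] = value
    return (
        AdjacencyMatrix(values=a, ids=ids, normalized=False),
        EntropyVector(values=entropies, ids=ids),
    )


def normalize_adjacency(a: AdjacencyMatrix, h: EntropyVector) -> AdjacencyMatrix:
    """Divide every off-diagonal entry by the maximum per-protein entropy.

    The entropy bound I_max <= min(H_i, H_j) puts the result in [0, 1];
    any residual entry above 1 (possible only through window-entropy
    fluctuation in the empirical estimates) is clipped to 1 and counted.
    """
    if a.normalized:
        raise ValueError("adjacency matrix is already normalized")
    hmax = float(np.max(h.values))
    if hmax <= 0.0:
        raise ValueError("cannot normalize: maximum entropy is zero")
    values = a.values / hmax
    over = values > 1.0
    clipped = int(over.sum() // 2)
    if clipped:
        logger.warning("clipped %d normalized entries above 1", clipped)
        values = np.minimum(values, 1.0)
    np.fill_diagonal(values, 0.0)
    return AdjacencyMatrix(
        values=values, ids=list(a.ids), normalized=True, clipped=clipped,
        meta={"max_entropy": hmax},
    )


# --------------------------------------------------------------------------
# matrix / entropy CSV round-trip
# --------------------------------------------------------------------------

def write_matrix_csv(a: AdjacencyMatrix, path: str | Path) -> None:
    """Write the full symmetric matrix with an id header row and index."""
    df = pd.DataFrame(a.values, index=a.ids, columns=a.ids)
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT)


def read_matrix_csv(path: str | Path, normalized: bool = True) -> AdjacencyMatrix:
    """Read a symmetric similarity matrix written by :func:`write_matrix_csv`.

    A precomputed matrix supplied by the user is assumed normalized
    (entries in [0, 1]) unless stated otherwise.
    """
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # symmetrise away CSV round-off
    np.fill_diagonal(values, 0.0)
    return AdjacencyMatrix(values=values, ids=ids, normalized=normalized)


def write_entropy_csv(h: EntropyVector, path: str | Path) -> None:
    pd.DataFrame({"id": h.ids, "H": h.values}).to_csv(
        path, index=False, float_format=CSV_FLOAT_FORMAT
    )


def read_entropy_csv(path: str | Path) -> EntropyVector:
    df = pd.read_csv(path)
    return EntropyVector(values=df["H"].to_numpy(float), ids=[str(i) for i in df["id"]])
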