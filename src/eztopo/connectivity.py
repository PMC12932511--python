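"""Band-wise functional networks from Pearson correlations.

Edges are zero-lag Pearson correlation coefficients between channel (or
region) time series; binary networks keep an edge wherever ``|r|``
reaches the absolute threshold (default 0.7).  Strong anticorrelations
count as couplings under the absolute rule; a ``signed=True`` option
restricts edges to ``r >= T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "pcc_matrix",
    "binarize",
    "threshold_sweep",
    "DEFAULT_THRESHOLD",
    "SWEEP_THRESHOLDS",
]

DEFAULT_THRESHOLD = 0.7
SWEEP_THRESHOLDS = (0.6, 0.7, 0.8)


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    node_labels: list[str]
    band: str = ""
    state: str = ""
    degenerate: np.ndarray = field(default=None)  # zero-variance channels

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v
        if self.degenerate is None:
            self.degenerate = np.zeros(v.shape[0], dtype=bool)


@dataclass
class BinaryNetwork:
    """Unweighted undirected network (binary adjacency, no self-loops)."""

    adjacency: np.ndarray
    threshold: float
    node_labels: list[str]
    band: str = ""
    state: str = ""
    ez_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def pcc_matrix(
    data: np.ndarray,
    node_labels: Sequence[str] | None = None,
    band: str = "",
    state: str = "",
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations over an epoch (channels x samples).

    Zero-variance channels yield r = 0 off-diagonal (logged); they stay
    in the matrix so node indexing keeps matching the clinical labels.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(data)):
        raise ValueError("input contains non-finite samples")
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance channel(s); correlations set to 0",
                       int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    if node_labels is None:
        node_labels = [f"ch{i + 1}" for i in range(data.shape[0])]
    return ConnectivityMatrix(r, list(node_labels), band=band, state=state,
                              degenerate=degenerate)


def binarize(
    conn: ConnectivityMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    signed: bool = False,
    ez_mask: Optional[np.ndarray] = None,
) -> BinaryNetwork:
    """Threshold a correlation matrix into a binary undirected network.

    An edge is kept iff ``|r_ij| >= threshold`` (ties included), or
    ``r_ij >= threshold`` with ``signed=True``.  Degenerate channels
    become isolated nodes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    r = conn.values
    a = (r >= threshold) if signed else (np.abs(r) >= threshold)
    a = a.astype(np.uint8)
    np.fill_diagonal(a, 0)
    if conn.degenerate is not None and conn.degenerate.any():
        a[conn.degenerate, :] = 0
        a[:, conn.degenerate] = 0
    return BinaryNetwork(a, threshold, conn.node_labels, band=conn.band,
                         state=conn.state, ez_mask=ez_mask)


def threshold_sweep(
    conn: ConnectivityMatrix,
    thresholds: Iterable[float] = SWEEP_THRESHOLDS,
    signed: bool = False,
    ez_mask: Optional[np.ndarray] = None,
) -> list[BinaryNetwork]:
    """One binary network per threshold (sensitivity analysis)."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list is empty")
    return [binarize(conn, t, signed=signed, ez_mask=ez_mask) for t in thresholds]
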