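"""Nodal graph metrics and EZ/NEZ sub-network densities.

Four nodal metrics characterize each node of a binary network:

* node degree ``ND_i = sum_j a_ij``
* clustering coefficient ``C_i = 2 e_i / (k_i (k_i - 1))`` with ``e_i``
  the edge count among the neighbors of ``i`` (0 when ``k_i < 2``)
* betweenness centrality ``BC(i) = sum_{s<t, s!=i!=t} sigma_st(i) /
  sigma_st`` — unnormalized raw pair counts (an optional flag divides by
  ``(N-1)(N-2)/2``); pairs in different components contribute 0
* local efficiency ``LE_i``: the efficiency of the subgraph induced by
  the neighbors of ``i`` (mean inverse shortest-path distance within
  that subgraph; unreachable pairs contribute 0; 0 when ``k_i < 2``)

Metrics are computed on the whole network first and only then split by
the EZ/NEZ labels, so a node's value never depends on its label.  The
sub-network density analysis reports within-block ("internal") and
between-block ("interaction") edge densities for the EZ/NEZ bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .bands import BAND_NAMES
from .connectivity import BinaryNetwork

__all__ = [
    "node_degree",
    "clustering_coefficient",
    "betweenness_centrality",
    "local_efficiency",
    "nodal_metrics",
    "nodal_feature_table",
    "subnetwork_densities",
    "DensityReport",
    "METRIC_NAMES",
    "FEATURE_COLUMNS",
]

METRIC_NAMES = ("bc", "c", "le", "nd")

#: The 28 feature columns: 7 bands x 4 metrics.
FEATURE_COLUMNS = tuple(f"{band}_{m}" for band in BAND_NAMES for m in METRIC_NAMES)


def _adj(net) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(np.uint8)


def node_degree(net) -> np.ndarray:
    """Row sums of the adjacency matrix."""
    return _adj(net).sum(axis=1).astype(int)


def clustering_coefficient(net) -> np.ndarray:
    """Per-node triangle density among immediate neighbors."""
    a = _adj(net).astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / np.where(denom > 0, denom, 1), 0.0)
    return c


def betweenness_centrality(net, normalized: bool = False) -> np.ndarray:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    a = _adj(net)
    g = ig.Graph.Adjacency(a.tolist(), mode="undirected")
    bc = np.asarray(g.betweenness(directed=False), dtype=float)
    n = a.shape[0]
    if normalized and n > 2:
        bc = bc / ((n - 1) * (n - 2) / 2.0)
    return bc


def local_efficiency(net) -> np.ndarray:
    """Efficiency of each node's neighbor-induced subgraph."""
    a = _adj(net)
    n = a.shape[0]
    le = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = shortest_path(csr_matrix(sub), method="D", unweighted=True, directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        le[i] = inv.sum() / (k * (k - 1))
    return le


def nodal_metrics(net) -> pd.DataFrame:
    """All four nodal metrics of one network as a DataFrame."""
    return pd.DataFrame(
        {
            "bc": betweenness_centrality(net),
            "c": clustering_coefficient(net),
            "le": local_efficiency(net),
            "nd": node_degree(net),
        }
    )


def nodal_feature_table(banded_networks: dict[str, BinaryNetwork]) -> pd.DataFrame:
    """The per-node feature matrix for one sample (default 28 columns).

    ``banded_networks`` maps band name -> network; all networks must
    share the node set.  Columns are named ``{band}_{metric}``.
    """
    items = list(banded_networks.items())
    if not items:
        raise ValueError("no networks supplied")
    labels = items[0][1].node_labels
    for _, net in items:
        if net.node_labels != labels:
            raise ValueError("inconsistent node sets across bands")
    cols = {}
    for band, net in items:
        m = nodal_metrics(net)
        for name in METRIC_NAMES:
            cols[f"{band}_{name}"] = m[name].to_numpy()
    out = pd.DataFrame(cols)
    out.insert(0, "node", labels)
    return out


@dataclass
class DensityReport:
    """Internal and interaction densities of the EZ/NEZ bipartition."""

    d_ez: float  # within-EZ edges / C(n_ez, 2); nan when n_ez < 2
    d_nez: float
    d_cross: float  # EZ-NEZ edges / (n_ez * n_nez)
    e_ez: int
    e_nez: int
    e_cross: int
    n_ez: int
    n_nez: int
    band: str = ""
    state: str = ""

    @property
    def defined(self) -> dict[str, bool]:
        return {"d_ez": self.n_ez >= 2, "d_nez": self.n_nez >= 2, "d_cross": True}


def subnetwork_densities(net, ez_mask: np.ndarray | None = None) -> DensityReport:
    """Observed/possible edge ratios within and between the EZ/NEZ blocks.

    Blocks with fewer than 2 nodes get an undefined (NaN) within-density
    rather than 0.
    """
    a = _adj(net)
    if ez_mask is None and isinstance(net, BinaryNetwork):
        ez_mask = net.ez_mask
    if ez_mask is None:
        raise ValueError("ez_mask required")
    ez = np.asarray(ez_mask, dtype=bool)
    if ez.size != a.shape[0]:
        raise ValueError("ez_mask length must equal node count")
    nez = ~ez
    n_ez, n_nez = int(ez.sum()), int(nez.sum())
    e_ez = int(a[np.ix_(ez, ez)].sum()) // 2
    e_nez = int(a[np.ix_(nez, nez)].sum()) // 2
    e_cross = int(a[np.ix_(ez, nez)].sum())
    d_ez = e_ez / (n_ez * (n_ez - 1) / 2) if n_ez >= 2 else float("nan")
    d_nez = e_nez / (n_nez * (n_nez - 1) / 2) if n_nez >= 2 else float("nan")
    d_cross = e_cross / (n_ez * n_nez) if n_ez and n_nez else float("nan")
    band = getattr(net, "band", "") if isinstance(net, BinaryNetwork) else ""
    state = getattr(net, "state", "") if isinstance(net, BinaryNetwork) else ""
    return DensityReport(d_ez, d_nez, d_cross, e_ez, e_nez, e_cross,
                         n_ez, n_nez, band=band, state=state)
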