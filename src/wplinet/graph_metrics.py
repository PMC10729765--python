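"""Weighted graph-theory metrics of a connectivity matrix.

Four scalars summarize each network, following the Brain Connectivity
Toolbox conventions for weighted undirected graphs:

* ``D``  - average degree (mean node strength): (1/N) sum_ij w_ij.
* ``CC`` - average clustering coefficient. On dense weighted graphs the
  binary definition is degenerate (every triangle exists), so the default is
  the geometric-mean-of-triangle-weights variant (Onnela) computed on weights
  normalized by the matrix maximum; the literal binary coefficient on a
  thresholded graph is available via ``variant="binary"``.
* ``CPL`` - characteristic path length: mean shortest-path length over
  ordered node pairs, with edge length 1/w_ij.
* ``GE`` - global efficiency: mean inverse shortest-path length (1/inf = 0),
  finite even for disconnected graphs.

Scaling all weights by k > 0 scales D and GE by k, CPL by 1/k, and leaves CC
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra


class DisconnectedNetworkWarning(UserWarning):
    """Raised when a shortest-path average involves disconnected node pairs."""


@dataclass
class WeightedNetwork:
    """Symmetric non-negative weight matrix with a zero diagonal."""

    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [f"N{i}" for i in range(w.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths; inf for disconnected pairs."""

    lengths: np.ndarray
    node_labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]


@dataclass
class NetworkMetrics:
    D: float
    CC: float
    CPL: float
    GE: float

    def as_dict(self) -> dict[str, float]:
        return {"D": self.D, "CC": self.CC, "CPL": self.CPL, "GE": self.GE}


def average_degree(net: WeightedNetwork) -> float:
    """Mean node strength: (1/N) * sum of w_ij over all ordered pairs."""
    return float(net.weights.sum() / net.n_nodes)


def clustering_coefficient(
    net: WeightedNetwork,
    variant: str = "weighted",
    threshold: float = 0.0,
) -> float:
    """Average clustering coefficient.

    variant="weighted" (default): Onnela geometric-mean-of-triangles on
    weights normalized by the global maximum,
        C_i = sum_{j,k} (w'_ij w'_jk w'_ki)^(1/3) / (k_i (k_i - 1)),
    where k_i counts nonzero neighbors; nodes with k_i < 2 contribute 0.

    variant="binary": fraction of closed neighbor pairs on the graph
    thresholded at ``weight > threshold``.
    """
    w = net.weights
    n = net.n_nodes
    if n == 0:
        return 0.0
    adj = w > (threshold if variant == "binary" else 0.0)
    k = adj.sum(axis=1)
    denom = k * (k - 1.0)
    if variant == "weighted":
        wmax = w.max()
        if wmax == 0:
            return 0.0
        cube = np.cbrt(w / wmax)
        tri = np.diag(cube @ cube @ cube)  # 2x (weighted triangles) per node
    elif variant == "binary":
        a = adj.astype(np.float64)
        tri = np.diag(a @ a @ a)
    else:
        raise ValueError(f"unknown clustering variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return float(c.mean())


def distance_matrix(net: WeightedNetwork) -> DistanceMatrix:
    """Shortest paths under the BCT weight-to-length map: length_ij = 1/w_ij
    for w_ij > 0, no edge otherwise (Dijkstra from every node)."""
    w = net.weights
    lengths = csr_matrix(np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0))
    dist = dijkstra(lengths, directed=False)
    return DistanceMatrix(lengths=dist, node_labels=net.node_labels)


def characteristic_path_length(dm: DistanceMatrix, finite_only: bool = False) -> float:
    """Mean shortest-path length over ordered pairs i != j.

    Disconnected pairs make the mean infinite; a warning is emitted. With
    ``finite_only=True`` the mean is taken over connected pairs instead
    (changes the estimand; off by default).
    """
    n = dm.n_nodes
    if n < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    off = dm.lengths[~np.eye(n, dtype=bool)]
    if np.isinf(off).any():
        warnings.warn(
            "network is disconnected; characteristic path length is infinite",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
        if finite_only:
            finite = off[np.isfinite(off)]
            return float(finite.mean()) if finite.size else float("inf")
        return float("inf")
    return float(off.mean())


def global_efficiency(dm: DistanceMatrix) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    n = dm.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    off = dm.lengths[~np.eye(n, dtype=bool)]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    return float(inv.mean())


def compute_all(net: WeightedNetwork, finite_only_cpl: bool = False) -> NetworkMetrics:
    """All four metrics of one network."""
    dm = distance_matrix(net)
    return NetworkMetrics(
        D=average_degree(net),
        CC=clustering_coefficient(net),
        CPL=characteristic_path_length(dm, finite_only=finite_only_cpl),
        GE=global_efficiency(dm),
    )
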