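"""Delayed-synchrony functional graphs and hub analysis.

For every ordered electrode pair (i, j) the fraction of "delayed
synchronous" spikes is computed: a spike on j at time t_j counts as
received from i when i fired inside the window

    [t_j - tau_ij - delta/2,  t_j - tau_ij + delta/2],

where tau_ij = distance(i, j) / conduction velocity is the expected
axonal delay and delta a small tolerance.  Normalizing by n_j, the
number of spikes on the postsynaptic electrode, gives the connectivity
matrix C[i][j] = n_synchr / n_j in [0, 1] — a cross-correlation analogue
for spike trains.  The largest 5% of entries form the functional graph;
electrodes with exceptionally many incident connections are its hubs.
Each electrode's hub coefficient is its incident-connection count over
the total number of connections in the graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .containers import SpikeRaster
from .geometry import ElectrodeGeometry

logger = logging.getLogger(__name__)


@dataclass
class SynchronyParams:
    """Conduction velocity, tolerance window and selection quantile."""

    velocity_m_s: float = 0.4
    delta_ms: float = 2.0
    quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.velocity_m_s <= 0:
            raise ValueError("velocity must be positive")
        if self.delta_ms <= 0:
            raise ValueError("delta must be positive")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")


@dataclass
class SynchronyMatrix:
    """Pairwise delayed-synchrony fractions.

    ``C[i, j]`` is the fraction of j's spikes with an i-spike in the
    delay window; the diagonal is zero by convention.  ``defined[j]`` is
    False for electrodes with no spikes, whose column is reported as 0.
    """

    C: np.ndarray
    n_spikes: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if self.C.size and (np.nanmin(self.C) < 0 or np.nanmax(self.C) > 1):
            raise ValueError("synchrony fractions must lie in [0, 1]")

    @property
    def n_electrodes(self) -> int:
        return self.C.shape[0]


@dataclass
class SynchronyGraph:
    """Selected functional connections plus per-electrode degrees."""

    edges: list[tuple[int, int, float]]   # (src, dst, weight)
    n_electrodes: int
    threshold: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        """Incident-edge count per electrode (in + out)."""
        deg = np.zeros(self.n_electrodes, dtype=np.int64)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def hub_coefficients(self) -> np.ndarray:
        """Per-electrode incident-connection count / total connections.

        Sums to 2 over the array whenever the graph has edges (every
        edge is incident to exactly two electrodes).
        """
        if self.n_edges == 0:
            return np.zeros(self.n_electrodes)
        return self.degrees() / self.n_edges

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_electrodes))
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class Hub:
    """A highly connected electrode of the functional graph."""

    electrode: int
    degree: int
    hub_coefficient: float


def synchrony_matrix(
    raster: SpikeRaster,
    geometry: ElectrodeGeometry,
    params: SynchronyParams | None = None,
) -> SynchronyMatrix:
    """Delayed-synchrony connectivity matrix of a raster.

    Each postsynaptic spike is counted at most once per pair, so
    ``C[i, j] <= 1``.  The window is closed on both sides; with
    continuous spike times the boundary carries no probability mass.
    Requires spikes on at least two electrodes.
    """
    params = params or SynchronyParams()
    n = geometry.n_electrodes
    trains = raster.times_by_electrode()
    n_spikes = np.array([t.size for t in trains], dtype=np.int64)
    if np.count_nonzero(n_spikes) < 2:
        raise ValueError("synchrony requires spikes on at least two electrodes")

    dist = geometry.distance_matrix_um()
    half = params.delta_ms / 2000.0  # s
    C = np.zeros((n, n))
    defined = n_spikes > 0
    for j in range(n):
        tj = trains[j]
        if tj.size == 0:
            continue
        for i in range(n):
            if i == j or trains[i].size == 0:
                continue
            tau = dist[i, j] * 1e-6 / params.velocity_m_s  # s
            lo = tj - tau - half
            hi = tj - tau + half
            ti = trains[i]
            matched = np.searchsorted(ti, lo, side="left") < np.searchsorted(ti, hi, side="right")
            C[i, j] = matched.sum() / tj.size
    return SynchronyMatrix(C=C, n_spikes=n_spikes, defined=defined)


def select_edges(
    matrix: SynchronyMatrix, quantile: float = 0.95
) -> SynchronyGraph:
    """Keep the largest (1 - quantile) fraction of connectivity entries.

    The threshold is the empirical ``quantile`` of all off-diagonal
    entries whose postsynaptic electrode fired; edges are the entries
    strictly above it.  With all entries equal the selection is
    degenerate and an empty graph is returned with a warning.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    n = matrix.n_electrodes
    off = ~np.eye(n, dtype=bool)
    valid = off & matrix.defined[None, :]
    vals = matrix.C[valid]
    if vals.size == 0 or np.all(vals == vals[0]):
        warnings.warn("degenerate connectivity matrix: no edges selected", stacklevel=2)
        return SynchronyGraph(edges=[], n_electrodes=n, threshold=float("nan"))
    threshold = float(np.quantile(vals, quantile))
    src, dst = np.nonzero(valid & (matrix.C > threshold))
    edges = [(int(i), int(j), float(matrix.C[i, j])) for i, j in zip(src, dst)]
    logger.info("selected %d edges above C=%.4f", len(edges), threshold)
    return SynchronyGraph(edges=edges, n_electrodes=n, threshold=threshold)


def identify_hubs(
    graph: SynchronyGraph, hub_min_degree: int | None = None
) -> list[Hub]:
    """Electrodes with a maximal number of functionally active connections.

    With ``hub_min_degree`` given, hubs are electrodes whose incident
    degree is at least that.  By default hubs are electrodes whose
    degree exceeds the 90th percentile of the nonzero degrees — "the
    most connected tail" of the degree distribution.
    """
    deg = graph.degrees()
    nonzero = deg[deg > 0]
    if nonzero.size == 0 or graph.n_edges == 0:
        return []
    coef = graph.hub_coefficients()
    if hub_min_degree is not None:
        chosen = np.flatnonzero(deg >= hub_min_degree)
    else:
        cut = np.percentile(nonzero, 90)
        chosen = np.flatnonzero(deg > cut)
    return [Hub(int(e), int(deg[e]), float(coef[e])) for e in chosen]


def hub_overlap(hubs_a: set[int] | list[int], hubs_b: set[int] | list[int]) -> float:
    """Percentage overlap between two hub sets (Jaccard index x 100).

    Used to quantify how stable the network's hub structure is between
    two recording sessions.  An empty union is reported as 0 with a
    warning.
    """
    a, b = set(hubs_a), set(hubs_b)
    union = a | b
    if not union:
        warnings.warn("overlap of two empty hub sets reported as 0", stacklevel=2)
        return 0.0
    return 100.0 * len(a & b) / len(union)
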