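"""Weighted global graph metrics on normalized connectivity matrices.

The three outcomes are the weighted clustering coefficient (CC, geometric-
mean triangle intensity), the characteristic path length (PL, mean
shortest-path distance with edge length = reciprocal weight) and the
small-world index (SWI), a within-participant ratio of CC to PL after
normalizing each by the mean of the other frequency bands.  Graphs are
fully weighted: no threshold is applied, every connection is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityStack, InputError

__all__ = [
    "WeightedGraph",
    "GraphOutcome",
    "DegenerateStackError",
    "DisconnectedGraphError",
    "normalize_stack",
    "clustering_coefficient",
    "path_length",
    "small_world_index",
    "aggregate_epochs",
]


class DegenerateStackError(ValueError):
    """A connectivity stack whose values are all equal cannot be rescaled."""


class DisconnectedGraphError(ValueError):
    """Path length is undefined when some node pairs are unreachable."""


@dataclass
class WeightedGraph:
    """Symmetric weighted undirected graph with weights in [0, 1]."""

    weights: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InputError("weights must be a square matrix")
        if w.shape[0] == 0:
            raise InputError("empty graph")
        if not np.allclose(w, w.T, atol=1e-12):
            raise InputError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise InputError("diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise InputError("weights must lie in [0, 1]")
        self.weights = np.clip(0.5 * (w + w.T), 0.0, 1.0)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphOutcome:
    """Global graph outcomes for one participant/session/condition/band/estimator."""

    participant_id: str
    session_id: str
    condition: str
    band: str
    estimator: str
    cc: float
    pl: float
    swi: float | None = None


def normalize_stack(stack: ConnectivityStack) -> list[WeightedGraph]:
    """Min-max rescale a stack's off-diagonal values onto exactly [0, 1].

    The minimum and maximum are located over ALL off-diagonal entries of
    all epochs in the stack (i.e. per participant, session, condition, band
    and estimator), then every matrix is mapped affinely so the stack-wide
    minimum becomes 0 and the maximum 1.  Epoch identity is retained.
    """
    if stack.n_epochs == 0:
        raise InputError("empty connectivity stack")
    vals = stack.offdiag_values()
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise DegenerateStackError(
            f"stack {stack.participant_id}/{stack.session_id}/{stack.condition} "
            f"({stack.estimator}, {stack.band.name}) is constant at {lo}: "
            "cannot rescale"
        )
    graphs = []
    for m in stack.matrices:
        w = (m - lo) / (hi - lo)
        np.fill_diagonal(w, 0.0)
        graphs.append(WeightedGraph(weights=w, node_labels=list(stack.channel_labels)))
    return graphs


def clustering_coefficient(g: WeightedGraph) -> float:
    """Global weighted clustering coefficient (geometric-mean triangles).

    Per node, ``C_i = (W^{1/3})^3_ii / (k_i (k_i - 1))`` with ``k_i`` the
    number of nonzero neighbours; nodes with fewer than two neighbours
    contribute 0.  Weights are assumed already in [0, 1]; the global value
    is the mean over all nodes.
    """
    w = g.weights
    k = np.count_nonzero(w, axis=1).astype(float)
    w13 = np.cbrt(w)
    tri = np.diagonal(w13 @ w13 @ w13)  # 2 x sum of triangle intensities per node
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(ci.mean())


def path_length(g: WeightedGraph) -> float:
    """Characteristic path length: mean shortest-path distance over node pairs.

    Edge lengths are reciprocal weights (stronger connection = shorter
    path); zero-weight edges are absent.  Raises
    :class:`DisconnectedGraphError` naming unreachable pairs.
    """
    w = g.weights
    n = g.n_nodes
    if n < 2:
        raise InputError("path length needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.isinf(dist[off])):
        bad = np.argwhere(np.isinf(dist) & off)
        pairs = [(g.node_labels[i], g.node_labels[j]) for i, j in bad[:5]]
        raise DisconnectedGraphError(
            f"{len(bad)} unreachable ordered node pairs, e.g. {pairs}"
        )
    return float(dist[off].mean())


def small_world_index(
    cc_by_band: Mapping[str, float],
    pl_by_band: Mapping[str, float],
) -> dict[str, float]:
    """Per-band SWI from cross-band normalized CC and PL.

    For band ``b``, CC and PL are each divided by the mean of the other
    bands' values (leave-one-band-out), and SWI_b is the ratio of the two
    normalized values.  Requires at least two bands and positive values.
    """
    bands = list(cc_by_band)
    if set(bands) != set(pl_by_band):
        raise InputError("CC and PL must cover the same bands")
    if len(bands) < 2:
        raise InputError("SWI normalization needs at least 2 bands")
    cc = np.array([cc_by_band[b] for b in bands], dtype=float)
    pl = np.array([pl_by_band[b] for b in bands], dtype=float)
    if np.any(cc <= 0) or np.any(pl <= 0):
        raise InputError("SWI requires strictly positive CC and PL in every band")
    out = {}
    for idx, b in enumerate(bands):
        others = np.arange(len(bands)) != idx
        norm_cc = cc[idx] / cc[others].mean()
        norm_pl = pl[idx] / pl[others].mean()
        out[b] = float(norm_cc / norm_pl)
    return out


def aggregate_epochs(
    per_epoch_cc: Sequence[float],
    per_epoch_pl: Sequence[float],
) -> tuple[float, float]:
    """Arithmetic means of per-epoch global CC and PL.

    SWI is computed afterwards from the epoch-averaged CC/PL across bands,
    not averaged per epoch.
    """
    cc = np.asarray(per_epoch_cc, dtype=float)
    pl = np.asarray(per_epoch_pl, dtype=float)
    if cc.size == 0 or cc.size != pl.size:
        raise InputError("need matching non-empty per-epoch CC and PL")
    return float(cc.mean()), float(pl.mean())
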