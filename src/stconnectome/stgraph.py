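"""Multilayer spatiotemporal graph and connected-component extraction.

Nodes are active (region, frame) cells of a point-process raster.  Two nodes
are linked when the regions are structurally connected (white-matter tract in
the binarized structural template) and co-active in the same frame or in two
consecutive frames; a region active in consecutive frames is also linked to
itself across the frame boundary, so a persistently active region does not
fragment.  Weakly connected components (CCs) of this graph are transient
spatiotemporal activity patterns; each is summarized by its spatial
activation vector x (per-region active-frame counts), its length (inclusive
frame span), and its height (fraction of all regions involved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from ._core import DimensionError, StructuralConnectome
from .pointprocess import ActivationRaster


@dataclass(frozen=True)
class SpatioTemporalGraph:
    """Node arrays (parallel region/frame ids) plus a symmetric sparse adjacency."""

    node_regions: np.ndarray
    node_frames: np.ndarray
    adjacency: sparse.csr_matrix
    n_regions: int
    n_frames: int

    @property
    def n_nodes(self) -> int:
        return int(self.node_regions.size)

    def nodes(self) -> list[tuple[int, int]]:
        return list(zip(self.node_regions.tolist(), self.node_frames.tolist()))

    def edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """Explicit undirected edge list, each edge once."""
        coo = sparse.triu(self.adjacency, k=1).tocoo()
        out = []
        for a, b in zip(coo.row, coo.col):
            out.append(
                (
                    (int(self.node_regions[a]), int(self.node_frames[a])),
                    (int(self.node_regions[b]), int(self.node_frames[b])),
                )
            )
        return out


@dataclass(frozen=True)
class ConnectedComponent:
    """One weakly connected cluster of (region, frame) activations.

    ``regions``/``frame_counts`` encode the spatial activation vector x in
    sparse form: region ``regions[k]`` is active in ``frame_counts[k]``
    distinct frames of the component.
    """

    regions: np.ndarray
    frame_counts: np.ndarray
    t_min: int
    t_max: int
    size: int
    n_regions_total: int
    node_regions: np.ndarray = field(repr=False, default=None)
    node_frames: np.ndarray = field(repr=False, default=None)
    subject_id: str | None = None

    @property
    def length(self) -> int:
        """Duration in frames: inclusive span t_max - t_min + 1."""
        return int(self.t_max - self.t_min + 1)

    @property
    def n_regions_involved(self) -> int:
        return int(self.regions.size)

    @property
    def height(self) -> float:
        """Fraction of all brain regions involved in the component."""
        return self.n_regions_involved / self.n_regions_total

    @property
    def x(self) -> np.ndarray:
        """Dense spatial activation vector of length N."""
        out = np.zeros(self.n_regions_total, dtype=np.int64)
        out[self.regions] = self.frame_counts
        return out


@dataclass(frozen=True)
class CCSet:
    """All components of one subject, plus the filter bookkeeping."""

    components: list[ConnectedComponent]
    n_regions: int
    n_frames: int
    min_size: int
    n_discarded: int
    discarded_nodes: int

    @property
    def n_cc(self) -> int:
        return len(self.components)

    @property
    def total_nodes(self) -> int:
        """Active cells covered by retained + discarded components."""
        return sum(c.size for c in self.components) + self.discarded_nodes


def build_graph(
    raster: ActivationRaster,
    sc: StructuralConnectome,
    sc_threshold: float = 0.0,
    temporal_self_edges: bool = True,
) -> SpatioTemporalGraph:
    """Assemble the multilayer graph from a raster and the structural template.

    Edge rule: {(i,t),(j,t')} is an edge iff |t-t'| <= 1 and either i=j
    (consecutive frames, when ``temporal_self_edges``) or regions i,j share a
    binarized structural connection (weight > ``sc_threshold``).
    """
    act = raster.active
    n_regions, n_frames = act.shape
    if sc.n_regions != n_regions:
        raise DimensionError(
            f"raster has {n_regions} regions but structural matrix is "
            f"{sc.n_regions} x {sc.n_regions}"
        )

    node_ids = np.full(act.shape, -1, dtype=np.int64)
    node_regions, node_frames = np.nonzero(act)
    node_ids[node_regions, node_frames] = np.arange(node_regions.size)

    ei, ej = sc.edge_list(sc_threshold)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []

    if ei.size:
        act_i = act[ei]  # (n_edges, T)
        act_j = act[ej]
        # co-active in the same frame
        e, t = np.nonzero(act_i & act_j)
        rows.append(node_ids[ei[e], t])
        cols.append(node_ids[ej[e], t])
        # co-active in consecutive frames, both directions
        e, t = np.nonzero(act_i[:, :-1] & act_j[:, 1:])
        rows.append(node_ids[ei[e], t])
        cols.append(node_ids[ej[e], t + 1])
        e, t = np.nonzero(act_j[:, :-1] & act_i[:, 1:])
        rows.append(node_ids[ej[e], t])
        cols.append(node_ids[ei[e], t + 1])

    if temporal_self_edges and n_frames > 1:
        i, t = np.nonzero(act[:, :-1] & act[:, 1:])
        rows.append(node_ids[i, t])
        cols.append(node_ids[i, t + 1])

    n_nodes = node_regions.size
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    data = np.ones(r.size, dtype=np.int8)
    adj = sparse.coo_matrix((data, (r, c)), shape=(n_nodes, n_nodes)).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.int8)

    return SpatioTemporalGraph(
        node_regions=node_regions,
        node_frames=node_frames,
        adjacency=adj,
        n_regions=n_regions,
        n_frames=n_frames,
    )


def extract_components(
    graph: SpatioTemporalGraph,
    min_size: int = 2,
    subject_id: str | None = None,
) -> CCSet:
    """Partition the graph into weakly connected components.

    Components with fewer than ``min_size`` nodes are discarded but counted,
    so retained + discarded nodes always equal the raster's active cells.
    """
    n_nodes = graph.n_nodes
    if n_nodes == 0:
        return CCSet([], graph.n_regions, graph.n_frames, min_size, 0, 0)

    n_comp, labels = connected_components(graph.adjacency, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(n_comp + 1))

    components: list[ConnectedComponent] = []
    n_discarded = 0
    discarded_nodes = 0
    for k in range(n_comp):
        idx = order[bounds[k] : bounds[k + 1]]
        if idx.size < min_size:
            n_discarded += 1
            discarded_nodes += idx.size
            continue
        regs = graph.node_regions[idx]
        frs = graph.node_frames[idx]
        uregs, counts = np.unique(regs, return_counts=True)
        components.append(
            ConnectedComponent(
                regions=uregs,
                frame_counts=counts,
                t_min=int(frs.min()),
                t_max=int(frs.max()),
                size=int(idx.size),
                n_regions_total=graph.n_regions,
                node_regions=regs,
                node_frames=frs,
                subject_id=subject_id,
            )
        )
    return CCSet(
        components=components,
        n_regions=graph.n_regions,
        n_frames=graph.n_frames,
        min_size=min_size,
        n_discarded=n_discarded,
        discarded_nodes=discarded_nodes,
    )


def cc_summary(ccset: CCSet) -> dict:
    """Per-subject record feeding the group-level ANCOVA.

    Returns ``n_cc`` plus the mean length and mean height over retained
    components; the means are NaN when no component was retained.
    """
    n = ccset.n_cc
    if n == 0:
        return {"n_cc": 0, "mean_length": float("nan"), "mean_height": float("nan")}
    return {
        "n_cc": n,
        "mean_length": float(np.mean([c.length for c in ccset.components])),
        "mean_height": float(np.mean([c.height for c in ccset.components])),
    }
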