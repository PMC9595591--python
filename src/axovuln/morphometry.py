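"""Neurite segmentation, skeleton-graph construction and morphometry.

Traces the marker channel (the cultures' neurites are overwhelmingly
axonal), reduces the binary trace to a one-pixel centerline, converts it
to a geometric graph, and reports the per-well length and branching
metrics: mean neurite length per neuron, segments ("sections", maximal
skeleton paths between branch/end nodes) per neuron, and mean segment
length.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sato, threshold_otsu
from skimage.morphology import (
    dilation,
    disk,
    remove_small_objects,
    skeletonize as _sk_skeletonize,
)

from .core import ImageField
from .census import SomaMask

DEFAULT_SPUR_LENGTH_UM = 1.0
DEFAULT_MIN_COMPONENT_UM = 2.0

# 8-neighbourhood: orthogonal steps first, then diagonals
_ORTH = ((0, 1), (1, 0), (0, -1), (-1, 0))
_DIAG = ((1, 1), (1, -1), (-1, 1), (-1, -1))


@dataclass
class SkeletonSegment:
    """Maximal skeleton path between nodes of degree != 2."""

    endpoints: tuple[int, int]
    polyline_um: np.ndarray  # (N, 2) of (x, y)
    length_um: float


@dataclass
class SkeletonGraph:
    """Geometric graph of neurite centerlines.

    ``graph`` is a networkx graph on pixel-node ids with per-edge
    ``length_um`` weights (orthogonal steps count ``pixel_size_um``,
    diagonal steps ``sqrt(2) * pixel_size_um``); ``segments`` are its
    degree-2 chains contracted into maximal paths.
    """

    graph: nx.Graph
    segments: list[SkeletonSegment]
    pixel_size_um: float

    @property
    def total_length_um(self) -> float:
        return float(
            sum(d["length_um"] for _, _, d in self.graph.edges(data=True))
        )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def segment_lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.segments])

    def node_xy_um(self, node: int) -> tuple[float, float]:
        x, y = self.graph.nodes[node]["xy_px"]
        return (x * self.pixel_size_um, y * self.pixel_size_um)


@dataclass
class MorphometryResult:
    """Per-well neurite morphometry, normalized to the well's neuron count."""

    well_id: str
    total_neurite_length_um: float
    n_segments: int
    n_neurons: int
    mean_length_per_neuron_um: float
    segments_per_neuron: float
    mean_segment_length_um: float
    valid: bool = True


def segment_neurites(
    field: ImageField,
    soma_mask: SomaMask | None = None,
    channel: str = "marker",
    min_component_um: float = DEFAULT_MIN_COMPONENT_UM,
    soma_dilation_um: float = 1.5,
) -> np.ndarray:
    """Binary raster of thin neurites.

    Union of a tubular-structure (ridge-filter) detection and a
    robust-intensity detection — the latter keeps varicosity sites, where
    a pure ridge response dips — minus the dilated soma mask; isolated
    components shorter than ``min_component_um`` are removed.
    """
    img = field.channel(channel).astype(float)
    px = field.pixel_size_um
    if img.max() == img.min():
        return np.zeros(img.shape, bool)
    ridge = sato(img, sigmas=(1.0, 1.5), black_ridges=False)
    pos = ridge[ridge > 0]
    ridge_mask = (
        ridge > threshold_otsu(pos) if pos.size and pos.max() > pos.min() else
        np.zeros(img.shape, bool)
    )
    smooth = ndi.gaussian_filter(img, 0.8)
    bg = np.median(smooth)
    mad = np.median(np.abs(smooth - bg)) * 1.4826
    intensity_mask = smooth > bg + 6.0 * max(mad, 1e-9)
    binary = ridge_mask | intensity_mask
    if soma_mask is not None and soma_mask.labels.max() > 0:
        soma = soma_mask.labels > 0
        soma = dilation(soma, disk(max(int(round(soma_dilation_um / px)), 1)))
        binary &= ~soma
    min_px = max(int(round(min_component_um / px)), 1)
    binary = remove_small_objects(binary, max_size=min_px - 1, connectivity=2)
    return binary


def _pixel_graph(skel: np.ndarray, pixel_size_um: float) -> nx.Graph:
    """8-connected pixel graph; a diagonal link is skipped when an
    orthogonal two-step path through a shared neighbour exists (avoids
    double-counting staircase length)."""
    h, w = skel.shape
    idx = -np.ones(skel.shape, dtype=np.int64)
    rows, cols = np.nonzero(skel)
    idx[rows, cols] = np.arange(rows.size)
    g = nx.Graph()
    for n, (r, c) in enumerate(zip(rows, cols)):
        g.add_node(int(n), xy_px=(int(c), int(r)))
    step = pixel_size_um
    diag = np.sqrt(2.0) * pixel_size_um
    for r, c in zip(rows, cols):
        a = idx[r, c]
        for dr, dc in _ORTH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and idx[rr, cc] >= 0 and idx[rr, cc] > a:
                g.add_edge(int(a), int(idx[rr, cc]), length_um=step)
        for dr, dc in _DIAG:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w and idx[rr, cc] >= 0 and idx[rr, cc] > a):
                continue
            if idx[r + dr, c] >= 0 or idx[r, c + dc] >= 0:
                continue  # orthogonal detour exists
            g.add_edge(int(a), int(idx[rr, cc]), length_um=diag)
    return g


def _prune_spurs(g: nx.Graph, max_spur_um: float) -> None:
    """Iteratively remove terminal chains shorter than ``max_spur_um`` that
    hang off a branch node (skeletonization artifacts)."""
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in g.nodes if g.degree(n) == 1]:
            if leaf not in g:
                continue
            chain = [leaf]
            length = 0.0
            cur, prev = leaf, None
            while True:
                nbrs = [n for n in g.neighbors(cur) if n != prev]
                if g.degree(cur) > 2 and cur != leaf:
                    break  # reached a junction; cur stays
                if not nbrs:
                    cur = None
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["length_um"]
                prev, cur = cur, nxt
                if g.degree(cur) != 2:
                    break
                chain.append(cur)
            # only prune if the chain terminates at a junction (degree > 2)
            if cur is not None and g.degree(cur) > 2 and length < max_spur_um:
                g.remove_nodes_from(chain)
                changed = True


def _contract_segments(g: nx.Graph, pixel_size_um: float) -> list[SkeletonSegment]:
    """Maximal paths between nodes of degree != 2 (plus isolated cycles)."""
    segments: list[SkeletonSegment] = []
    seen_edges: set[frozenset[int]] = set()

    def walk(start: int, first: int) -> None:
        path = [start, first]
        length = g.edges[start, first]["length_um"]
        prev, cur = start, first
        while g.degree(cur) == 2:
            nxt = next(n for n in g.neighbors(cur) if n != prev)
            length += g.edges[cur, nxt]["length_um"]
            path.append(nxt)
            prev, cur = cur, nxt
            if cur == start:
                break
        key = frozenset((path[0], path[-1], len(path)))
        poly = np.array(
            [g.nodes[n]["xy_px"] for n in path], float
        ) * pixel_size_um
        segments.append(SkeletonSegment((path[0], path[-1]), poly, float(length)))
        for a, b in zip(path[:-1], path[1:]):
            seen_edges.add(frozenset((a, b)))

    junction_or_end = [n for n in g.nodes if g.degree(n) != 2]
    for node in junction_or_end:
        for nbr in g.neighbors(node):
            if frozenset((node, nbr)) not in seen_edges:
                walk(node, nbr)
    # pure cycles (every node degree 2)
    for comp in nx.connected_components(g):
        comp_edges = g.subgraph(comp).edges
        if any(frozenset(e) in seen_edges for e in comp_edges):
            continue
        if all(g.degree(n) == 2 for n in comp):
            start = next(iter(comp))
            walk(start, next(iter(g.neighbors(start))))
    return segments


def skeletonize(
    mask: np.ndarray,
    pixel_size_um: float,
    spur_length_um: float = DEFAULT_SPUR_LENGTH_UM,
) -> SkeletonGraph:
    """1-px topological skeleton of a binary raster as a geometric graph.

    Edge lengths follow the explicit convention: orthogonal pixel steps
    count ``pixel_size_um`` and diagonal steps ``sqrt(2) * pixel_size_um``.
    Terminal spurs shorter than ``spur_length_um`` are pruned.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    skel = _sk_skeletonize(mask.astype(bool))
    g = _pixel_graph(skel, pixel_size_um)
    if spur_length_um > 0:
        _prune_spurs(g, spur_length_um)
    g.remove_nodes_from(list(nx.isolates(g)))
    segments = _contract_segments(g, pixel_size_um)
    return SkeletonGraph(g, segments, pixel_size_um)


def morphometry(
    graph: SkeletonGraph, n_neurons: int, well_id: str = ""
) -> MorphometryResult:
    """Per-well metrics normalized to the neuron count.

    ``n_neurons == 0`` yields a flagged (``valid=False``) result with NaN
    per-neuron quantities; such wells are excluded downstream.
    """
    total = graph.total_length_um
    n_seg = graph.n_segments
    if n_neurons < 1:
        return MorphometryResult(
            well_id, total, n_seg, n_neurons, np.nan, np.nan, np.nan, valid=False
        )
    return MorphometryResult(
        well_id=well_id,
        total_neurite_length_um=total,
        n_segments=n_seg,
        n_neurons=n_neurons,
        mean_length_per_neuron_um=total / n_neurons,
        segments_per_neuron=n_seg / n_neurons,
        mean_segment_length_um=total / n_seg if n_seg else 0.0,
    )


def measure_field(
    field: ImageField,
    soma_mask: SomaMask | None = None,
    well_id: str = "",
    n_neurons: int | None = None,
) -> tuple[SkeletonGraph, MorphometryResult]:
    """Convenience: segment, skeletonize and summarize one field."""
    binary = segment_neurites(field, soma_mask)
    graph = skeletonize(binary, field.pixel_size_um)
    if n_neurons is None:
        n_neurons = soma_mask.count if soma_mask is not None else 1
    return graph, morphometry(graph, n_neurons, well_id)
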