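"""Primary-root identification by maximum accumulated specific score.

A primary root appears in the reduced graph as the simple path between
two terminal vertices that maximises the accumulated specific score
sum(alpha_i).  With a handful of vertices the optimum is found by
exhaustive simple-path enumeration; larger graphs use best-first
branch-and-bound with the admissible upper bound "current score plus
the sum of all remaining positive edge scores", which can only prune
provably suboptimal partial paths, so both routes are exact.

Primary extraction is greedy: the best-scoring terminal-pair path is
accepted, its edges removed, and the search repeated until no remaining
path passes the primary gates (positive score, primary-calibre mean
thickness, minimum physical length).  Accepted paths are expanded via
edge provenance onto the original graph for trait measurement.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import SearchConfig
from .errors import InputError
from .root_graph import Edge, RootGraphStruct


@dataclass
class PrimaryRootPath:
    id: int
    terminal_vertices: tuple[int, int]
    #: reduced-graph edges in path order
    reduced_edges: list[Edge]
    #: ordered original-graph edge ids (provenance expansion)
    edge_sequence: list[int]
    #: ordered pixel chain over the whole path
    pixels: np.ndarray
    #: per-pixel thickness along the path (px)
    profile: np.ndarray
    total_score: float
    total_length: float
    vertex_sequence: list[int] = field(default_factory=list)

    @property
    def mean_thickness(self) -> float:
        return float(self.profile.mean())


def _path_from_edges(graph, va, edge_keys) -> tuple[list[Edge], list[int]]:
    edges = [graph.edges[k] for k in edge_keys]
    verts = [va]
    cur = va
    for e in edges:
        cur = e.other(cur)
        verts.append(cur)
    return edges, verts


def _assemble(graph: RootGraphStruct, va: int, vb: int, edge_keys, pid=0) -> PrimaryRootPath:
    edges, verts = _path_from_edges(graph, va, edge_keys)
    pieces, profs, orig = [], [], []
    cur = va
    for e in edges:
        p = e.oriented_path(cur)
        t = e.oriented_profile(cur)
        o = e.orig_ids if e.u == cur else list(reversed(e.orig_ids))
        if pieces:
            p, t = p[1:], t[1:]
        pieces.append(p)
        profs.append(t)
        orig.extend(o)
        cur = e.other(cur)
    return PrimaryRootPath(
        id=pid,
        terminal_vertices=(va, vb),
        reduced_edges=edges,
        edge_sequence=orig,
        pixels=np.vstack(pieces),
        profile=np.concatenate(profs),
        total_score=float(sum(e.score for e in edges)),
        total_length=float(sum(e.length for e in edges)),
        vertex_sequence=verts,
    )


def _best_exhaustive(graph: RootGraphStruct, va: int, vb: int):
    best_score, best_keys = -np.inf, None
    for ep in nx.all_simple_edge_paths(graph.g, va, vb):
        keys = [k for _, _, k in ep]
        s = sum(graph.edges[k].score for k in keys)
        if s > best_score:
            best_score, best_keys = s, keys
    return best_keys


def _best_branch_bound(graph: RootGraphStruct, va: int, vb: int):
    pos_total = graph.total_positive_score()
    best_score, best_keys = -np.inf, None
    # heap of (-upper_bound, tiebreak, score, vertex, visited, keys)
    counter = itertools.count()
    heap = [(-(pos_total), next(counter), 0.0, va, frozenset([va]), [])]
    while heap:
        neg_ub, _, score, cur, visited, keys = heapq.heappop(heap)
        if -neg_ub <= best_score:
            break  # no remaining state can beat the incumbent
        if cur == vb and keys:
            continue
        for _, nxt, k in graph.g.edges(cur, keys=True):
            if nxt in visited and nxt != vb:
                continue
            if nxt == va:
                continue
            e = graph.edges[k]
            ns = score + e.score
            if nxt == vb:
                if ns > best_score:
                    best_score, best_keys = ns, keys + [k]
                continue
            used_pos = sum(graph.edges[kk].score for kk in keys + [k]
                           if graph.edges[kk].score > 0)
            ub = ns + (pos_total - used_pos)
            if ub <= best_score:
                continue
            heapq.heappush(heap, (-ub, next(counter), ns, nxt,
                                  visited | {nxt}, keys + [k]))
    return best_keys


def best_path(
    graph: RootGraphStruct,
    v_a: int,
    v_b: int,
    config: SearchConfig | None = None,
) -> PrimaryRootPath | None:
    """Simple path between two vertices maximising the accumulated
    specific score, or None if they are disconnected."""
    cfg = config or SearchConfig()
    if v_a not in graph.vertices or v_b not in graph.vertices:
        raise InputError(f"vertices {v_a}, {v_b} not both in graph")
    if v_a == v_b:
        raise InputError("path endpoints must differ")
    if not nx.has_path(graph.g, v_a, v_b):
        return None
    if graph.n_vertices <= cfg.exhaustive_max_vertices:
        keys = _best_exhaustive(graph, v_a, v_b)
    else:
        keys = _best_branch_bound(graph, v_a, v_b)
    if keys is None:
        return None
    return _assemble(graph, v_a, v_b, keys)


def identify_primaries(
    reduced: RootGraphStruct,
    config: SearchConfig | None = None,
) -> list[PrimaryRootPath]:
    """Greedy extraction of edge-disjoint primary-root paths.

    Repeatedly evaluates the best path over all terminal-vertex pairs,
    accepts the highest-scoring one that looks like a primary root
    (positive score, mean thickness above theta_t, length above the
    minimum), removes its edges, and recurses.  Returns primaries sorted
    by score descending (the greedy order).
    """
    cfg = config or SearchConfig()
    work = reduced.copy()
    # a primary-like path must be primary-calibre on average: thicker than
    # the midpoint between the lateral and primary mixture means (theta_t
    # alone is ~2 lateral SDs, which almost any thin chain exceeds)
    theta = work.theta_t if work.theta_t is not None else 0.0
    if work.thin_cutoff is not None:
        theta = max(theta, work.thin_cutoff)
    out: list[PrimaryRootPath] = []
    while True:
        ends = work.end_vertices()
        best: PrimaryRootPath | None = None
        for va, vb in itertools.combinations(sorted(ends), 2):
            p = best_path(work, va, vb, cfg)
            if p is None:
                continue
            if p.total_score <= 0:
                continue
            if p.mean_thickness <= theta:
                continue
            if p.total_length < cfg.min_primary_length_px:
                continue
            if best is None or p.total_score > best.total_score:
                best = p
        if best is None:
            break
        best.id = len(out)
        out.append(best)
        for e in best.reduced_edges:
            work.remove_edge(e.id)
        for vid in [v for v in list(work.g.nodes) if work.g.degree(v) == 0]:
            work.remove_vertex(vid)
    # primaries are the plant's long axes: candidates far shorter than
    # the longest accepted path (wide laterals, overlap residues) are
    # demoted back to the lateral class
    if out:
        longest = max(p.total_length for p in out)
        out = [p for p in out
               if p.total_length >= cfg.min_relative_primary_length * longest]
        for i, p in enumerate(out):
            p.id = i
    return out
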