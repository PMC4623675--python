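"""Skeleton-to-graph conversion, edge scoring and graph reduction.

The skeleton is turned into an undirected multigraph G = (V, E):
vertices sit at skeleton pixels with one neighbour (root tips / broken
ends) or three or more neighbours (junctions, with 8-adjacent junction
pixels merged into a single vertex); edges are the pixel chains between
them, each carrying its ordered pixel path, chain-code length l_i and
per-pixel thickness profile.

Each edge receives a *specific score*

    alpha_i = (Tbar_i - theta_t) * l_i

where Tbar_i is the edge's mean thickness and theta_t = 2*sigma_1 is
twice the spread of the lateral component of the thickness mixture.
Long thick (primary-like) segments score strongly positive; thin
segments score near zero or negative.  The score drives both the graph
reduction rules and the primary-root path search.

Reduction applies, iteratively to a fixed point: self-loop removal,
removal of negative-score terminal edges (Rule 1), removal of terminal
edges whose score is smallest at their junction (Rule 3), parallel-edge
reduction to the best-scoring member (Rule 2), and contraction of
degree-2 vertices with score recomputation over the merged profile
(Rule 4).  Overlap junctions are then cleaned by pruning lateral-calibre
minimum-score edges (Rule 5); an unconditional variant is reserved for
graphs still above the search cap, since it can break a primary root in
two (the event is logged).  Every reduced edge records the original
edges it covers, so accepted primary paths can be expanded back onto
the original graph exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage as ndi

from .config import GraphConfig
from .errors import StateError
from .thickness import DistanceMap, ThicknessMixture, diameters
from .thinning import NEIGHBORS8, Skeleton, chain_length, neighbor_count


@dataclass
class Vertex:
    id: int
    pos: tuple[int, int]
    kind: str  # "end" | "junction" | "isolated"
    #: all skeleton pixels merged into this vertex (junction clusters)
    pixels: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Edge:
    id: int
    u: int  # vertex id at path[0]
    v: int  # vertex id at path[-1]
    path: np.ndarray  # (n,2) ordered pixel chain, u-end first
    profile: np.ndarray  # per-pixel thickness (diameter, px)
    length: float = 0.0
    score: float | None = None
    #: original edge ids covered by this (possibly merged) edge, in order
    orig_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path)
        self.profile = np.asarray(self.profile, float)
        if not self.length:
            self.length = max(chain_length(self.path), 0.5)
        if not self.orig_ids:
            self.orig_ids = [self.id]

    @property
    def mean_thickness(self) -> float:
        return float(self.profile.mean())

    def other(self, vid: int) -> int:
        return self.v if vid == self.u else self.u

    def oriented_path(self, from_vertex: int) -> np.ndarray:
        return self.path if from_vertex == self.u else self.path[::-1]

    def oriented_profile(self, from_vertex: int) -> np.ndarray:
        return self.profile if from_vertex == self.u else self.profile[::-1]


class RootGraphStruct:
    """Vertices plus scored edges, backed by a networkx MultiGraph."""

    def __init__(self) -> None:
        self.vertices: dict[int, Vertex] = {}
        self.edges: dict[int, Edge] = {}
        self.g = nx.MultiGraph()
        self.theta_t: float | None = None
        #: midpoint between the two mixture means; edges thinner than this
        #: are lateral-calibre (used by the overlap rule)
        self.thin_cutoff: float | None = None
        #: fitted mean primary thickness (px); overlap ribbons exceed it
        self.primary_mean: float | None = None
        self.log: list[str] = []
        self._next_vid = 0
        self._next_eid = 0

    # -- construction -----------------------------------------------------
    def add_vertex(self, pos, kind, pixels=None) -> int:
        vid = self._next_vid
        self._next_vid += 1
        self.vertices[vid] = Vertex(vid, tuple(pos), kind, list(pixels or [tuple(pos)]))
        self.g.add_node(vid)
        return vid

    def add_edge(self, u, v, path, profile, orig_ids=None) -> int:
        eid = self._next_eid
        self._next_eid += 1
        e = Edge(eid, u, v, path, profile, orig_ids=list(orig_ids or []))
        self.edges[eid] = e
        self.g.add_edge(u, v, key=eid)
        return eid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self.g.remove_edge(e.u, e.v, key=eid)

    def remove_vertex(self, vid: int) -> None:
        self.vertices.pop(vid)
        self.g.remove_node(vid)

    # -- queries ----------------------------------------------------------
    def degree(self, vid: int) -> int:
        return self.g.degree(vid)

    def incident_edges(self, vid: int) -> list[Edge]:
        return [self.edges[k] for _, _, k in self.g.edges(vid, keys=True)]

    def end_vertices(self) -> list[int]:
        return [v for v in self.g.nodes if self.g.degree(v) == 1]

    @property
    def n_vertices(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def total_positive_score(self) -> float:
        return sum(e.score for e in self.edges.values() if e.score and e.score > 0)

    def copy(self) -> "RootGraphStruct":
        out = RootGraphStruct()
        out.vertices = {k: Vertex(v.id, v.pos, v.kind, list(v.pixels)) for k, v in self.vertices.items()}
        out.edges = {
            k: Edge(e.id, e.u, e.v, e.path.copy(), e.profile.copy(), e.length,
                    e.score, list(e.orig_ids))
            for k, e in self.edges.items()
        }
        out.g = self.g.copy()
        out.theta_t = self.theta_t
        out.thin_cutoff = self.thin_cutoff
        out.primary_mean = self.primary_mean
        out.log = list(self.log)
        out._next_vid = self._next_vid
        out._next_eid = self._next_eid
        return out

    @property
    def provenance(self) -> dict[int, list[int]]:
        """Reduced-edge id -> ordered original edge ids."""
        return {eid: list(e.orig_ids) for eid, e in self.edges.items()}


# ---------------------------------------------------------------------------
# graph construction from a skeleton
# ---------------------------------------------------------------------------

def build_graph(skeleton: Skeleton | np.ndarray, dm: DistanceMap) -> RootGraphStruct:
    """Trace the skeleton into vertices (ends, junctions) and pixel-path
    edges with per-pixel thickness from the distance map."""
    skel = skeleton.skel if isinstance(skeleton, Skeleton) else np.asarray(skeleton, bool)
    G = RootGraphStruct()
    if not skel.any():
        return G
    cnt = neighbor_count(skel)
    H, W = skel.shape

    vertex_of: dict[tuple[int, int], int] = {}

    # junction clusters: 8-connected groups of >=3-neighbour pixels
    jmask = cnt >= 3
    if jmask.any():
        lbl, n = ndi.label(jmask, structure=np.ones((3, 3)))
        for comp in range(1, n + 1):
            pts = [tuple(p) for p in np.argwhere(lbl == comp)]
            centroid = np.mean(pts, axis=0)
            pos = min(pts, key=lambda p: (abs(p[0] - centroid[0]) + abs(p[1] - centroid[1]), p))
            vid = G.add_vertex(pos, "junction", pts)
            for p in pts:
                vertex_of[p] = vid

    # endpoints
    for p in map(tuple, np.argwhere(cnt == 1)):
        vertex_of[p] = G.add_vertex(p, "end")

    # isolated single pixels
    for p in map(tuple, np.argwhere((cnt == 0) & skel)):
        G.add_vertex(p, "isolated")

    def _profile(path: np.ndarray) -> np.ndarray:
        return diameters(dm, path)

    visited = np.zeros_like(skel)
    seen_direct: set[frozenset] = set()

    def neighbors(p):
        for dr, dc in NEIGHBORS8:
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < H and 0 <= q[1] < W and skel[q]:
                yield q

    # trace chains starting at each vertex pixel
    for vp, vid in list(vertex_of.items()):
        for q in neighbors(vp):
            if q in vertex_of:
                qvid = vertex_of[q]
                if qvid == vid:
                    continue  # intra-cluster adjacency
                key = frozenset((vp, q))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                path = np.array([vp, q])
                G.add_edge(vid, qvid, path, _profile(path))
                continue
            if visited[q]:
                continue
            # walk the degree-2 chain
            path = [vp, q]
            visited[q] = True
            prev, cur = vp, q
            end_vid = None
            while True:
                nxt = None
                for r in neighbors(cur):
                    if r == prev:
                        continue
                    if r in vertex_of:
                        nxt = r
                        end_vid = vertex_of[r]
                        break
                    if not visited[r]:
                        nxt = r
                        break
                if nxt is None:
                    # dead end without an endpoint marker (should not occur)
                    end_vid = vertex_of.get(cur)
                    break
                path.append(nxt)
                if end_vid is not None:
                    break
                visited[nxt] = True
                prev, cur = cur, nxt
            if end_vid is None:
                continue
            arr = np.array(path)
            G.add_edge(vid, end_vid, arr, _profile(arr))

    _merge_blob_junctions(G)

    # pure cycles: leftover unvisited degree-2 pixels form closed rings
    leftover = skel & ~visited.astype(bool)
    for p in vertex_of:
        leftover[p] = False
    if leftover.any():
        lbl, n = ndi.label(leftover, structure=np.ones((3, 3)))
        for comp in range(1, n + 1):
            pts = [tuple(x) for x in np.argwhere(lbl == comp)]
            start = min(pts)
            vid = G.add_vertex(start, "junction")
            # walk the ring
            path = [start]
            prev, cur = None, start
            while True:
                nxt = None
                for r in neighbors(cur):
                    if r != prev and (lbl[r] == comp if r != start else True):
                        if r == start and len(path) > 2:
                            nxt = r
                            break
                        if r != start and r not in path[-3:]:
                            nxt = r
                            break
                if nxt is None or nxt == start:
                    break
                path.append(nxt)
                prev, cur = cur, nxt
                if len(path) > len(pts) + 1:
                    break
            path.append(start)
            arr = np.array(path)
            G.add_edge(vid, vid, arr, _profile(arr))
            for q in pts:
                visited[q] = True

    return G


def _contract_bridge(G: RootGraphStruct, e: Edge) -> None:
    """Merge e's two endpoint vertices into one; e's pixels join the
    merged junction neighbourhood."""
    keep, drop = e.u, e.v
    G.remove_edge(e.id)
    for other in list(G.incident_edges(drop)):
        G.g.remove_edge(other.u, other.v, key=other.id)
        if other.u == drop:
            other.u = keep
        if other.v == drop:
            other.v = keep
        G.g.add_edge(other.u, other.v, key=other.id)
    vu, vv = G.vertices[keep], G.vertices[drop]
    vu.pixels = list(vu.pixels) + list(vv.pixels) + [tuple(p) for p in e.path]
    G.remove_vertex(drop)


def _merge_blob_junctions(G: RootGraphStruct) -> None:
    """Collapse junction pairs linked by an edge shorter than its own
    local diameter into a single vertex.

    Where two roots cross, the overlap blob skeletonises into two nearby
    junctions joined by a sub-diameter bridge; leaving the bridge as a
    real edge lets one root's path consume it and disconnect the other.
    The bridge pixels become part of the merged junction neighbourhood.
    """
    changed = True
    while changed:
        changed = False
        for eid, e in list(G.edges.items()):
            if eid not in G.edges or e.u == e.v:
                continue
            vu, vv = G.vertices[e.u], G.vertices[e.v]
            if vu.kind != "junction" or vv.kind != "junction":
                continue
            # overlap blobs (including shallow-angle crossings) separate
            # their two junctions by up to ~2 local diameters
            if e.length >= 2.0 * float(e.profile.max()):
                continue
            _contract_bridge(G, e)
            changed = True
            break


def _rule_ribbon(G: RootGraphStruct) -> bool:
    """Contract overlap ribbons: where two roots cross at a shallow angle
    they run stacked for tens of pixels and skeletonise into one segment
    roughly twice as thick as a single primary.  Such a segment belongs
    to both roots at once, so it is absorbed into a single shared vertex
    rather than being consumed by one path."""
    if G.primary_mean is None:
        return False
    thin_cut = G.thin_cutoff if G.thin_cutoff is not None else 0.0
    changed = False
    progress = True
    while progress:
        progress = False
        for eid, e in list(G.edges.items()):
            if eid not in G.edges or e.u == e.v:
                continue
            if G.degree(e.u) < 3 or G.degree(e.v) < 3:
                continue
            # a ribbon (two roots stacked) is thicker than the single-root
            # legs meeting it, and two primary-calibre legs diverge at
            # each of its ends; comparing against the local legs rather
            # than a global mean keeps segments of a thicker-than-average
            # root from being mistaken for ribbons
            leg_sets = [
                [o for o in G.incident_edges(v)
                 if o.id != e.id and o.mean_thickness >= thin_cut]
                for v in (e.u, e.v)
            ]
            legs = leg_sets[0] + leg_sets[1]
            if not legs:
                continue
            max_leg = max(o.mean_thickness for o in legs)
            diverging = all(len(s) >= 2 for s in leg_sets)
            is_ribbon = (
                e.mean_thickness > 1.2 * max_leg
                or (diverging and e.mean_thickness > 1.05 * max_leg)
            )
            if not is_ribbon:
                continue
            _contract_bridge(G, e)
            G.log.append(f"overlap ribbon edge {eid} contracted "
                         f"(Tbar={e.mean_thickness:.1f})")
            progress = True
            changed = True
            break
    return changed


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_edges(
    graph: RootGraphStruct,
    mixture: ThicknessMixture,
    config: GraphConfig | None = None,
) -> RootGraphStruct:
    """Set theta_t = 2*sigma_1 from the lateral mixture component and
    score every edge as alpha = (Tbar - theta_t) * l (in place)."""
    cfg = config or GraphConfig()
    if mixture.K < 2:
        raise StateError("edge scoring needs a fitted K=2 thickness mixture")
    graph.theta_t = mixture.theta_t(from_variance=cfg.theta_from_variance)
    graph.thin_cutoff = float(0.5 * (mixture.means[0] + mixture.means[1]))
    graph.primary_mean = float(mixture.means[1])
    for e in graph.edges.values():
        e.score = (e.mean_thickness - graph.theta_t) * e.length
    return graph


# ---------------------------------------------------------------------------
# reduction rules
# ---------------------------------------------------------------------------

def _remove_isolated_vertices(G: RootGraphStruct) -> None:
    for vid in [v for v in G.g.nodes if G.g.degree(v) == 0]:
        G.remove_vertex(vid)


def _rule_loops(G: RootGraphStruct) -> bool:
    """Self-loops and hair-scale 2-cycles are soil/root-hair artefacts."""
    changed = False
    for eid, e in list(G.edges.items()):
        if e.u == e.v:
            G.remove_edge(eid)
            changed = True
    # tiny 2-cycles: parallel pairs whose combined length is below the
    # local diameter; drop the weaker member (keeps connectivity)
    seen: set[tuple[int, int]] = set()
    for eid, e in list(G.edges.items()):
        if eid not in G.edges:
            continue
        pair = tuple(sorted((e.u, e.v)))
        if pair in seen:
            continue
        seen.add(pair)
        parallels = [G.edges[k] for _, _, k in G.g.edges(e.u, keys=True)
                     if tuple(sorted((G.edges[k].u, G.edges[k].v))) == pair]
        if len(parallels) == 2:
            combined = sum(p.length for p in parallels)
            local_diam = max(p.profile.max() for p in parallels)
            if combined < local_diam:
                weaker = min(parallels, key=lambda p: (p.score, -p.id))
                G.remove_edge(weaker.id)
                changed = True
    return changed


def _rule1(G: RootGraphStruct) -> bool:
    """Negative-score edges hanging off end vertices are laterals."""
    changed = False
    for vid in list(G.end_vertices()):
        if vid not in G.vertices or G.degree(vid) != 1:
            continue
        (e,) = G.incident_edges(vid)
        if e.score is not None and e.score < 0:
            G.remove_edge(e.id)
            G.remove_vertex(vid)
            changed = True
    return changed


def _rule3(G: RootGraphStruct, protect_len: float = 120.0) -> bool:
    """Terminal edges scoring lowest among their junction's edges are
    (possibly positive-score) laterals near primary ends.

    Long primary-calibre terminal edges are never removed: near root
    crossings a genuine primary half can transiently score lowest at the
    shared junction, and the rule targets (short, possibly thick) near-tip
    laterals, not whole root halves.
    """
    changed = False
    cutoff = G.thin_cutoff if G.thin_cutoff is not None else np.inf
    for vid in list(G.end_vertices()):
        if vid not in G.vertices or G.degree(vid) != 1:
            continue
        (e,) = G.incident_edges(vid)
        if e.mean_thickness >= cutoff and e.length >= protect_len:
            continue
        j = e.other(vid)
        neigh = G.incident_edges(j)
        if len(neigh) < 3:
            # no competing branch at the junction: the terminal edge is
            # the continuation of the same root (Rule 4 merges it)
            continue
        # the comparison is against a root that continues through the
        # junction; where every edge is terminal (e.g. two primaries
        # crossing) the weakest edge is a genuine root half, not a lateral
        def _terminal(x):
            o = x.other(j)
            return G.degree(o) == 1
        if all(_terminal(x) for x in neigh):
            continue
        smallest = min(neigh, key=lambda x: (x.score, -x.id))
        if smallest.id == e.id:
            G.remove_edge(e.id)
            G.remove_vertex(vid)
            changed = True
    return changed


def _rule2(G: RootGraphStruct) -> bool:
    """Among parallel edges keep only the best one.

    Primary-calibre members always beat lateral-calibre ones (a long
    lateral detour can out-score a short thick primary connector purely
    through its length); within a calibre class the maximum score wins.
    """
    changed = False
    cutoff = G.thin_cutoff if G.thin_cutoff is not None else np.inf
    seen: set[tuple[int, int]] = set()
    for eid, e in list(G.edges.items()):
        if eid not in G.edges or e.u == e.v:
            continue
        pair = tuple(sorted((e.u, e.v)))
        if pair in seen:
            continue
        seen.add(pair)
        parallels = [G.edges[k] for _, _, k in G.g.edges(e.u, keys=True)
                     if tuple(sorted((G.edges[k].u, G.edges[k].v))) == pair]
        if len(parallels) > 1:
            best = max(
                parallels,
                key=lambda x: (x.mean_thickness >= cutoff, x.score, -x.id),
            )
            for p in parallels:
                if p.id != best.id:
                    G.remove_edge(p.id)
                    changed = True
    return changed


def _merge_at(G: RootGraphStruct, vid: int) -> bool:
    """Rule 4 contraction of one degree-2 vertex."""
    inc = G.incident_edges(vid)
    if len(inc) != 2 or inc[0].id == inc[1].id:
        return False
    e1, e2 = inc
    a, b = e1.other(vid), e2.other(vid)
    p1 = e1.oriented_path(a)          # a .. vid
    p2 = e2.oriented_path(vid)        # vid .. b
    t1 = e1.oriented_profile(a)
    t2 = e2.oriented_profile(vid)
    path = np.vstack([p1, p2[1:]])
    prof = np.concatenate([t1, t2[1:]])
    orig1 = e1.orig_ids if e1.u == a else list(reversed(e1.orig_ids))
    orig2 = e2.orig_ids if e2.u == vid else list(reversed(e2.orig_ids))
    orig = list(orig1) + list(orig2)
    G.remove_edge(e1.id)
    G.remove_edge(e2.id)
    G.remove_vertex(vid)
    eid = G.add_edge(a, b, path, prof, orig_ids=orig)
    e = G.edges[eid]
    if G.theta_t is not None:
        e.score = (e.mean_thickness - G.theta_t) * e.length
    return True


def _rule4(G: RootGraphStruct) -> bool:
    changed = False
    for vid in list(G.g.nodes):
        if vid in G.vertices and G.degree(vid) == 2:
            if _merge_at(G, vid):
                changed = True
    return changed


def _rule5_thin(G: RootGraphStruct) -> bool:
    """Overlap cleanup: at any >=3-edge junction prune the smallest-score
    edge provided it is lateral-calibre (thinner than the mixture-means
    midpoint).  This is what removes lateral 'bridges' created by roots
    crossing on the scanner bed."""
    changed = False
    cutoff = G.thin_cutoff if G.thin_cutoff is not None else np.inf
    for vid in list(G.g.nodes):
        if vid not in G.vertices or G.degree(vid) < 3:
            continue
        thin_inc = [e for e in G.incident_edges(vid)
                    if e.mean_thickness < cutoff]
        if not thin_inc:
            continue
        smallest = min(thin_inc, key=lambda x: (x.score, -x.id))
        G.remove_edge(smallest.id)
        changed = True
    return changed


def _rule5_forced(G: RootGraphStruct, cap: int) -> bool:
    """Unconditional overlap pruning, only above the search cap.  Known
    hazard: can break one primary root into two pieces."""
    changed = False
    while G.n_vertices > cap:
        busy = [v for v in G.g.nodes if G.g.degree(v) >= 3]
        if not busy:
            break
        vid = max(busy, key=lambda v: G.g.degree(v))
        inc = G.incident_edges(vid)
        smallest = min(inc, key=lambda x: (x.score, -x.id))
        G.remove_edge(smallest.id)
        G.log.append(f"rule5(forced): removed edge {smallest.id} at vertex {vid}; "
                     "a primary root may have been split")
        changed = True
        _remove_isolated_vertices(G)
        _rule4(G)
    return changed


def prune(graph: RootGraphStruct, config: GraphConfig | None = None) -> RootGraphStruct:
    """Reduce a scored graph to its primary-root backbone.

    Returns a new reduced graph whose edges carry provenance
    (``orig_ids``) back to ``graph``; the input is left untouched.
    """
    cfg = config or GraphConfig()
    if any(e.score is None for e in graph.edges.values()) and graph.n_edges:
        raise StateError("prune requires a scored graph (call score_edges first)")
    G = graph.copy()
    G.log = []

    def sweep() -> bool:
        changed = False
        changed |= _rule_loops(G)
        changed |= _rule1(G)
        changed |= _rule3(G, cfg.protect_primary_len_px)
        changed |= _rule2(G)
        changed |= _rule4(G)
        _remove_isolated_vertices(G)
        return changed

    for _ in range(cfg.max_sweeps):
        if not sweep():
            break
    if _rule_ribbon(G):
        while sweep():
            pass
    for _ in range(cfg.max_sweeps):
        changed = _rule5_thin(G)
        _remove_isolated_vertices(G)
        while sweep():
            pass
        if not changed:
            break
    if G.n_vertices > cfg.rule5_vertex_cap:
        _rule5_forced(G, cfg.rule5_vertex_cap)
        while sweep():
            pass
        _remove_isolated_vertices(G)
    return G
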