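"""Per-root trait quantification and lateral grouping.

Geometric traits treat the root locally as a cylinder whose diameter is
the perpendicular width w(s) at arc position s: a path increment dl at
width w contributes pi*w*dl to surface area and pi*w^2*dl/4 to volume.
Lengths are chain-code arc lengths (1 per axial step, sqrt(2) per
diagonal step) converted to millimetres via dpi.

Lateral roots are the non-primary part of the original graph: each
connected subtree is assigned to the primary root it attaches to, its
tip count is the number of end vertices it contains, and per-primary
linear densities (tips per cm, lateral length per primary length) are
reported.  Subtrees attaching to several primaries (root overlap) are
split edge-by-edge by path distance to the nearest attachment point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .image_io import TRAIT_COLUMNS, px_to_mm
from .primary_search import PrimaryRootPath
from .root_graph import RootGraphStruct


@dataclass
class LateralGroup:
    primary_id: int
    lateral_edges: list[int] = field(default_factory=list)  # original edge ids
    lateral_count: int = 0  # number of lateral tips
    total_lateral_length_px: float = 0.0
    split_from_overlap: bool = False


@dataclass
class TraitReport:
    per_primary: pd.DataFrame
    plant_summary: dict
    unassigned_length_px: float = 0.0
    unassigned_edges: list[int] = field(default_factory=list)


def measure_root(
    path: np.ndarray, profile: np.ndarray, dpi: float
) -> tuple[float, float, float, float]:
    """Cylinder-model measurement of one root.

    Returns (length_mm, mean_diameter_mm, surface_area_mm2, volume_mm3)
    for an ordered pixel path with per-pixel diameter profile (px).
    """
    path = np.asarray(path, float)
    profile = np.asarray(profile, float)
    if len(path) == 0:
        raise InputError("empty root path")
    if len(path) == 1:
        d_mm = px_to_mm(profile[0], dpi)
        return 0.0, d_mm, 0.0, 0.0
    d = np.diff(path, axis=0)
    dl = np.hypot(d[:, 0], d[:, 1])
    w = 0.5 * (profile[:-1] + profile[1:])
    mm = 25.4 / dpi
    length_mm = float(dl.sum()) * mm
    area_mm2 = float(np.sum(np.pi * w * dl)) * mm * mm
    vol_mm3 = float(np.sum(np.pi * w**2 * dl / 4.0)) * mm**3
    mean_d_mm = float(profile.mean()) * mm
    return length_mm, mean_d_mm, area_mm2, vol_mm3


def _junction_filtered_profile(
    primary: PrimaryRootPath, graph: RootGraphStruct, exclusion_radii: float
) -> np.ndarray:
    """Thickness samples away from junctions: the distance transform is
    inflated where roots meet, so samples within one local radius of a
    junction vertex are excluded from diameter statistics."""
    if exclusion_radii <= 0:
        return primary.profile
    junctions = [
        graph.vertices[v].pos
        for v in primary.vertex_sequence
        if v in graph.vertices and graph.vertices[v].kind == "junction"
    ]
    # also junctions that sit mid-path (vertices of the original graph)
    if not junctions:
        return primary.profile
    pts = primary.pixels.astype(float)
    keep = np.ones(len(pts), bool)
    for (jr, jc) in junctions:
        d = np.hypot(pts[:, 0] - jr, pts[:, 1] - jc)
        local_r = 0.5 * (primary.profile[np.argmin(d)] + 1.0)
        keep &= d > exclusion_radii * local_r
    if keep.sum() < max(3, 0.1 * len(pts)):
        return primary.profile
    return primary.profile[keep]


def assign_laterals(
    original_graph: RootGraphStruct,
    primaries: list[PrimaryRootPath],
) -> tuple[list[LateralGroup], LateralGroup]:
    """Assign every non-primary edge of the original graph to the primary
    root its subtree attaches to.

    Returns (groups, unassigned) where ``unassigned`` collects
    free-floating debris components that touch no primary.
    """
    primary_edge_ids: set[int] = set()
    edge_owner: dict[int, int] = {}
    for p in primaries:
        for eid in p.edge_sequence:
            primary_edge_ids.add(eid)
            edge_owner[eid] = p.id

    # vertices lying on each primary
    vertex_owner: dict[int, set[int]] = {}
    for p in primaries:
        for e_id in p.edge_sequence:
            e = original_graph.edges[e_id]
            for v in (e.u, e.v):
                vertex_owner.setdefault(v, set()).add(p.id)

    groups = {p.id: LateralGroup(primary_id=p.id) for p in primaries}
    unassigned = LateralGroup(primary_id=-1)

    # residual graph = original minus primary edges
    H = nx.MultiGraph()
    H.add_nodes_from(original_graph.g.nodes)
    for eid, e in original_graph.edges.items():
        if eid not in primary_edge_ids:
            H.add_edge(e.u, e.v, key=eid, length=e.length)

    deg_orig = {v: original_graph.g.degree(v) for v in original_graph.g.nodes}

    for comp in nx.connected_components(H):
        eids = {k for u, v, k in H.subgraph(comp).edges(keys=True)}
        if not eids:
            continue
        attach: dict[int, set[int]] = {}  # primary id -> attachment vertices
        for v in comp:
            for pid in vertex_owner.get(v, ()):  # vertex on a primary path
                attach.setdefault(pid, set()).add(v)
        # lateral tips: end vertices of the ORIGINAL graph inside this
        # component that are not on a primary
        tips = [v for v in comp if deg_orig[v] == 1 and v not in vertex_owner]
        total_len = sum(original_graph.edges[k].length for k in eids)

        if not attach:
            unassigned.lateral_edges.extend(sorted(eids))
            unassigned.total_lateral_length_px += total_len
            unassigned.lateral_count += len(tips)
            continue
        if len(attach) == 1:
            (pid,) = attach.keys()
            g = groups[pid]
            g.lateral_edges.extend(sorted(eids))
            g.total_lateral_length_px += total_len
            g.lateral_count += len(tips)
            continue
        # overlap: subtree touches several primaries -> split by path
        # distance to the nearest attachment vertex
        sub = H.subgraph(comp)
        dist_by_pid = {}
        for pid, sources in attach.items():
            dist_by_pid[pid] = nx.multi_source_dijkstra_path_length(
                sub, sources, weight="length"
            )
        def nearest_pid(v):
            best_pid, best_d = None, np.inf
            for pid in sorted(dist_by_pid):
                d = dist_by_pid[pid].get(v, np.inf)
                if d < best_d:
                    best_pid, best_d = pid, d
            return best_pid
        for k in sorted(eids):
            e = original_graph.edges[k]
            mid_d = {pid: 0.5 * (dist_by_pid[pid].get(e.u, np.inf)
                                 + dist_by_pid[pid].get(e.v, np.inf))
                     for pid in dist_by_pid}
            pid = min(sorted(mid_d), key=lambda q: mid_d[q])
            groups[pid].lateral_edges.append(k)
            groups[pid].total_lateral_length_px += e.length
            groups[pid].split_from_overlap = True
        for v in tips:
            pid = nearest_pid(v)
            if pid is None:
                unassigned.lateral_count += 1
            else:
                groups[pid].lateral_count += 1
        original_graph.log.append(
            f"lateral subtree split between primaries {sorted(attach)} at overlap"
        )
    return [groups[p.id] for p in primaries], unassigned


def laterals_per_cm(
    group: LateralGroup, primary_length_cm: float, dpi: float = 600.0
) -> tuple[float, float]:
    """(lateral tips per cm of primary, lateral length / primary length).

    The second value is the dimensionless average linear lateral density
    by length: total lateral length borne by the primary divided by the
    primary's own length.
    """
    if not primary_length_cm > 0:
        raise InputError("primary length must be positive")
    density = group.lateral_count / primary_length_cm
    lat_len_cm = px_to_mm(group.total_lateral_length_px, dpi) / 10.0
    return density, lat_len_cm / primary_length_cm


def compile_report(
    original_graph: RootGraphStruct,
    primaries: list[PrimaryRootPath],
    groups: list[LateralGroup],
    unassigned: LateralGroup,
    dpi: float,
    junction_exclusion_radii: float = 1.0,
) -> TraitReport:
    """Assemble the per-primary trait table and plant summary."""
    rows = []
    for p, g in zip(primaries, groups):
        length_mm, _, area, vol = measure_root(p.pixels, p.profile, dpi)
        prof = _junction_filtered_profile(p, original_graph, junction_exclusion_radii)
        mm = 25.4 / dpi
        lat_len_mm = px_to_mm(g.total_lateral_length_px, dpi)
        length_cm = length_mm / 10.0
        rows.append(
            {
                "root_id": p.id,
                "length_mm": length_mm,
                "mean_diameter_mm": float(prof.mean()) * mm,
                "min_diameter_mm": float(prof.min()) * mm,
                "max_diameter_mm": float(prof.max()) * mm,
                "surface_area_mm2": area,
                "volume_mm3": vol,
                "lateral_count": g.lateral_count,
                "total_lateral_length_mm": lat_len_mm,
                "laterals_per_cm": g.lateral_count / length_cm if length_cm > 0 else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    summary = {
        "primary_count": len(primaries),
        "lateral_count": int(sum(g.lateral_count for g in groups)),
        "total_primary_length_mm": float(df["length_mm"].sum()) if len(df) else 0.0,
        "total_lateral_length_mm": float(df["total_lateral_length_mm"].sum()) if len(df) else 0.0,
        "total_surface_area_mm2": float(df["surface_area_mm2"].sum()) if len(df) else 0.0,
        "total_volume_mm3": float(df["volume_mm3"].sum()) if len(df) else 0.0,
        "unassigned_count": unassigned.lateral_count,
        "unassigned_length_mm": px_to_mm(unassigned.total_lateral_length_px, dpi),
    }
    return TraitReport(
        per_primary=df,
        plant_summary=summary,
        unassigned_length_px=unassigned.total_lateral_length_px,
        unassigned_edges=list(unassigned.lateral_edges),
    )
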