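"""End-to-end analysis: scan image -> trait report.

Stages: segmentation -> distance transform -> thinning -> thickness
mixture -> graph construction + scoring -> reduction -> primary-root
search -> lateral grouping -> trait table.  Each intermediate layer is
kept on the result object for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DegenerateInputError
from .image_io import ScanImage
from .primary_search import PrimaryRootPath, identify_primaries
from .root_graph import RootGraphStruct, build_graph, prune, score_edges
from .segmentation import RootMask, segment
from .thickness import (
    DistanceMap,
    ThicknessMixture,
    build_histogram,
    distance_transform,
    fit_mixture,
)
from .thinning import Skeleton, thin
from .traits import LateralGroup, TraitReport, assign_laterals, compile_report


@dataclass
class PipelineResult:
    mask: RootMask
    distance_map: DistanceMap
    skeleton: Skeleton
    mixture: ThicknessMixture | None
    original_graph: RootGraphStruct
    reduced_graph: RootGraphStruct
    primaries: list[PrimaryRootPath]
    lateral_groups: list[LateralGroup]
    unassigned: LateralGroup
    report: TraitReport
    log: list[str] = field(default_factory=list)

    @property
    def primary_count(self) -> int:
        return len(self.primaries)

    @property
    def lateral_count(self) -> int:
        """Lateral tips attached to identified primaries."""
        return int(sum(g.lateral_count for g in self.lateral_groups))

    @property
    def total_lateral_tips(self) -> int:
        """All non-primary root tips in the scan, including tips in
        components whose attachment could not be established."""
        return self.lateral_count + int(self.unassigned.lateral_count)


def analyze_mask(mask: RootMask, config: PipelineConfig | None = None) -> PipelineResult:
    """Run every stage after segmentation on a binary root mask."""
    cfg = config or DEFAULT_CONFIG
    dm = distance_transform(mask)
    skeleton = thin(mask, dm, cfg.thinning)
    graph = build_graph(skeleton, dm)
    mixture = None
    if skeleton.skel.any():
        hist = build_histogram(dm, skeleton)
        try:
            mixture = fit_mixture(hist, K=2)
            score_edges(graph, mixture, cfg.graph)
        except DegenerateInputError:
            # single-calibre scene: score against a zero threshold
            for e in graph.edges.values():
                e.score = e.mean_thickness * e.length
            graph.theta_t = 0.0
    reduced = prune(graph, cfg.graph)
    primaries = identify_primaries(reduced, cfg.search)
    # re-anchor primary ids and expand onto the original graph
    groups, unassigned = assign_laterals(graph, primaries)
    report = compile_report(
        graph, primaries, groups, unassigned, mask.dpi,
        cfg.junction_exclusion_radii,
    )
    return PipelineResult(
        mask=mask,
        distance_map=dm,
        skeleton=skeleton,
        mixture=mixture,
        original_graph=graph,
        reduced_graph=reduced,
        primaries=primaries,
        lateral_groups=groups,
        unassigned=unassigned,
        report=report,
        log=list(reduced.log) + list(graph.log),
    )


def analyze_image(image: ScanImage, config: PipelineConfig | None = None) -> PipelineResult:
    """Full pipeline from a grayscale scan."""
    cfg = config or DEFAULT_CONFIG
    mask = segment(image, cfg.segmentation)
    return analyze_mask(mask, cfg)
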