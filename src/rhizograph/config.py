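"""Pipeline configuration.

Every tunable that the analysis exposes lives here with its default.
Defaults are chosen for 600–800 dpi flatbed scans of washed cereal roots
(dark roots on a light, possibly graded, background) and are documented
in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SegmentationConfig:
    """Knobs of the edge + RANSAC background-surface segmentation."""

    #: polynomial degree of the background surface (2 -> 6 coefficients)
    surface_degree: int = 2
    #: RANSAC minimal sample size (>= number of surface coefficients)
    ransac_min_samples: int = 6
    #: RANSAC iterations
    ransac_iters: int = 200
    #: residual tolerance = this factor x median absolute residual of an
    #: initial global fit (auto-derived, no manual threshold)
    ransac_tol_factor: float = 2.0
    #: RANSAC RNG seed (deterministic by default)
    ransac_seed: int = 0
    #: foreground margin: pixel is root if darker than surface - k*sigma
    foreground_k: float = 3.0
    #: hysteresis edge-detector percentiles for low/high gradient thresholds
    edge_low_pct: float = 90.0
    edge_high_pct: float = 98.0
    #: speck suppression: drop components with area < (dpi/600)^2 * this
    #: (px); 32 px at 600 dpi is a disk of ~0.27 mm diameter, smaller than
    #: any plausible root fragment at the 0.338 mm lateral/primary scale
    min_component_area_600dpi: float = 32.0


@dataclass
class ThinningConfig:
    #: terminal branch pruned iff chain length < factor*DT(junction) + extra
    spur_factor: float = 1.5
    #: additive allowance for boundary-speck radius (px)
    spur_extra_px: float = 3.0
    #: disable to obtain the plain (noise-sensitive) thinning baseline
    prune_spurs: bool = True


@dataclass
class GraphConfig:
    #: read theta_t = 2*sigma_1 from the SD (False) or variance (True) of
    #: the lateral mixture component
    theta_from_variance: bool = False
    #: unconditional smallest-score pruning at busy junctions only kicks in
    #: above this vertex count (known to risk breaking a primary in two)
    rule5_vertex_cap: int = 80
    #: maximum pruning sweeps (fixed point is normally reached much earlier)
    max_sweeps: int = 100
    #: terminal edges that are primary-calibre AND at least this long are
    #: protected from end-edge pruning (they are root halves at crossings,
    #: not near-tip laterals)
    protect_primary_len_px: float = 120.0


@dataclass
class SearchConfig:
    #: exhaustive simple-path enumeration below this vertex count
    exhaustive_max_vertices: int = 12
    #: minimum accepted primary path length (px); rejects soil-speck
    #: fragments and residual overlap-blob segments (120 px = 5 mm at
    #: 600 dpi, far below any real primary root)
    min_primary_length_px: float = 120.0
    #: a candidate much shorter than the plant's longest primary is a
    #: stub (wide lateral, overlap residue), not a primary axis
    min_relative_primary_length: float = 0.25


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    thinning: ThinningConfig = field(default_factory=ThinningConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    #: thickness samples closer than this many local radii to a junction
    #: are excluded from a root's diameter statistics (DT inflates there)
    junction_exclusion_radii: float = 1.0


DEFAULT_CONFIG = PipelineConfig()
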