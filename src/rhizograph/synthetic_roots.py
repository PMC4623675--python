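"""Ground-truthed synthetic root-scan generator.

Emulates flatbed scans of washed, spread cereal roots: a handful of
thick, smoothly curved primary roots running down the tray; thinner
lateral roots branching off them at a specified linear density; a light
background with an illumination gradient; particulate "soil" specks, a
stated fraction of which touch root boundaries (the hard case for
skeleton-based tip counting); and occasional forced primary-root
crossings (root overlap).

The binary truth mask is rendered without anti-aliasing so ground truth
is exact, while the intensity image is separately blurred and noised so
segmentation is exercised realistically.  Laterals attach only within
the basal 8-85% of a primary's arc length: the apical region of a young
cereal root (elongation zone) is developmentally bare of laterals.

Every random choice is drawn from one seeded generator, so a given
(spec, seed) pair reproduces the scene bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .image_io import ScanImage


@dataclass
class SceneSpec:
    """Parameters of one synthetic root scene (defaults: barley-like
    scan at 600 dpi)."""

    n_primaries: int = 5
    primary_width_px: tuple[float, float] = (9.0, 0.5)  # mean, sd
    lateral_width_px: tuple[float, float] = (4.0, 0.4)
    laterals_per_cm: float = 1.5
    lateral_length_px: tuple[float, float] = (130.0, 35.0)
    #: (base intensity, (gradient_row, gradient_col)) of the background
    background: tuple[float, tuple[float, float]] = (0.85, (0.05, 0.08))
    #: (speck count, (min radius, max radius) px, fraction attached to roots)
    noise: tuple[int, tuple[float, float], float] = (150, (1.0, 2.0), 0.5)
    overlap_probability: float = 0.3
    dpi: float = 600.0
    seed: int = 0
    height_px: int = 2200
    width_px: int = 1700
    root_intensity: float = 0.25
    #: laterals attach within this fraction range of the primary arc length
    branch_zone: tuple[float, float] = (0.08, 0.85)

    def validate(self) -> None:
        if self.primary_width_px[0] <= self.lateral_width_px[0]:
            raise InputError(
                "primary width mean must exceed lateral width mean "
                f"({self.primary_width_px[0]} <= {self.lateral_width_px[0]})"
            )
        if self.n_primaries < 0 or self.dpi <= 0:
            raise InputError("invalid scene spec")


@dataclass
class RootTruth:
    centerline: np.ndarray  # (n,2) float (row, col), fine sampling
    width_px: float
    length_px: float
    attach_s: float | None = None  # arc position on parent (laterals)


@dataclass
class SceneTruth:
    """Exact ground truth of a rendered scene."""

    primaries: list[RootTruth]
    #: laterals grouped per primary (same order as ``primaries``)
    laterals: list[list[RootTruth]]
    specks: list[tuple[int, int, float]]  # (row, col, radius)
    mask: np.ndarray  # rendered foreground incl. specks
    root_mask: np.ndarray  # roots only
    n_crossings: int = 0

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def lateral_counts(self) -> list[int]:
        return [len(ls) for ls in self.laterals]

    @property
    def total_lateral_count(self) -> int:
        return int(sum(self.lateral_counts))

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Re-render the foreground from the stored geometry; equals
        ``mask`` exactly (truth-consistency invariant)."""
        m = np.zeros(shape, bool)
        for p, lats in zip(self.primaries, self.laterals):
            _stamp(m, p.centerline, p.width_px)
            for l in lats:
                _stamp(m, l.centerline, l.width_px)
        for r, c, rad in self.specks:
            _stamp(m, np.array([[r, c]], float), 2 * rad + 1)
        return m


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr**2 + dc**2 <= radius**2 + 1e-9
    return dr[keep], dc[keep]


def _stamp(mask: np.ndarray, centerline: np.ndarray, width_px: float) -> None:
    """Paint pixels within (width-1)/2 of the (rounded) centerline."""
    H, W = mask.shape
    radius = max((width_px - 1.0) / 2.0, 0.0)
    offr, offc = _disk_offsets(radius)
    pts = np.unique(np.round(centerline).astype(int), axis=0)
    rows = (pts[:, 0][:, None] + offr[None, :]).ravel()
    cols = (pts[:, 1][:, None] + offc[None, :]).ravel()
    ok = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    mask[rows[ok], cols[ok]] = True


def _polyline_length(p: np.ndarray) -> float:
    return float(np.hypot(*np.diff(p, axis=0).T).sum())


def _primary_centerline(rng, H, W, x0, x1) -> np.ndarray:
    """Smooth low-curvature curve from top to bottom margin: linear drift
    from x0 to x1 plus sinusoidal wiggles vanishing at the ends."""
    y = np.arange(40.0, H - 40.0, 0.7)
    s = (y - y[0]) / (y[-1] - y[0])
    x = (1 - s) * x0 + s * x1
    for k in (1, 2, 3):
        amp = rng.uniform(-45, 45) / k
        phase = rng.uniform(0, 2 * np.pi)
        x = x + amp * np.sin(np.pi * k * s + phase) * np.sin(np.pi * s)
    x = np.clip(x, 25, W - 25)
    return np.column_stack([y, x])


def _lateral_centerline(rng, start, tangent, length, H, W) -> np.ndarray:
    """Gently curving branch of given arc length starting at ``start``."""
    # diverge from the parent: emergence angle well off the parent axis
    # and curvature too gentle to bend back into it over a lateral's length
    side = rng.choice([-1.0, 1.0])
    ang0 = np.arctan2(tangent[0], tangent[1]) + side * rng.uniform(0.7, 1.4)
    curvature = rng.uniform(-0.0025, 0.0025)
    n = max(int(length / 0.7), 4)
    ang = ang0 + curvature * 0.7 * np.arange(n)
    steps = 0.7 * np.column_stack([np.sin(ang), np.cos(ang)])
    pts = start + np.cumsum(steps, axis=0)
    ok = (pts[:, 0] > 6) & (pts[:, 0] < H - 6) & (pts[:, 1] > 6) & (pts[:, 1] < W - 6)
    stop = np.argmin(ok) if not ok.all() else len(pts)
    return np.vstack([start, pts[: max(stop, 3)]])


def generate_scene(spec: SceneSpec) -> tuple[ScanImage, SceneTruth]:
    """Render one synthetic scene; returns the scan and its exact truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px

    # primary endpoints: evenly spaced columns with jitter; forced
    # crossings swap the bottom targets of an adjacent pair
    n = spec.n_primaries
    truth_primaries: list[RootTruth] = []
    truth_laterals: list[list[RootTruth]] = [[] for _ in range(n)]
    n_crossings = 0
    if n:
        slots = np.linspace(0.12, 0.88, n) * W
        x_top = slots + rng.uniform(-30, 30, n)
        x_bot = slots + rng.uniform(-60, 60, n)
        if n >= 2 and rng.uniform() < spec.overlap_probability:
            i = int(rng.integers(0, n - 1))
            x_bot[[i, i + 1]] = x_bot[[i + 1, i]]
            n_crossings += 1

    root_mask = np.zeros((H, W), bool)
    px_per_cm = spec.dpi / 2.54

    for i in range(n):
        width = max(rng.normal(*spec.primary_width_px), spec.lateral_width_px[0] + 2)
        line = _primary_centerline(rng, H, W, x_top[i], x_bot[i])
        length = _polyline_length(line)
        truth_primaries.append(RootTruth(line, width, length))

    for p in truth_primaries:
        _stamp(root_mask, p.centerline, p.width_px)

    # occupancy samples for tip-visibility checks: (point, radius) of all
    # drawn roots, plus the tips that must stay uncovered.  A lateral whose
    # distal tip ends up inside another root's footprint has no countable
    # tip (not even for a manual count), so tips are kept visible:
    # retract the tip out of occupied ground, redraw, or drop the lateral.
    from scipy.spatial import cKDTree

    occ_pts = [p.centerline[::2] for p in truth_primaries]
    occ_rad = [np.full(len(q), (p.width_px - 1) / 2)
               for q, p in zip(occ_pts, truth_primaries)]
    tips: list[tuple[np.ndarray, float]] = [
        (p.centerline[-1], (p.width_px - 1) / 2) for p in truth_primaries
    ]

    def tip_clear(lat_line, lat_r, own_start_n=8):
        """Index up to which the lateral may extend so its tip stays
        clear of other roots; -1 if no prefix works."""
        if not occ_pts:
            return len(lat_line) - 1
        tree = cKDTree(np.vstack(occ_pts))
        rmax = max(r.max() for r in occ_rad)
        clearance = lat_r + rmax + 2.5
        # walk back from the distal end to the first clear point
        for idx in range(len(lat_line) - 1, own_start_n, -1):
            d, _ = tree.query(lat_line[idx])
            if d > clearance:
                return idx
        return -1

    for i, prim in enumerate(truth_primaries):
        line, width, length = prim.centerline, prim.width_px, prim.length_px
        seglen = np.hypot(*np.diff(line, axis=0).T)
        arclen = np.concatenate([[0.0], np.cumsum(seglen)])
        zone = (spec.branch_zone[0] * length, spec.branch_zone[1] * length)
        expected = spec.laterals_per_cm * (zone[1] - zone[0]) / px_per_cm
        n_lat = int(rng.poisson(expected))
        attach_ss = np.sort(rng.uniform(zone[0], zone[1], n_lat))
        for s_attach in attach_ss:
            idx = int(np.searchsorted(arclen, s_attach))
            idx = min(max(idx, 1), len(line) - 2)
            start = line[idx]
            tangent = line[idx + 1] - line[idx - 1]
            tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
            # floor of 3 px (~0.13 mm at 600 dpi): thinner laterals are
            # below what a flatbed scan resolves
            lat_w = float(np.clip(rng.normal(*spec.lateral_width_px), 3.0, width - 2.0))
            lat_r = (lat_w - 1) / 2
            lat_len = float(max(rng.normal(*spec.lateral_length_px), 40.0))
            for _attempt in range(4):
                lat_line = _lateral_centerline(rng, start, tangent, lat_len, H, W)
                # keep clear of previously drawn tips along the whole body
                if tips:
                    tp = np.array([t[0] for t in tips])
                    tr = np.array([t[1] for t in tips])
                    d = np.hypot(
                        lat_line[:, None, 0] - tp[None, :, 0],
                        lat_line[:, None, 1] - tp[None, :, 1],
                    )
                    bad = (d < (tr + lat_r + 2.5)).any(axis=1)
                    if bad.any():
                        cut = int(np.argmax(bad))
                        lat_line = lat_line[:max(cut, 0)]
                if len(lat_line) < 8:
                    continue
                end = tip_clear(lat_line, lat_r)
                if end > 0:
                    lat_line = lat_line[: end + 1]
                    if _polyline_length(lat_line) >= 30.0:
                        break
            else:
                continue  # no visible-tip placement found: drop the lateral
            truth_laterals[i].append(
                RootTruth(lat_line, lat_w, _polyline_length(lat_line), float(s_attach))
            )
            _stamp(root_mask, lat_line, lat_w)
            occ_pts.append(lat_line[::2])
            occ_rad.append(np.full(len(occ_pts[-1]), lat_r))
            tips.append((lat_line[-1], lat_r))

    # soil specks: some attached to root boundaries, some free
    n_specks, (r_lo, r_hi), attach_frac = spec.noise
    specks: list[tuple[int, int, float]] = []
    all_roots = truth_primaries + [l for ls in truth_laterals for l in ls]
    fg = root_mask.copy()
    for k in range(n_specks):
        rad = rng.uniform(r_lo, r_hi)
        if all_roots and rng.uniform() < attach_frac:
            root = all_roots[int(rng.integers(0, len(all_roots)))]
            j = int(rng.integers(0, len(root.centerline)))
            pt = root.centerline[j]
            if j + 1 < len(root.centerline):
                t = root.centerline[j + 1] - root.centerline[j]
            else:
                t = root.centerline[j] - root.centerline[j - 1]
            t = t / (np.linalg.norm(t) + 1e-12)
            normal = np.array([-t[1], t[0]]) * rng.choice([-1.0, 1.0])
            center = pt + normal * ((root.width_px - 1) / 2.0 + rad - 0.5)
        else:
            center = np.array([rng.uniform(10, H - 10), rng.uniform(10, W - 10)])
        r, c = int(round(center[0])), int(round(center[1]))
        if not (0 <= r < H and 0 <= c < W):
            continue
        specks.append((r, c, rad))
        _stamp(fg, np.array([[r, c]], float), 2 * rad + 1)

    truth = SceneTruth(
        primaries=truth_primaries,
        laterals=truth_laterals,
        specks=specks,
        mask=fg,
        root_mask=root_mask,
        n_crossings=n_crossings,
    )

    # intensity image: graded light background, dark roots, blur + noise
    base, (g_r, g_c) = spec.background
    rr, cc = np.mgrid[0:H, 0:W]
    img = base + g_r * (rr / max(H - 1, 1) - 0.5) + g_c * (cc / max(W - 1, 1) - 0.5)
    img = img.astype(float)
    img[fg] = spec.root_intensity
    from scipy import ndimage as ndi

    img = ndi.gaussian_filter(img, 0.8)
    img = img + rng.normal(0.0, 0.02, img.shape)
    img = np.clip(img, 0.0, 1.0)
    scan = ScanImage(pixels=img, dpi=spec.dpi, source_path=f"synthetic:seed={spec.seed}")
    return scan, truth


def default_spec(seed: int = 0, **overrides) -> SceneSpec:
    """The default study conditions with a given seed."""
    return SceneSpec(seed=seed, **overrides)
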