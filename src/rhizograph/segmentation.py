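"""Root/background segmentation without manual thresholds.

Flatbed scans of washed roots have a light but rarely homogeneous
background (illumination gradients, moisture film).  A fixed global
threshold therefore misclassifies either the faint laterals or the
background gradient.  Instead:

1. detect edges (every root boundary pixel is an edge pixel, though not
   conversely);
2. fit a smooth low-order polynomial surface to the pixels *away* from
   edges with RANSAC, so dark outliers (roots, soil) cannot drag the fit;
3. classify as foreground every pixel darker than the fitted background
   surface by more than ``k`` times the robust residual spread.

The only remaining knobs are statistical (percentiles, k), not image-
specific thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, morphology

from .config import SegmentationConfig
from .errors import DegenerateInputError
from .image_io import ScanImage


@dataclass
class RootMask:
    """Binary foreground mask (True = root) with inherited resolution."""

    mask: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


@dataclass
class BackgroundSurface:
    """A fitted 2-D polynomial intensity surface with its RANSAC stats."""

    coefficients: np.ndarray
    degree: int
    shape: tuple[int, int]
    inlier_fraction: float
    residual_sigma: float

    def evaluate(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        A = _design_matrix(rows, cols, self.degree, self.shape)
        return A @ self.coefficients

    def evaluate_full(self) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return self.evaluate(rr.ravel(), cc.ravel()).reshape(self.shape)


def _design_matrix(rows, cols, degree: int, shape) -> np.ndarray:
    """Bivariate polynomial design matrix on coordinates scaled to [-1,1]
    (conditioning; raw pixel indices make the normal equations singular)."""
    r = 2.0 * np.asarray(rows, float) / max(shape[0] - 1, 1) - 1.0
    c = 2.0 * np.asarray(cols, float) / max(shape[1] - 1, 1) - 1.0
    terms = [np.ones_like(r)]
    for total in range(1, degree + 1):
        for i in range(total + 1):
            terms.append(r ** (total - i) * c**i)
    return np.stack(terms, axis=1)


def detect_edges(image: ScanImage, config: SegmentationConfig | None = None) -> np.ndarray:
    """Boolean raster of locally-maximal gradient pixels.

    Canny-style: Gaussian-smoothed gradient magnitude, non-maximum
    suppression along the gradient, hysteresis with thresholds taken from
    gradient-magnitude percentiles, so no user threshold is required.
    """
    cfg = config or SegmentationConfig()
    px = image.pixels
    gy, gx = np.gradient(ndi.gaussian_filter(px, 1.0))
    gmag = np.hypot(gx, gy)
    if gmag.max() <= 1e-12:  # constant image
        return np.zeros_like(px, dtype=bool)
    nz = gmag[gmag > 1e-12]
    # percentile thresholds with a floor relative to the strongest edge:
    # on a quantised or noise-free background the percentiles collapse to
    # the ambient ripple and everything would become an edge
    gmax = float(gmag.max())
    low = max(np.percentile(nz, cfg.edge_low_pct), 0.05 * gmax)
    high = max(np.percentile(nz, cfg.edge_high_pct), 0.15 * gmax)
    return feature.canny(px, sigma=1.0, low_threshold=low, high_threshold=high)


def fit_background(
    image: ScanImage,
    edges: np.ndarray,
    config: SegmentationConfig | None = None,
) -> BackgroundSurface:
    """RANSAC fit of a smooth background surface to off-edge pixels.

    Candidate samples are pixels well away from any edge (edges dilated
    by the expected root half-width scale).  Repeatedly fit the surface
    on a random minimal subset, count inliers within an automatically
    derived residual tolerance, keep the consensus model and refit on all
    its inliers.
    """
    cfg = config or SegmentationConfig()
    px = image.pixels
    shape = px.shape
    n_params = (cfg.surface_degree + 1) * (cfg.surface_degree + 2) // 2

    # stay clear of boundaries: dilate edges by ~ a root half-width
    halfwidth = max(3, int(round(image.dpi / 600.0 * 6)))
    far = ~ndi.binary_dilation(edges, iterations=halfwidth) if edges.any() else np.ones(shape, bool)
    need = max(n_params, cfg.ransac_min_samples)
    if far.sum() < 4 * need and edges.any():
        far = ~edges  # edge dilation covered the frame: relax
    if far.sum() < need:
        far = np.ones(shape, bool)
    rows, cols = np.nonzero(far)
    if rows.size < need:
        raise DegenerateInputError(
            f"only {rows.size} candidate background pixels for "
            f"{n_params}-parameter surface"
        )

    # subsample on a coarse spatial grid for speed and spatial coverage
    max_samples = 4000
    if rows.size > max_samples:
        rng0 = np.random.default_rng(cfg.ransac_seed)
        idx = rng0.choice(rows.size, size=max_samples, replace=False)
        rows, cols = rows[idx], cols[idx]
    vals = px[rows, cols]
    A = _design_matrix(rows, cols, cfg.surface_degree, shape)

    # auto tolerance from a global least-squares pre-fit: the MAD about
    # the median residual tracks the inlier spread even when the pre-fit
    # itself is dragged by dark outliers
    coef0, *_ = np.linalg.lstsq(A, vals, rcond=None)
    resid0 = vals - A @ coef0
    mad = 1.4826 * np.median(np.abs(resid0 - np.median(resid0)))
    tol = max(cfg.ransac_tol_factor * mad, 1e-4)

    rng = np.random.default_rng(cfg.ransac_seed)
    m = max(cfg.ransac_min_samples, n_params)
    best_inliers: np.ndarray | None = None
    best_count = -1
    for _ in range(cfg.ransac_iters):
        pick = rng.choice(rows.size, size=m, replace=False)
        try:
            coef, *_ = np.linalg.lstsq(A[pick], vals[pick], rcond=None)
        except np.linalg.LinAlgError:  # pragma: no cover - lstsq rarely fails
            continue
        resid = np.abs(vals - A @ coef)
        inl = resid <= tol
        count = int(inl.sum())
        if count > best_count:
            best_count = count
            best_inliers = inl
    assert best_inliers is not None
    if best_count < n_params:  # no consensus at all: fall back to global fit
        best_inliers = np.ones(rows.size, bool)
    coef, *_ = np.linalg.lstsq(A[best_inliers], vals[best_inliers], rcond=None)
    resid = vals[best_inliers] - A[best_inliers] @ coef
    sigma = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
    sigma = max(sigma, 1e-4)
    return BackgroundSurface(
        coefficients=coef,
        degree=cfg.surface_degree,
        shape=shape,
        inlier_fraction=best_count / rows.size,
        residual_sigma=sigma,
    )


def segment(image: ScanImage, config: SegmentationConfig | None = None) -> RootMask:
    """Full automatic segmentation: edge detection, RANSAC background
    surface, margin thresholding and sub-speck suppression."""
    cfg = config or SegmentationConfig()
    edges = detect_edges(image, cfg)
    surface = fit_background(image, edges, cfg)
    bg = surface.evaluate_full()
    margin = cfg.foreground_k * surface.residual_sigma
    detect = image.pixels < (bg - margin)
    # refine the boundary: the statistical margin flags every pixel that
    # is provably darker than background, which on a blurred scan reaches
    # ~1-2 px outside the true root.  Re-threshold at the midpoint between
    # the background surface and the detected foreground's core intensity
    # (both estimated from the image, so still no manual threshold).
    fg = detect
    if detect.any():
        # isodata-style iteration: the first detection set is contaminated
        # by the bright blur halo, so re-estimate the foreground core and
        # threshold until the midpoint stabilises
        px = image.pixels
        for _ in range(20):
            fg_core = float(np.median(px[fg]))
            new_fg = px < np.minimum(0.5 * (bg + fg_core), bg - margin)
            if not new_fg.any() or np.array_equal(new_fg, fg):
                fg = new_fg if new_fg.any() else fg
                break
            fg = new_fg
    # only components far smaller than any root fragment are dropped
    min_area = max(1, int(round((image.dpi / 600.0) ** 2 * cfg.min_component_area_600dpi)))
    if fg.any() and min_area > 1:
        lbl, n = ndi.label(fg, structure=np.ones((3, 3)))
        if n:
            areas = np.bincount(lbl.ravel())
            keep = areas >= min_area
            keep[0] = False
            fg = keep[lbl]
    return RootMask(mask=fg, dpi=image.dpi)
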