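"""Root thickness estimation and the two-component thickness mixture.

The Euclidean distance transform of the root mask gives, at every medial
axis (skeleton) point, the perpendicular distance to the root boundary;
twice that distance (minus one, under the pixel-centre convention)
estimates the local root *diameter*.  Pooling the diameters of all
medial-axis points into a histogram yields a characteristically bimodal
distribution — thin lateral roots and thick primary roots — which is
modelled as a K=2 Gaussian mixture

    P(chi) = sum_k W_k N(chi | mu_k, sigma_k).

The mixture parameters are estimated by minimising the mean squared
error between the normalised histogram H(chi)/N_m and P(chi); the fitted
lateral component supplies the score threshold theta_t = 2*sigma_1 used
by the graph stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares

from .errors import DegenerateInputError, InputError
from .segmentation import RootMask

SIGMA_FLOOR = 0.25  # px; 1-px bins cannot support narrower components


@dataclass
class DistanceMap:
    """Exact Euclidean distance (px) to the nearest background pixel
    centre; zero on background."""

    dist: np.ndarray

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)


@dataclass
class ThicknessHistogram:
    """Histogram of medial-axis diameters, unit (1 px) bins."""

    bin_centers: np.ndarray
    counts: np.ndarray
    n_medial: int
    samples: np.ndarray = field(default=None, repr=False)  # raw diameters


@dataclass
class ThicknessMixture:
    """K-component Gaussian mixture over medial thickness, canonically
    ordered so component 1 (laterals) has the smaller mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    mse: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.means = np.asarray(self.means, float)
        self.sds = np.asarray(self.sds, float)

    @property
    def K(self) -> int:
        return len(self.means)

    def pdf(self, chi: np.ndarray) -> np.ndarray:
        return mixture_pdf(chi, self.weights, self.means, self.sds)

    def theta_t(self, from_variance: bool = False) -> float:
        """Score threshold: twice the spread of the lateral component."""
        s1 = self.sds[0]
        return float(2.0 * (s1**2 if from_variance else s1))


def mixture_pdf(chi, weights, means, sds) -> np.ndarray:
    chi = np.asarray(chi, float)[..., None]
    w = np.asarray(weights, float)
    mu = np.asarray(means, float)
    sd = np.asarray(sds, float)
    comp = w / (sd * np.sqrt(2 * np.pi)) * np.exp(-((chi - mu) ** 2) / (2 * sd**2))
    return comp.sum(axis=-1)


def mixture_bin_mass(centers, weights, means, sds, width: float = 1.0) -> np.ndarray:
    """Mixture probability mass integrated over unit bins.

    With 1-px bins and lateral spreads of ~0.5 px, evaluating the density
    at the bin centre misstates the bin's share badly; the integrated
    mass is the correct discretisation of the density-matching objective.
    """
    from scipy.special import erf

    c = np.asarray(centers, float)[..., None]
    w = np.asarray(weights, float)
    mu = np.asarray(means, float)
    sd = np.asarray(sds, float)
    z_hi = (c + width / 2 - mu) / (sd * np.sqrt(2))
    z_lo = (c - width / 2 - mu) / (sd * np.sqrt(2))
    comp = w * 0.5 * (erf(z_hi) - erf(z_lo))
    return comp.sum(axis=-1)


def distance_transform(mask: RootMask | np.ndarray) -> DistanceMap:
    """Exact Euclidean distance transform of the foreground.

    Distance is measured between pixel centres, so an isolated foreground
    pixel has distance 1 to its nearest background neighbour.
    """
    fg = mask.mask if isinstance(mask, RootMask) else np.asarray(mask, bool)
    if not fg.any():
        return DistanceMap(np.zeros(fg.shape))
    # pad so foreground touching the image border still sees background
    padded = np.pad(fg, 1)
    d = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    return DistanceMap(d)


def thickness_at(dm: DistanceMap, medial_point: tuple[int, int]) -> float:
    """Local root diameter at a medial point: ``2*dist - 1`` px.

    The -1 accounts for the pixel-centre convention: the centre row of a
    w-px-wide ribbon lies (w+1)/2 px from the nearest background centre,
    so 2d-1 recovers w exactly.
    """
    r, c = medial_point
    d = dm.dist[r, c]
    if d <= 0:
        raise InputError(f"point {medial_point!r} is background")
    return 2.0 * float(d) - 1.0


def diameters(dm: DistanceMap, points: np.ndarray) -> np.ndarray:
    """Vectorised :func:`thickness_at` for an (n,2) array of medial points."""
    pts = np.asarray(points)
    d = dm.dist[pts[:, 0], pts[:, 1]]
    if np.any(d <= 0):
        raise InputError("some points are background")
    return 2.0 * d - 1.0


def build_histogram(dm: DistanceMap, skeleton) -> ThicknessHistogram:
    """One diameter sample per skeleton pixel, unit bins."""
    skel = getattr(skeleton, "skel", skeleton)
    pts = np.argwhere(skel)
    if len(pts) == 0:
        raise DegenerateInputError("empty skeleton: no medial-axis points")
    samples = diameters(dm, pts)
    lo, hi = int(np.floor(samples.min())), int(np.ceil(samples.max()))
    edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
    counts, _ = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ThicknessHistogram(
        bin_centers=centers, counts=counts, n_medial=len(pts), samples=samples
    )


def _two_means_init(samples: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic K-means-style split of the 1-D samples (K<=2)."""
    s = np.sort(samples)
    if K == 1:
        mu = np.array([s.mean()])
        sd = np.array([max(s.std(), SIGMA_FLOOR)])
        return np.array([1.0]), mu, sd
    # init split at midpoint of range, iterate assignment/means
    cut = 0.5 * (s[0] + s[-1])
    for _ in range(50):
        left = s[s <= cut]
        right = s[s > cut]
        if len(left) == 0 or len(right) == 0:
            break
        new_cut = 0.5 * (left.mean() + right.mean())
        if abs(new_cut - cut) < 1e-9:
            break
        cut = new_cut
    left = s[s <= cut]
    right = s[s > cut]
    if len(left) == 0 or len(right) == 0:
        left = right = s
    w = np.array([len(left), len(right)], float)
    w /= w.sum()
    mu = np.array([left.mean(), right.mean()])
    sd = np.array([max(left.std(), SIGMA_FLOOR), max(right.std(), SIGMA_FLOOR)])
    return w, mu, sd


def fit_mixture(hist: ThicknessHistogram, K: int = 2) -> ThicknessMixture:
    """Least-squares fit of the K-component mixture density to the
    normalised histogram.

    The objective is the mean squared error between ``H(chi)/N_m`` and
    ``P(chi)`` over the occupied bins, minimised with a trust-region
    nonlinear least-squares solver; initialisation is a deterministic
    two-means split of the raw samples, so the fit is reproducible.
    Components are returned ordered by increasing mean (ties broken by
    descending weight).
    """
    centers = np.asarray(hist.bin_centers, float)
    counts = np.asarray(hist.counts, float)
    if hist.n_medial <= 0 or counts.sum() <= 0:
        raise DegenerateInputError("empty thickness histogram")
    n_distinct = int((counts > 0).sum())
    if n_distinct < K:
        raise DegenerateInputError(
            f"{n_distinct} distinct thickness bins cannot support K={K}"
        )
    # pad with empty bins so broad components are penalised for mass
    # spilled outside the observed thickness range
    pad = np.arange(1, 4)
    centers = np.concatenate([centers.min() - pad[::-1], centers, centers.max() + pad])
    counts = np.concatenate([np.zeros(3), counts, np.zeros(3)])
    target = counts / float(hist.n_medial)

    samples = hist.samples
    if samples is None:  # rebuild approximate samples from the histogram
        samples = np.repeat(hist.bin_centers, hist.counts.astype(int))
    samples = np.asarray(samples, float)

    lo_mu, hi_mu = centers.min() - 1.0, centers.max() + 1.0

    def residuals(p):
        w = p[:K]
        mu = p[K : 2 * K]
        sd = p[2 * K :]
        return mixture_bin_mass(centers, w, mu, sd) - target

    def split_init(cut):
        left, right = samples[samples <= cut], samples[samples > cut]
        if len(left) == 0 or len(right) == 0:
            return None
        w = np.array([len(left), len(right)], float) / len(samples)
        mu = np.array([left.mean(), right.mean()])
        sd = np.array([max(left.std(), SIGMA_FLOOR), max(right.std(), SIGMA_FLOOR)])
        return w, mu, sd

    # multi-start: the 2-means split, a two-mode histogram split and a
    # percentile split.  A single 2-means init can lump a dominant thick
    # mode with the thin class when the two peaks are unbalanced.
    inits = [_two_means_init(samples, K)]
    if K == 2:
        hc, hb = np.asarray(hist.counts, float), np.asarray(hist.bin_centers, float)
        order = np.argsort(hc)[::-1]
        m1 = hb[order[0]]
        for o in order[1:]:
            if abs(hb[o] - m1) >= 3.0 and hc[o] > 0:
                valley = 0.5 * (m1 + hb[o])
                cand = split_init(valley)
                if cand:
                    inits.append(cand)
                break
        cand = split_init(0.5 * (np.percentile(samples, 20) + np.percentile(samples, 90)))
        if cand:
            inits.append(cand)

    lb = np.concatenate([np.zeros(K), np.full(K, lo_mu), np.full(K, SIGMA_FLOOR)])
    ub = np.concatenate([np.full(K, 2.0), np.full(K, hi_mu), np.full(K, np.inf)])
    best = None
    for w0, mu0, sd0 in inits:
        p0 = np.clip(np.concatenate([w0, mu0, sd0]), lb + 1e-9, None)
        sol = least_squares(residuals, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    sol = best
    w, mu, sd = sol.x[:K], sol.x[K : 2 * K], sol.x[2 * K :]
    # canonical ordering: by mean ascending, ties by weight descending
    order = np.lexsort((-w, mu))
    w, mu, sd = w[order], mu[order], sd[order]
    mse = float(np.mean(residuals(np.concatenate([w, mu, sd])) ** 2))
    return ThicknessMixture(weights=w, means=mu, sds=sd, mse=mse)


def plot_thickness_fit(
    hist: ThicknessHistogram, mixture: ThicknessMixture, path: str
) -> None:
    """Save a diagnostic plot of the thickness histogram with the fitted
    two-peak mixture density overlaid (lateral and primary classes)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.bin_centers, hist.counts / hist.n_medial, width=0.9,
           color="0.8", edgecolor="0.5", label="medial thickness")
    chi = np.linspace(hist.bin_centers.min() - 2, hist.bin_centers.max() + 2, 400)
    ax.plot(chi, mixture.pdf(chi), "k-", lw=1.5, label="fitted mixture")
    for k, name in enumerate(["lateral", "primary"][: mixture.K]):
        ax.plot(chi, mixture_pdf(chi, [mixture.weights[k]], [mixture.means[k]],
                                 [mixture.sds[k]]), "--", lw=1,
                label=f"{name} (mu={mixture.means[k]:.1f}px)")
    ax.set_xlabel("root thickness (px)")
    ax.set_ylabel("fraction of medial-axis points")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def fit_mixture_em(samples: np.ndarray, K: int = 2, seed: int = 0) -> ThicknessMixture:
    """Sample-likelihood EM fit (cross-check utility for the default
    least-squares density fit), via scikit-learn's GaussianMixture."""
    from sklearn.mixture import GaussianMixture

    x = np.asarray(samples, float).reshape(-1, 1)
    gm = GaussianMixture(n_components=K, random_state=seed, n_init=3).fit(x)
    w = gm.weights_
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    order = np.lexsort((-w, mu))
    return ThicknessMixture(weights=w[order], means=mu[order], sds=sd[order])
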