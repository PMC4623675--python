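"""Distance transform, medial thickness and the two-component mixture."""

import numpy as np
import pytest

from rhizograph.errors import DegenerateInputError, InputError
from rhizograph.segmentation import RootMask
from rhizograph.thickness import (
    ThicknessHistogram,
    build_histogram,
    distance_transform,
    fit_mixture,
    fit_mixture_em,
    mixture_pdf,
    thickness_at,
)
from rhizograph.thinning import thin

from conftest import random_blob_mask


def brute_force_dt(mask: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-background search, the independent oracle."""
    fg = np.argwhere(mask)
    # background includes the implicit border outside the image
    H, W = mask.shape
    padded = np.pad(mask, 1)
    bg = np.argwhere(~padded) - 1
    out = np.zeros(mask.shape)
    for r, c in fg:
        d2 = ((bg - (r, c)) ** 2).sum(axis=1)
        out[r, c] = np.sqrt(d2.min())
    return out


class TestDistanceTransform:
    def test_empty_mask(self):
        dm = distance_transform(np.zeros((5, 5), bool))
        assert np.all(dm.dist == 0)

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert distance_transform(m).dist[2, 2] == 1.0

    def test_stripe_center(self):
        # 7-px-wide horizontal stripe: centre row is 4 px from background
        m = np.zeros((17, 40), bool)
        m[5:12] = True
        dm = distance_transform(m)
        assert np.all(dm.dist[8, 5:35] == 4.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((rng.integers(4, 32), rng.integers(4, 32))) > 0.6
        dm = distance_transform(m)
        assert np.allclose(dm.dist, brute_force_dt(m))

    def test_lipschitz(self):
        rng = np.random.default_rng(7)
        m = random_blob_mask(rng)
        d = distance_transform(m).dist
        assert np.all(np.abs(np.diff(d, axis=0)) <= 1.0 + 1e-9)
        assert np.all(np.abs(np.diff(d, axis=1)) <= 1.0 + 1e-9)


class TestThicknessAt:
    def test_stripe_diameter(self):
        m = np.zeros((17, 40), bool)
        m[5:12] = True
        dm = distance_transform(m)
        assert thickness_at(dm, (8, 20)) == 7.0

    def test_single_line(self):
        m = np.zeros((5, 20), bool)
        m[2] = True
        dm = distance_transform(m)
        assert thickness_at(dm, (2, 10)) == 1.0

    def test_background_raises(self):
        dm = distance_transform(np.zeros((5, 5), bool))
        with pytest.raises(InputError):
            thickness_at(dm, (1, 1))


class TestHistogram:
    def test_single_stripe(self):
        m = np.zeros((17, 110), bool)
        m[5:12, 3:107] = True
        dm = distance_transform(m)
        sk = thin(RootMask(m, 600), dm)
        hist = build_histogram(dm, sk)
        assert hist.n_medial == int(sk.skel.sum())
        assert hist.counts.sum() == hist.n_medial
        # dominant bin at diameter 7
        assert hist.bin_centers[np.argmax(hist.counts)] == 7.0

    def test_bimodal_two_stripes(self):
        m = np.zeros((40, 120), bool)
        m[5:8, 5:115] = True  # width 3
        m[20:29, 5:115] = True  # width 9
        dm = distance_transform(m)
        sk = thin(RootMask(m, 600), dm)
        hist = build_histogram(dm, sk)
        top2 = hist.bin_centers[np.argsort(hist.counts)[-2:]]
        assert set(top2) == {3.0, 9.0}

    def test_empty_skeleton_raises(self):
        dm = distance_transform(np.zeros((5, 5), bool))
        with pytest.raises(DegenerateInputError):
            build_histogram(dm, np.zeros((5, 5), bool))


class TestMixtureFit:
    def _hist_from_samples(self, samples):
        samples = np.asarray(samples, float)
        lo, hi = int(np.floor(samples.min())), int(np.ceil(samples.max()))
        edges = np.arange(lo - 0.5, hi + 1.5, 1.0)
        counts, _ = np.histogram(samples, bins=edges)
        return ThicknessHistogram(
            bin_centers=0.5 * (edges[:-1] + edges[1:]),
            counts=counts,
            n_medial=len(samples),
            samples=samples,
        )

    def test_single_component_limit(self):
        hist = self._hist_from_samples(np.full(500, 5.0))
        fit = fit_mixture(hist, K=1)
        assert fit.means[0] == pytest.approx(5.0, abs=0.05)
        assert fit.sds[0] == pytest.approx(0.25, abs=0.05)  # the floor
        assert fit.weights[0] == pytest.approx(1.0, abs=0.05)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 5000
        comp = rng.random(n) < 0.7
        samples = np.where(
            comp, rng.normal(3.0, 0.5, n), rng.normal(9.0, 1.0, n)
        )
        fit = fit_mixture(self._hist_from_samples(samples), K=2)
        assert fit.means[0] == pytest.approx(3.0, abs=0.2)
        assert fit.means[1] == pytest.approx(9.0, abs=0.2)
        assert fit.weights[0] == pytest.approx(0.7, abs=0.05)
        assert fit.weights[1] == pytest.approx(0.3, abs=0.05)
        assert fit.means[0] < fit.means[1]  # canonical ordering

    def test_agrees_with_em_cross_check(self):
        rng = np.random.default_rng(11)
        n = 4000
        comp = rng.random(n) < 0.6
        samples = np.where(
            comp, rng.normal(3.5, 0.6, n), rng.normal(8.5, 0.9, n)
        )
        ls = fit_mixture(self._hist_from_samples(samples), K=2)
        em = fit_mixture_em(samples, K=2, seed=0)
        assert np.allclose(ls.means, em.means, atol=0.3)
        assert np.allclose(ls.weights, em.weights, atol=0.08)

    def test_fit_reduces_objective(self):
        rng = np.random.default_rng(5)
        samples = np.concatenate(
            [rng.normal(3, 0.5, 1500), rng.normal(9, 1.0, 700)]
        )
        hist = self._hist_from_samples(samples)
        fit = fit_mixture(hist, K=2)
        # objective at a deliberately poor parameter set
        target = hist.counts / hist.n_medial
        bad = np.mean(
            (mixture_pdf(hist.bin_centers, [0.5, 0.5], [1.0, 12.0], [2.0, 2.0]) - target) ** 2
        )
        assert fit.mse <= bad

    def test_bin_order_invariance(self):
        rng = np.random.default_rng(9)
        samples = np.concatenate([rng.normal(3, 0.5, 800), rng.normal(9, 1, 800)])
        hist = self._hist_from_samples(samples)
        perm = rng.permutation(len(hist.bin_centers))
        shuffled = ThicknessHistogram(
            bin_centers=hist.bin_centers[perm],
            counts=hist.counts[perm],
            n_medial=hist.n_medial,
            samples=hist.samples,
        )
        f1, f2 = fit_mixture(hist), fit_mixture(shuffled)
        assert np.allclose(f1.means, f2.means, atol=1e-6)
        assert np.allclose(f1.weights, f2.weights, atol=1e-6)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_mixture(self._hist_from_samples(np.full(100, 4.0)), K=2)

    def test_theta_t(self):
        rng = np.random.default_rng(2)
        samples = np.concatenate([rng.normal(3, 0.5, 800), rng.normal(9, 1, 800)])
        fit = fit_mixture(self._hist_from_samples(samples), K=2)
        assert fit.theta_t() == pytest.approx(2 * fit.sds[0])
        assert fit.theta_t(from_variance=True) == pytest.approx(2 * fit.sds[0] ** 2)

    def test_fit_plot_export(self, tmp_path):
        from rhizograph.thickness import plot_thickness_fit

        rng = np.random.default_rng(3)
        samples = np.concatenate([rng.normal(3, 0.5, 500), rng.normal(9, 1, 500)])
        hist = self._hist_from_samples(samples)
        fit = fit_mixture(hist, K=2)
        out = tmp_path / "fit.png"
        plot_thickness_fit(hist, fit, str(out))
        assert out.stat().st_size > 0

    def test_component_normalization(self):
        # each mixture component integrates to its weight
        chi = np.linspace(-20, 40, 20001)
        w, mu, sd = [0.6, 0.4], [3.0, 9.0], [0.5, 1.0]
        total = np.trapezoid(mixture_pdf(chi, w, mu, sd), chi)
        assert total == pytest.approx(sum(w), abs=1e-6)
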