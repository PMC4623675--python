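"""Skeleton-to-graph conversion, specific scores and reduction rules."""

import numpy as np
import pytest

from rhizograph.config import GraphConfig
from rhizograph.errors import StateError
from rhizograph.root_graph import build_graph, prune, score_edges
from rhizograph.segmentation import RootMask
from rhizograph.thickness import ThicknessMixture, distance_transform
from rhizograph.thinning import Skeleton, chain_length, thin

from conftest import make_scored_graph


def graph_from_mask(mask):
    dm = distance_transform(mask)
    sk = thin(RootMask(mask, 600), dm)
    return build_graph(sk, dm), dm, sk


def stub_mixture(mu1=3.0, mu2=9.0, s1=1.0, s2=1.0, w1=0.6):
    return ThicknessMixture(
        weights=[w1, 1 - w1], means=[mu1, mu2], sds=[s1, s2]
    )


class TestBuildGraph:
    def test_straight_line(self):
        m = np.zeros((11, 60), bool)
        m[3:8, 5:55] = True
        G, _, _ = graph_from_mask(m)
        kinds = sorted(v.kind for v in G.vertices.values())
        assert kinds == ["end", "end"]
        assert G.n_edges == 1

    def test_y_shape(self):
        m = np.zeros((80, 80), bool)
        m[38:43, 5:75] = True  # horizontal bar
        m[5:40, 38:43] = True  # stem up from the middle
        G, _, _ = graph_from_mask(m)
        ends = [v for v in G.vertices.values() if v.kind == "end"]
        junctions = [v for v in G.vertices.values() if v.kind == "junction"]
        assert len(ends) == 3
        assert len(junctions) == 1
        assert G.n_edges == 3

    def test_ring_attached_at_one_point(self):
        # a stem ending in a closed ring: the graph needs a self-loop
        m = np.zeros((60, 60), bool)
        rr, cc = np.mgrid[0:60, 0:60]
        ring = (np.hypot(rr - 30, cc - 38) < 14) & (np.hypot(rr - 30, cc - 38) > 8)
        m |= ring
        m[28:33, 2:28] = True  # stem touching the ring
        G, _, _ = graph_from_mask(m)
        self_loops = [e for e in G.edges.values() if e.u == e.v]
        assert len(self_loops) == 1
        # exhaustive pixel accounting: every skeleton pixel is in exactly
        # one edge path interior or a vertex neighbourhood
        sk = thin(RootMask(m, 600)).skel
        covered = set()
        for e in G.edges.values():
            covered.update(map(tuple, e.path))
        for v in G.vertices.values():
            covered.update(v.pixels)
        assert covered == set(map(tuple, np.argwhere(sk)))

    def test_empty_skeleton(self):
        G = build_graph(
            Skeleton(np.zeros((5, 5), bool)), distance_transform(np.zeros((5, 5), bool))
        )
        assert G.n_vertices == 0 and G.n_edges == 0

    def test_edge_lengths_are_chain_code(self):
        m = np.zeros((40, 40), bool)
        for i in range(30):  # diagonal ribbon
            m[i + 3 : i + 8, i + 3 : i + 8] = True
        G, _, _ = graph_from_mask(m)
        for e in G.edges.values():
            assert e.length == pytest.approx(chain_length(e.path))


class TestScoreEdges:
    @pytest.mark.parametrize(
        "tbar,theta,length,alpha",
        [(6.0, 2.0, 10.0, 40.0), (2.0, 2.0, 7.0, 0.0), (1.0, 2.0, 5.0, -5.0)],
    )
    def test_specific_score_formula(self, tbar, theta, length, alpha):
        G = make_scored_graph([("a", "b", 0)])
        e = next(iter(G.edges.values()))
        e.profile = np.full(len(e.path), tbar)
        e.length = length
        mix = stub_mixture(s1=theta / 2.0)
        score_edges(G, mix)
        assert e.score == pytest.approx(alpha)

    def test_theta_from_sd_not_variance(self):
        G = make_scored_graph([("a", "b", 0)])
        mix = stub_mixture(s1=0.7)
        score_edges(G, mix)
        assert G.theta_t == pytest.approx(1.4)
        score_edges(G, mix, GraphConfig(theta_from_variance=True))
        assert G.theta_t == pytest.approx(2 * 0.7**2)

    def test_unfitted_mixture_raises(self):
        G = make_scored_graph([("a", "b", 0)])
        with pytest.raises(StateError):
            score_edges(G, ThicknessMixture(weights=[1.0], means=[5.0], sds=[1.0]))


def scored(edges, **vertex_pos):
    G = make_scored_graph(edges, vertex_pos or None)
    return G


class TestPrune:
    def test_self_loop_removed_plain_edge_kept(self):
        G = make_scored_graph([("a", "a", 5.0), ("a", "b", 7.0)])
        R = prune(G)
        assert R.n_edges == 1
        assert next(iter(R.edges.values())).score == 7.0

    def test_rule1_negative_end_edge(self):
        # junction j with thick body a-j, j-c and a negative thin end edge
        G = make_scored_graph(
            [("a", "j", 50.0), ("j", "c", 60.0), ("j", "t", -4.0)]
        )
        R = prune(G)
        assert all(e.score >= 0 for e in R.edges.values())

    def test_rule3_smallest_positive_end_edge(self):
        # the lateral keeps a positive score but is smallest at its
        # junction, while the main root continues through (non-terminal
        # chain on both sides)
        G = make_scored_graph(
            [
                ("a", "j1", 50.0),
                ("j1", "j2", 40.0),
                ("j2", "b", 45.0),
                ("j1", "lat", 8.0),  # positive but smallest at j1
            ]
        )
        for e in G.edges.values():  # mark thin lateral calibre
            if e.score == 8.0:
                e.profile = np.full(len(e.path), 2.0)
        G.thin_cutoff = 6.0
        R = prune(G)
        assert 8.0 not in [e.score for e in R.edges.values()]

    def test_rule4_contraction_recomputes_profile(self):
        m = np.zeros((11, 100), bool)
        m[3:8, 5:95] = True
        m[3:8, 40:46] = True
        G, dm, sk = graph_from_mask(m)
        mix = stub_mixture(mu1=1.0, mu2=5.0, s1=0.5)
        score_edges(G, mix)
        R = prune(G)
        assert R.n_edges == 1
        merged = next(iter(R.edges.values()))
        # mean thickness equals recomputation from the concatenated profile
        assert merged.mean_thickness == pytest.approx(merged.profile.mean())
        assert merged.score == pytest.approx(
            (merged.profile.mean() - G.theta_t) * merged.length
        )

    def test_provenance_round_trip(self, small_scene):
        from rhizograph import analyze_image

        scan, _ = small_scene
        res = analyze_image(scan)
        R, G = res.reduced_graph, res.original_graph
        for e in R.edges.values():
            assert e.orig_ids, "reduced edge lost provenance"
            orig_pixels = set()
            for oid in e.orig_ids:
                orig_pixels.update(map(tuple, G.edges[oid].path))
            red_pixels = set(map(tuple, e.path))
            # the reduced path is covered by its original edges
            assert red_pixels <= orig_pixels

    def test_prune_requires_scores(self):
        G = make_scored_graph([("a", "b", 1.0)])
        next(iter(G.edges.values())).score = None
        with pytest.raises(StateError):
            prune(G)

    def test_prune_empty_graph_is_noop(self):
        from rhizograph.root_graph import RootGraphStruct

        R = prune(RootGraphStruct())
        assert R.n_vertices == 0

    def test_reduced_vertex_count_small_on_scenes(self):
        # the working regime the search relies on: reduction leaves a
        # graph of only a few dozen vertices at most
        from rhizograph import analyze_image, generate_scene
        from conftest import small_spec

        small = 0
        for seed in (1, 2, 3, 4, 5):
            scan, _ = generate_scene(small_spec(seed=seed))
            res = analyze_image(scan)
            if res.reduced_graph.n_vertices <= 30:
                small += 1
        assert small >= 4
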