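"""Shared fixtures: small, fast synthetic scenes and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from rhizograph import SceneSpec, generate_scene
from rhizograph.root_graph import RootGraphStruct


def small_spec(seed: int = 1, **over) -> SceneSpec:
    """A reduced-size scene (3 primaries, ~700x900 px) for fast tests."""
    defaults = dict(seed=seed, height_px=900, width_px=700, n_primaries=3)
    defaults.update(over)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic small scene with its ground truth."""
    return generate_scene(small_spec(seed=1))


def make_scored_graph(edge_list, positions=None) -> RootGraphStruct:
    """Build a RootGraphStruct from (u, v, score) triples.

    Vertices are created on demand; each edge gets a synthetic straight
    two-pixel path and a constant thickness profile, with the score set
    directly (path search only reads scores, paths and lengths).
    """
    G = RootGraphStruct()
    vid_of = {}

    def vert(name):
        if name not in vid_of:
            pos = positions[name] if positions else (len(vid_of), 0)
            vid_of[name] = G.add_vertex(pos, "end")
        return vid_of[name]

    for u, v, score in edge_list:
        uu, vv = vert(u), vert(v)
        path = np.array([G.vertices[uu].pos, G.vertices[vv].pos])
        if np.array_equal(path[0], path[1]):
            path = np.array([path[0], path[0] + [0, 1]])
        profile = np.full(len(path), 5.0)
        eid = G.add_edge(uu, vv, path, profile)
        G.edges[eid].score = float(score)
    G.theta_t = 0.0
    return G


def random_scored_graph(rng: np.random.Generator, n_vertices: int) -> RootGraphStruct:
    """Random connected multigraph with signed scores, for oracle tests."""
    names = list(range(n_vertices))
    edges = []
    # random spanning tree first, then extra edges (parallels allowed)
    for i in range(1, n_vertices):
        j = int(rng.integers(0, i))
        edges.append((i, j, float(rng.normal(0, 20))))
    extra = int(rng.integers(0, n_vertices))
    for _ in range(extra):
        u, v = rng.integers(0, n_vertices, 2)
        if u == v:
            continue
        edges.append((int(u), int(v), float(rng.normal(0, 20))))
    positions = {i: (i, int(rng.integers(0, 50))) for i in names}
    return make_scored_graph(edges, positions)


def random_blob_mask(rng: np.random.Generator, shape=(48, 48), thresh=0.55) -> np.ndarray:
    """Random smooth blobby binary mask (for thinning/DT property tests)."""
    from scipy import ndimage as ndi

    noise = rng.random(shape)
    smooth = ndi.gaussian_filter(noise, 4.0)
    smooth = (smooth - smooth.min()) / (np.ptp(smooth) + 1e-12)
    return smooth > thresh
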