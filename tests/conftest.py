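"""Shared fixtures: small complexes and one cached bifurcation pipeline run."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hodgeflow import RunConfig, fit_tree
from hodgeflow import synthetic_data as syn
from hodgeflow.simplicial_complex import SimplicialComplex


@pytest.fixture(scope="session")
def toy():
    return syn.toy_complex()


@pytest.fixture(scope="session")
def toy_sc(toy) -> SimplicialComplex:
    """The 8-vertex reference complex as a 0-indexed SimplicialComplex."""
    edges = np.array(toy.edges) - 1
    tris = np.array(toy.triangles) - 1
    return SimplicialComplex(n_vertices=8, edges=edges, triangles=tris)


def hollow_ring_complex(n: int = 12) -> SimplicialComplex:
    """Triangulated annulus with one hole: inner/outer rings of n points."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    inner = np.c_[np.cos(t), np.sin(t)]
    outer = 2 * np.c_[np.cos(t), np.sin(t)]
    pts = np.vstack([inner, outer])
    edges, tris = [], []
    for i in range(n):
        j = (i + 1) % n
        a, b = i, j  # inner
        c, d = n + i, n + j  # outer
        tris.append(tuple(sorted((a, b, c))))
        tris.append(tuple(sorted((b, c, d))))
    for tri in tris:
        for u, v in ((0, 1), (1, 2), (0, 2)):
            edges.append((tri[u], tri[v]))
    edges = np.unique(np.sort(np.array(edges), axis=1), axis=0)
    tris = np.unique(np.array(sorted(tris)), axis=0)
    return SimplicialComplex(
        n_vertices=2 * n, edges=edges, triangles=tris, layout=pts
    )


@pytest.fixture(scope="session")
def ring_sc() -> SimplicialComplex:
    return hollow_ring_complex()


def random_small_complex(rng: np.random.Generator) -> SimplicialComplex:
    """Random filtered Delaunay complex over 10-25 points (may have holes).

    Vertices isolated by the filter are dropped and the rest reindexed, so
    every vertex keeps a positive degree.
    """
    import warnings

    from hodgeflow.simplicial_complex import delaunay_complex, filter_edges_quantile

    n = int(rng.integers(10, 26))
    pts = rng.standard_normal((n, 2))
    sc = delaunay_complex(pts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc = filter_edges_quantile(sc, factor=float(rng.uniform(1.0, 2.5)), q=0.75)
    used = np.unique(sc.edges)
    remap = -np.ones(sc.n_vertices, dtype=int)
    remap[used] = np.arange(len(used))
    return SimplicialComplex(
        n_vertices=len(used),
        edges=remap[sc.edges],
        triangles=remap[sc.triangles] if sc.n_triangles else sc.triangles,
        layout=sc.layout[used],
    )


@pytest.fixture(scope="session")
def bifurcation_cloud():
    return syn.gen_bifurcation_cloud(600, noise_sd=0.05, seed=1)


@pytest.fixture(scope="session")
def bifurcation_fit(bifurcation_cloud):
    """One full pipeline run on the two-fate cloud, shared across tests."""
    cfg = RunConfig(n_paths=500, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_tree(
            bifurcation_cloud.points, [bifurcation_cloud.root_index], cfg
        )
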