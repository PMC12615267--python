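"""Pseudotime smoothing on the pruned graph and 2-D stress layout.

Gradients of the diffusion potential on the fully connected kernel graph
are transferred onto the pruned kNN graph by ridge-regularized least
squares on the two incidence matrices; a second least-squares fit turns
the pruned gradients back into a smoothed vertex potential.  A stress-
majorization (SMACOF) layout of the pruned graph provides the 2-D
coordinates on which the simplicial complex is later triangulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import shortest_path
from sklearn.manifold import smacof

__all__ = [
    "IncidencePair",
    "Layout2D",
    "incidence_from_graph",
    "complete_graph_divergence",
    "fit_pruned_gradients",
    "fit_potentials",
    "layout_2d",
    "stress_value",
]


def incidence_from_graph(edges: np.ndarray, n_vertices: int) -> sp.csc_matrix:
    """Signed vertex x edge incidence matrix B1.

    Edges are oriented low-index -> high-index: the column of edge (i, j)
    has -1 at the tail i (the edge leaves i) and +1 at the head j.
    """
    edges = np.asarray(edges, dtype=int)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise ValueError("edges must be an (m, 2) array")
    if np.any((edges < 0) | (edges >= n_vertices)):
        raise ValueError("edge endpoint out of range")
    if np.any(edges[:, 0] == edges[:, 1]):
        raise ValueError("self-loops are not allowed")
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    m = len(edges)
    rows = np.concatenate([lo, hi])
    cols = np.tile(np.arange(m), 2)
    data = np.concatenate([-np.ones(m), np.ones(m)])
    return sp.csc_matrix((data, (rows, cols)), shape=(n_vertices, m))


@dataclass
class IncidencePair:
    """Incidence matrices of the full and pruned graphs over one vertex set."""

    B1_full: sp.spmatrix | None
    B1_pruned: sp.spmatrix
    pruned_edges: np.ndarray

    @classmethod
    def from_edges(
        cls,
        pruned_edges: np.ndarray,
        n_vertices: int,
        full_edges: np.ndarray | None = None,
    ) -> "IncidencePair":
        b1f = (
            incidence_from_graph(full_edges, n_vertices)
            if full_edges is not None
            else None
        )
        return cls(
            B1_full=b1f,
            B1_pruned=incidence_from_graph(pruned_edges, n_vertices),
            pruned_edges=np.asarray(pruned_edges, dtype=int),
        )


def complete_graph_divergence(u: np.ndarray) -> np.ndarray:
    """B1^F w^F for the complete graph with gradient weights w_ij = u_j - u_i.

    For edge (i, j) (i < j) with weight u_j - u_i the signed sums per
    vertex telescope to n*u - sum(u), so the divergence never requires the
    O(n^2)-edge incidence matrix explicitly.
    """
    u = np.asarray(u, dtype=float)
    return u.size * u - u.sum()


def fit_pruned_gradients(
    pair: IncidencePair,
    w_full: np.ndarray | None,
    lam: float | None = None,
    divergence: np.ndarray | None = None,
) -> np.ndarray:
    """Ridge fit of pruned-graph gradients to the full-graph divergence.

    Minimizes ||B1^F w^F - B1^P w_P||^2 + lam ||w_P||^2 through the normal
    equations (B1^P' B1^P + lam I) w_P = B1^P' (B1^F w^F).  ``lam=None``
    uses the scale-free default 0.01 * lambda_max(B1^P' B1^P).  With
    lam = 0 on a rank-deficient system the minimum-norm solution is
    returned with a warning.
    """
    b1p = pair.B1_pruned.tocsc()
    if divergence is None:
        if pair.B1_full is None or w_full is None:
            raise ValueError("need either (B1_full, w_full) or a divergence vector")
        divergence = pair.B1_full @ np.asarray(w_full, dtype=float)
    gram = (b1p.T @ b1p).tocsc()
    if lam is None:
        lmax = float(
            spla.eigsh(gram.asfptype(), k=1, which="LA", return_eigenvectors=False)[0]
        )
        lam = 0.01 * lmax
    if lam < 0:
        raise ValueError("lam must be >= 0")
    rhs = b1p.T @ divergence
    if lam == 0:
        from scipy.sparse.csgraph import connected_components

        n = b1p.shape[0]
        adj = sp.coo_matrix(
            (np.ones(len(pair.pruned_edges)), tuple(pair.pruned_edges.T)),
            shape=(n, n),
        )
        n_comp, _ = connected_components(adj, directed=False)
        if b1p.shape[1] > n - n_comp:  # cycles => rank-deficient columns
            warnings.warn(
                "lam=0 with rank-deficient system; returning minimum-norm solution",
                stacklevel=2,
            )
        return spla.lsqr(b1p.tocsr(), divergence, atol=1e-14, btol=1e-14)[0]
    m = gram.shape[0]
    sol = spla.spsolve(gram + lam * sp.identity(m, format="csc"), rhs)
    return np.asarray(sol).ravel()


def fit_potentials(
    pair: IncidencePair,
    w_pruned: np.ndarray,
    roots: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares vertex potential whose gradient best matches w^P.

    Solves min_u ||B1^P' u - w^P||^2 (the solution is defined per connected
    component up to a constant; LSQR returns the minimum-norm representative)
    and gauge-fixes so the mean potential over ``roots`` (all vertices when
    omitted) is zero.  Returns (potential, gradient = B1^P' potential).
    """
    b1t = pair.B1_pruned.T.tocsr()
    u = spla.lsqr(b1t, np.asarray(w_pruned, dtype=float), atol=1e-12, btol=1e-12)[0]
    if roots is not None and len(np.atleast_1d(roots)) > 0:
        u = u - u[np.atleast_1d(roots)].mean()
    else:
        u = u - u.mean()
    return u, b1t @ u


@dataclass
class Layout2D:
    """Seeded 2-D stress-majorization layout of a graph."""

    coords: np.ndarray
    stress: float
    seed: int


def _graph_distances(
    edges: np.ndarray, n_vertices: int, lengths: np.ndarray
) -> np.ndarray:
    g = sp.coo_matrix(
        (lengths, (edges[:, 0], edges[:, 1])), shape=(n_vertices, n_vertices)
    ).tocsr()
    d = shortest_path(g, directed=False)
    if np.isinf(d).any():
        # disconnected graphs: place components a fixed gap apart
        finite_max = d[np.isfinite(d)].max() if np.isfinite(d).any() else 1.0
        d[np.isinf(d)] = 1.5 * finite_max
    return d


def _classical_mds_init(d: np.ndarray, seed: int) -> np.ndarray:
    """Top-2 classical-MDS coordinates of a distance matrix (deterministic)."""
    n = d.shape[0]
    d2 = d**2
    rm = d2.mean(axis=1)
    gram = -0.5 * (d2 - rm[:, None] - rm[None, :] + d2.mean())
    gram = 0.5 * (gram + gram.T)
    if n <= 600:
        evals, vecs = np.linalg.eigh(gram)
        evals, vecs = evals[::-1][:2], vecs[:, ::-1][:, :2]
    else:
        evals, vecs = spla.eigsh(
            gram, k=2, which="LA", v0=np.random.default_rng(seed).standard_normal(n)
        )
        order = np.argsort(evals)[::-1]
        evals, vecs = evals[order], vecs[:, order]
    return vecs * np.sqrt(np.maximum(evals, 1e-12))


def stress_value(coords: np.ndarray, distances: np.ndarray) -> float:
    """Raw Kruskal stress: sum over pairs of (||x_i-x_j|| - d_ij)^2 / 2."""
    diff = coords[:, None, :] - coords[None, :, :]
    dd = np.sqrt((diff**2).sum(-1))
    return float(((dd - distances) ** 2).sum() / 2.0)


def layout_2d(
    edges: np.ndarray,
    n_vertices: int,
    weights: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> Layout2D:
    """2-D stress-majorization layout of a weighted graph.

    Pairwise targets are graph shortest-path distances with edge lengths
    ``weights`` (unit lengths when omitted).  The SMACOF iteration starts
    from a deterministic classical-MDS configuration, so the result is
    reproducible under a fixed seed, and stress is non-increasing.
    """
    edges = np.asarray(edges, dtype=int)
    lengths = (
        np.ones(len(edges)) if weights is None else np.asarray(weights, dtype=float)
    )
    d = _graph_distances(edges, n_vertices, lengths)
    init = _classical_mds_init(d, seed)
    coords, stress = smacof(
        d,
        metric=True,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=False,
    )
    return Layout2D(coords=coords, stress=float(stress), seed=seed)
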