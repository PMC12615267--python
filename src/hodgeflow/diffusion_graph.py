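"""Diffusion-map graph construction and random-walk pseudotime.

The cell embedding is turned into a locally scaled Gaussian kernel
W_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j)), with sigma_i the distance
to the ``scale_neighbor``-th nearest neighbour.  A lazy random walk
M = D^{-1} W over this (fully connected) kernel graph, iterated for ``s``
steps from the root cells, yields a potential u whose min-max-normalized
negation serves as pseudotime: roots near 0, terminal states near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingMatrix",
    "CellGraph",
    "DiffusionOperator",
    "local_scaling_kernel",
    "graph_laplacian0",
    "transition_matrix",
    "diffusion_pseudotime",
    "knn_prune",
]


@dataclass
class EmbeddingMatrix:
    """A cells x dims low-dimensional embedding with unique cell labels."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 3:
            raise ValueError("embedding must be a 2-D matrix with >= 3 cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains non-finite entries")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length does not match embedding rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids: list[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        try:
            return np.array([lookup[c] for c in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message matters, not path
            raise KeyError(f"unknown cell id: {e.args[0]!r}") from None


@dataclass
class CellGraph:
    """Kernel graph over cells plus (optional) pseudotime annotations."""

    embedding: EmbeddingMatrix
    kernel: np.ndarray
    sigma: np.ndarray
    knn_edges: np.ndarray | None = None
    knn_k: int | None = None
    edge_gradient: np.ndarray | None = None
    potential: np.ndarray | None = None
    pseudotime: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.kernel.shape[0]

    @property
    def degree(self) -> np.ndarray:
        return self.kernel.sum(axis=1)


@dataclass
class DiffusionOperator:
    """Random-walk operator M = D^{-1} W with a lazy spectral form.

    The symmetric conjugate M' = D^{-1/2} W D^{-1/2} shares eigenvalues
    with M (all real, in [-1, 1]); its eigendecomposition Q Lambda Q^T
    gives M^s = D^{-1/2} Q Lambda^s Q^T D^{1/2} without forming powers.
    """

    kernel: np.ndarray
    degree: np.ndarray
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.degree <= 0):
            bad = int(np.argmin(self.degree))
            raise ValueError(f"isolated cell with zero degree at index {bad}")

    @property
    def M(self) -> np.ndarray:
        return self.kernel / self.degree[:, None]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors (Q) of the symmetric form M'."""
        if self._eig is None:
            ds = 1.0 / np.sqrt(self.degree)
            m_sym = self.kernel * ds[:, None] * ds[None, :]
            evals, q = np.linalg.eigh(m_sym)
            self._eig = (evals, q)
        return self._eig

    def propagate(self, p0: np.ndarray, steps: int) -> np.ndarray:
        """Left-multiply: p0 @ M^steps by repeated matrix-vector products."""
        p = np.asarray(p0, dtype=float)
        m = self.M
        for _ in range(steps):
            p = p @ m
        return p

    def propagate_spectral(self, p0: np.ndarray, steps: int) -> np.ndarray:
        """p0 @ M^steps through the eigendecomposition of M'."""
        evals, q = self.eigendecomposition()
        dsi = 1.0 / np.sqrt(self.degree)
        # p M^s = ((p D^{-1/2}) Q) Lambda^s Q^T D^{1/2}
        coef = (np.asarray(p0, dtype=float) * dsi) @ q
        return (coef * evals**steps) @ q.T * np.sqrt(self.degree)


def local_scaling_kernel(
    embedding: EmbeddingMatrix | np.ndarray,
    scale_neighbor: int = 7,
    cell_ids: list[str] | None = None,
) -> CellGraph:
    """Gaussian kernel with per-cell local scaling.

    ``sigma_i`` is the Euclidean distance from cell i to its
    ``scale_neighbor``-th nearest neighbour (self excluded).  Duplicated
    points with sigma = 0 fall back to the smallest positive neighbour
    distance, with a warning.
    """
    if not isinstance(embedding, EmbeddingMatrix):
        x = np.asarray(embedding, dtype=float)
        ids = cell_ids if cell_ids is not None else [f"c{i}" for i in range(len(x))]
        embedding = EmbeddingMatrix(x, ids)
    x = embedding.values
    n = x.shape[0]
    if scale_neighbor >= n:
        raise ValueError("scale_neighbor must be < n_cells")
    nn = NearestNeighbors(n_neighbors=min(n, scale_neighbor + 1)).fit(x)
    dist, _ = nn.kneighbors(x)
    sigma = dist[:, -1].copy()  # self occupies column 0
    if np.any(sigma == 0):
        pos = dist[dist > 0]
        fallback = pos.min() if pos.size else 1.0
        warnings.warn(
            f"{int((sigma == 0).sum())} cells have duplicate neighbourhoods; "
            "falling back to smallest positive neighbour distance",
            stacklevel=2,
        )
        sigma[sigma == 0] = fallback
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    w = np.exp(-d2 / (sigma[:, None] * sigma[None, :]))
    w = 0.5 * (w + w.T)  # symmetrize away round-off
    np.fill_diagonal(w, 1.0)
    return CellGraph(embedding=embedding, kernel=w, sigma=sigma)


def graph_laplacian0(graph: CellGraph | np.ndarray) -> np.ndarray:
    """Unnormalized graph Laplacian L0 = D - W (rows sum to zero)."""
    w = graph.kernel if isinstance(graph, CellGraph) else np.asarray(graph, float)
    lap = -w.copy()
    np.fill_diagonal(lap, 0.0)
    np.fill_diagonal(lap, -lap.sum(axis=1))
    return lap


def transition_matrix(graph: CellGraph | np.ndarray) -> DiffusionOperator:
    """Random-walk operator M = D^{-1} W for the kernel graph."""
    w = graph.kernel if isinstance(graph, CellGraph) else np.asarray(graph, float)
    return DiffusionOperator(kernel=w, degree=w.sum(axis=1))


def diffusion_pseudotime(
    op: DiffusionOperator,
    roots: np.ndarray,
    steps: int = 100,
    spectral: bool | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Root-seeded diffusion potential and min-max pseudotime.

    The potential is u = r M^s with r uniform over the root cells.  M is
    row-stochastic so the total mass of u stays 1 for any s.  Pseudotime
    is (max u - u) / (max u - min u): roots (high retained mass) map near
    0 and terminal cells near 1.

    ``spectral`` selects the evaluation route (eigendecomposition vs
    repeated multiplication); by default the dense spectral route is used
    for graphs up to 1,500 cells.  Both agree to solver precision.
    """
    roots = np.atleast_1d(np.asarray(roots, dtype=int))
    if roots.size == 0:
        raise ValueError("roots must be non-empty")
    n = op.kernel.shape[0]
    if np.any((roots < 0) | (roots >= n)):
        raise ValueError("root index out of range")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    r = np.zeros(n)
    r[roots] = 1.0 / roots.size
    if spectral is None:
        spectral = n <= 1500
    u = op.propagate_spectral(r, steps) if spectral else op.propagate(r, steps)
    rng_u = u.max() - u.min()
    pt = np.zeros_like(u) if rng_u == 0 else (u.max() - u) / rng_u
    return u, pt


def knn_prune(graph: CellGraph, k: int = 15, potential: np.ndarray | None = None) -> CellGraph:
    """Prune the kernel graph to a union-kNN edge set.

    An edge (i, j) is retained when j is among the k nearest neighbours of
    i or vice versa (neighbourhoods in the embedding metric).  Edges are
    stored low-index -> high-index; when a potential u is given, each edge
    carries the full-graph gradient w_ij = u_j - u_i as initial weight.
    """
    n = graph.n_cells
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n_cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(graph.embedding.values)
    _, idx = nn.kneighbors(graph.embedding.values)
    pairs = set()
    for i in range(n):
        for j in idx[i, 1:]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int)
    grad = None
    if potential is None:
        potential = graph.potential
    if potential is not None:
        grad = potential[edges[:, 1]] - potential[edges[:, 0]]
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"pruned kNN graph has {n_comp} connected components", stacklevel=2
        )
    return CellGraph(
        embedding=graph.embedding,
        kernel=graph.kernel,
        sigma=graph.sigma,
        knn_edges=edges,
        knn_k=k,
        edge_gradient=grad,
        potential=graph.potential,
        pseudotime=graph.pseudotime,
    )
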