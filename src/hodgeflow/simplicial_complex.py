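"""Two-dimensional simplicial complex over the cell layout.

A Delaunay triangulation of the 2-D layout gives a hole-free disc of
triangles; overlong edges are filtered (3 x Q75 of the edge-length
distribution by default, or a 0-dimensional-persistence radius), and
artificial ("dummy") edges and triangles connect each group of terminal
cells back to the root cells.  Every terminal group then bounds one hole,
so the first Betti number of the final complex equals the number of
terminal differentiation states.

Orientation bookkeeping: edges point from low to high vertex index,
triangles are ascending triples.  B2 follows the induced-boundary
convention of the reference worked example in the package docs: for triangle (a, b, c) the edges
(a, b) and (b, c) carry +1 and (a, c) carries -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "SimplicialComplex",
    "RadiusThreshold",
    "delaunay_complex",
    "filter_edges_quantile",
    "filter_edges_radius",
    "ph0_radius_threshold",
    "find_terminal_groups",
    "add_terminal_root_links",
    "boundary_matrices",
    "triangles_from_edges",
    "betti1",
]


@dataclass
class SimplicialComplex:
    """Vertices, oriented edges and triangles with boundary operators."""

    n_vertices: int
    edges: np.ndarray  # (m, 2) int, each row sorted low < high, lexsorted
    triangles: np.ndarray  # (t, 3) int, ascending triples
    layout: np.ndarray | None = None  # (n, 2) coordinates used for lengths
    dummy_edges: np.ndarray = field(default=None)  # bool mask over edges
    dummy_triangles: np.ndarray = field(default=None)  # bool mask over triangles
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.dummy_edges is None:
            self.dummy_edges = np.zeros(len(self.edges), dtype=bool)
        if self.dummy_triangles is None:
            self.dummy_triangles = np.zeros(len(self.triangles), dtype=bool)
        self._edge_index = {tuple(e): i for i, e in enumerate(map(tuple, self.edges))}

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_id(self, u: int, v: int) -> int:
        return self._edge_index[(min(u, v), max(u, v))]

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self._edge_index

    @property
    def edge_lengths(self) -> np.ndarray:
        if self.layout is None:
            raise ValueError("complex has no layout coordinates")
        diff = self.layout[self.edges[:, 0]] - self.layout[self.edges[:, 1]]
        return np.linalg.norm(diff, axis=1)

    @property
    def B1(self) -> sp.csc_matrix:
        return boundary_matrices(self)[0]

    @property
    def B2(self) -> sp.csc_matrix:
        return boundary_matrices(self)[1]

    def adjacency(self, weighted: bool = True) -> sp.csr_matrix:
        w = self.edge_lengths if (weighted and self.layout is not None) else np.ones(
            self.n_edges
        )
        a = sp.coo_matrix(
            (w, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_vertices, self.n_vertices),
        )
        return (a + a.T).tocsr()


@dataclass(frozen=True)
class RadiusThreshold:
    """PH0-derived edge-length threshold for single connectivity."""

    min_single_component_radius: float
    factor: float
    threshold: float


def _canonical_edges(edges: np.ndarray) -> np.ndarray:
    e = np.sort(np.asarray(edges, dtype=int), axis=1)
    e = np.unique(e, axis=0)
    return e


def delaunay_complex(
    layout: np.ndarray, cell_ids: list[str] | None = None
) -> SimplicialComplex:
    """Delaunay triangulation of 2-D points as a simplicial complex."""
    pts = np.asarray(layout, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("layout must be an (n, 2) coordinate array")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(
            "Delaunay triangulation failed (points may be collinear); "
            "jitter the layout or supply more dimensions"
        ) from e
    triangles = np.sort(tri.simplices, axis=1)
    triangles = np.unique(triangles, axis=0)
    edges = _canonical_edges(
        np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]])
    )
    return SimplicialComplex(
        n_vertices=pts.shape[0],
        edges=edges,
        triangles=triangles,
        layout=pts,
        cell_ids=cell_ids,
    )


def _drop_edges(sc: SimplicialComplex, drop_mask: np.ndarray) -> SimplicialComplex:
    keep_edges = sc.edges[~drop_mask]
    kept = {tuple(e) for e in map(tuple, keep_edges)}
    tri_keep = np.array(
        [
            all(
                (t[i], t[j]) in kept
                for i, j in ((0, 1), (1, 2), (0, 2))
            )
            for t in sc.triangles
        ],
        dtype=bool,
    ) if len(sc.triangles) else np.zeros(0, dtype=bool)
    return SimplicialComplex(
        n_vertices=sc.n_vertices,
        edges=keep_edges,
        triangles=sc.triangles[tri_keep],
        layout=sc.layout,
        dummy_edges=sc.dummy_edges[~drop_mask],
        dummy_triangles=sc.dummy_triangles[tri_keep] if len(sc.triangles) else None,
        cell_ids=sc.cell_ids,
    )


def _warn_if_disconnected(sc: SimplicialComplex, context: str) -> None:
    n_comp, labels = connected_components(sc.adjacency(weighted=False), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        warnings.warn(
            f"{context} left {n_comp} components (sizes {sorted(sizes.tolist(), reverse=True)[:5]}...)",
            stacklevel=3,
        )


def filter_edges_quantile(
    sc: SimplicialComplex, factor: float = 3.0, q: float = 0.75
) -> SimplicialComplex:
    """Remove edges longer than ``factor`` x the q-quantile of edge lengths.

    Triangles losing an edge are removed with it, so B1 B2 = 0 is
    preserved.  A warning reports the component census if the filter
    disconnects the complex.
    """
    lengths = sc.edge_lengths
    thr = factor * np.quantile(lengths, q)
    out = _drop_edges(sc, lengths > thr)
    _warn_if_disconnected(out, "quantile edge filter")
    return out


def ph0_radius_threshold(layout: np.ndarray, factor: float = 1.2) -> RadiusThreshold:
    """Radius at which the point cloud first becomes one component, scaled.

    The longest edge of the Euclidean minimum spanning tree is the death
    radius of the last-merging 0-dimensional persistence class; keeping
    edges shorter than ``factor`` x that radius guarantees a single
    connected component.
    """
    pts = np.asarray(layout, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    mst = minimum_spanning_tree(d)
    radius = float(mst.data.max())
    return RadiusThreshold(
        min_single_component_radius=radius, factor=factor, threshold=factor * radius
    )


def filter_edges_radius(sc: SimplicialComplex, threshold: float) -> SimplicialComplex:
    """Remove edges longer than an absolute length threshold."""
    out = _drop_edges(sc, sc.edge_lengths > threshold)
    _warn_if_disconnected(out, "radius edge filter")
    return out


def find_terminal_groups(
    graph: SimplicialComplex | np.ndarray,
    pseudotime: np.ndarray,
    persistence: float = 0.025,
    min_peak_pt: float = 0.02,
) -> list[np.ndarray]:
    """Group terminal cells: one group per differentiation end state.

    Peaks of pseudotime are extracted by a superlevel-set filtration
    (0-dimensional persistence of -pseudotime): vertices enter in
    decreasing pseudotime order and union with already-present
    neighbours.  When two peak components meet, the lower peak is
    absorbed if its persistence (peak height minus merge level) is below
    ``persistence`` (pseudotime units, scale 0-1) — a noise wiggle — and
    otherwise survives as a terminal group whose members are its basin at
    the merge level.  Groups peaking below ``min_peak_pt`` x the maximum
    pseudotime (the noise shell around the root, where the diffusion
    potential is still essentially flat) are dropped.

    ``graph`` is a complex or an (m, 2) edge array; the pruned kNN graph
    in embedding space is the faithful neighbourhood structure (2-D
    layout adjacency can bridge unrelated branches).
    """
    pt = np.asarray(pseudotime, dtype=float)
    if isinstance(graph, SimplicialComplex):
        adj = graph.adjacency(weighted=False).tolil()
        n_vertices = graph.n_vertices
    else:
        edges = np.asarray(graph, dtype=int)
        n_vertices = pt.shape[0]
        a = sp.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
            shape=(n_vertices, n_vertices),
        )
        adj = (a + a.T).tolil()
    floor = min_peak_pt * float(pt.max())
    order = np.argsort(pt)[::-1]
    parent = np.full(n_vertices, -1, dtype=int)  # union-find, -1 = absent
    peak_of: dict[int, int] = {}  # uf-root -> peak vertex
    members: dict[int, list[int]] = {}  # uf-root -> live member list
    frozen: list[tuple[int, np.ndarray]] = []  # (peak, basin) of survivors

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v in order:
        v = int(v)
        parent[v] = v
        peak_of[v] = v
        members[v] = [v]
        roots = {find(int(w)) for w in adj.rows[v] if parent[int(w)] != -1}
        roots.discard(v)
        for r in roots:
            rv = find(v)
            if r == rv:
                continue
            hi, lo = (rv, r) if pt[peak_of[rv]] >= pt[peak_of[r]] else (r, rv)
            if pt[peak_of[lo]] - pt[v] >= persistence:
                # the lower peak survives: freeze its basin as a group
                frozen.append((peak_of[lo], np.array(members[lo], dtype=int)))
            parent[lo] = hi
            members[hi].extend(members.pop(lo))
            peak_of.pop(lo)
    # remaining components: their peaks survive with their full basins
    for r, peak in list(peak_of.items()):
        if find(r) == r and pt[peak] >= floor:
            frozen.append((peak, np.array(members[r], dtype=int)))
    groups = [basin for peak, basin in frozen if pt[peak] >= floor]
    groups.sort(key=lambda g: -float(pt[g].max()))
    return groups


def add_terminal_root_links(
    sc: SimplicialComplex,
    pseudotime: np.ndarray,
    m: int = 5,
    terminal_groups: list[np.ndarray] | None = None,
) -> SimplicialComplex:
    """Link each terminal group back to the root cells with dummy simplices.

    For every terminal group a cone is glued onto the complex: the apex is
    the lowest-pseudotime (root) cell, the base the group's ``m``
    highest-pseudotime cells restricted to one connected patch of the
    complex.  Dummy edges run from every base cell to the apex and dummy
    triangles fill the cone over every existing base-internal edge.  A
    cone is contractible and meets the complex in the connected base plus
    the isolated apex, so each terminal group closes exactly one
    independent cycle: the final complex carries one hole per group (for
    groups in the root's connected component).
    """
    pt = np.asarray(pseudotime, dtype=float)
    if terminal_groups is None:
        terminal_groups = find_terminal_groups(sc, pt)
    order = np.argsort(pt)
    roots = order[: min(m, sc.n_vertices)]
    if len(roots) < m:
        warnings.warn(f"only {len(roots)} root cells available", stacklevel=2)
    apex = int(roots[0])
    adj = sc.adjacency(weighted=False).tolil()
    new_edges: list[tuple[int, int]] = []
    new_tris: list[tuple[int, int, int]] = []
    existing = {tuple(e) for e in map(tuple, sc.edges)}
    existing_t = {tuple(t) for t in map(tuple, sc.triangles)}
    for grp in terminal_groups:
        g = np.asarray(grp, dtype=int)
        top = g[np.argsort(pt[g])[::-1][: min(m, len(g))]]
        if len(top) < m:
            warnings.warn(
                f"terminal group has only {len(top)} cells (< m={m})", stacklevel=2
            )
        # keep the connected piece of the base containing the group's peak
        base_set = set(int(v) for v in top)
        peak = int(top[0])
        stack, comp = [peak], {peak}
        while stack:
            v = stack.pop()
            for w in adj.rows[v]:
                if int(w) in base_set and int(w) not in comp:
                    comp.add(int(w))
                    stack.append(int(w))
        base = sorted(comp)
        for t in base:
            if t == apex:
                continue
            e = (min(t, apex), max(t, apex))
            if e not in existing:
                existing.add(e)
                new_edges.append(e)
        for i, t1 in enumerate(base):
            for t2 in base[i + 1 :]:
                if t2 in (int(w) for w in adj.rows[t1]):
                    tri = tuple(sorted((t1, t2, apex)))
                    if len(set(tri)) == 3 and tri not in existing_t:
                        existing_t.add(tri)
                        new_tris.append(tri)
    edges = np.vstack([sc.edges, np.array(new_edges, dtype=int).reshape(-1, 2)])
    dummy_e = np.concatenate(
        [sc.dummy_edges, np.ones(len(new_edges), dtype=bool)]
    )
    order_e = np.lexsort((edges[:, 1], edges[:, 0]))
    edges, dummy_e = edges[order_e], dummy_e[order_e]
    tris = np.vstack(
        [sc.triangles, np.array(new_tris, dtype=int).reshape(-1, 3)]
    )
    dummy_t = np.concatenate(
        [sc.dummy_triangles, np.ones(len(new_tris), dtype=bool)]
    )
    order_t = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0]))
    return SimplicialComplex(
        n_vertices=sc.n_vertices,
        edges=edges,
        triangles=tris[order_t],
        layout=sc.layout,
        dummy_edges=dummy_e,
        dummy_triangles=dummy_t[order_t],
        cell_ids=sc.cell_ids,
    )


def boundary_matrices(
    sc: SimplicialComplex,
) -> tuple[sp.csc_matrix, sp.csc_matrix]:
    """Oriented boundary operators (B1, B2) in integer arithmetic.

    B1: column of edge (i, j), i < j, is -1 at i (edge leaves i) and +1 at
    j (edge enters j).  B2: for triangle (a, b, c), a < b < c, the sides
    (a, b) and (b, c) agree with the induced boundary orientation (+1) and
    (a, c) opposes it (-1); B1 @ B2 = 0 exactly.
    """
    m = sc.n_edges
    rows = np.concatenate([sc.edges[:, 0], sc.edges[:, 1]])
    cols = np.tile(np.arange(m), 2)
    data = np.concatenate([-np.ones(m, dtype=np.int64), np.ones(m, dtype=np.int64)])
    b1 = sp.csc_matrix((data, (rows, cols)), shape=(sc.n_vertices, m), dtype=np.int64)
    t = sc.n_triangles
    if t == 0:
        b2 = sp.csc_matrix((m, 0), dtype=np.int64)
        return b1, b2
    r2, c2, d2 = [], [], []
    for q, (a, b, c) in enumerate(sc.triangles):
        for (u, v), s in (((a, b), 1), ((b, c), 1), ((a, c), -1)):
            r2.append(sc.edge_id(u, v))
            c2.append(q)
            d2.append(s)
    b2 = sp.csc_matrix((d2, (r2, c2)), shape=(m, t), dtype=np.int64)
    return b1, b2


def triangles_from_edges(edges: np.ndarray) -> list[tuple[int, int, int]]:
    """All 3-cliques of an undirected edge list, as ascending triples."""
    e = _canonical_edges(edges)
    nbrs: dict[int, set[int]] = {}
    for u, v in e:
        nbrs.setdefault(int(u), set()).add(int(v))
        nbrs.setdefault(int(v), set()).add(int(u))
    out = []
    for u, v in e:
        common = nbrs[int(u)] & nbrs[int(v)]
        for w in common:
            if w > v:
                out.append((int(u), int(v), int(w)))
    return sorted(out)


def betti1(sc: SimplicialComplex) -> int:
    """First Betti number by rank arithmetic: |E| - rank(B1) - rank(B2)."""
    b1, b2 = boundary_matrices(sc)
    r1 = np.linalg.matrix_rank(b1.toarray()) if b1.shape[1] else 0
    r2 = np.linalg.matrix_rank(b2.toarray()) if b2.shape[1] else 0
    return int(sc.n_edges - r1 - r2)
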