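"""Divergence-following random walks, edge flows and trajectory clustering.

Walks start at the lowest-pseudotime cells and step along the pruned kNN
graph with probability proportional to the positive pseudotime gradient,
terminating at local maxima (terminal states).  Each walk is lifted onto
the simplicial complex (missing edges replaced by layout-weighted
shortest paths), encoded as a signed edge-flow vector, and projected onto
the harmonic basis: one h-dimensional point per trajectory.  DBSCAN in
that embedding recovers the major differentiation trajectory groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .simplicial_complex import SimplicialComplex

__all__ = [
    "PathEnsemble",
    "sample_random_walks",
    "lift_to_complex",
    "edge_flow",
    "flow_matrix",
    "trajectory_embedding",
    "cluster_trajectories",
    "build_ensemble",
]


@dataclass
class PathEnsemble:
    """Sampled paths with their flows, harmonic embedding and group labels."""

    paths: list[np.ndarray]  # raw vertex sequences on the kNN graph
    lifted: list[np.ndarray]  # vertex sequences on the SC
    flows: sp.csc_matrix  # (n_edges, n_paths) signed net-traversal flows
    embedding: np.ndarray  # (n_paths, h) harmonic coordinates
    group_labels: np.ndarray = field(default=None)  # -1 = outlier
    seed: int = 0

    @property
    def n_paths(self) -> int:
        return len(self.lifted)

    def visit_counts(self, n_vertices: int, exclude_outliers: bool = True) -> np.ndarray:
        """Number of path visits per vertex (over non-outlier paths)."""
        counts = np.zeros(n_vertices, dtype=int)
        for i, p in enumerate(self.lifted):
            if (
                exclude_outliers
                and self.group_labels is not None
                and self.group_labels[i] == -1
            ):
                continue
            counts[np.unique(p)] += 1
        return counts

    def terminal_vertices(self) -> np.ndarray:
        return np.array([p[-1] for p in self.lifted], dtype=int)

    def save_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["seed"] = self.seed
            f.create_dataset("path_lengths", data=[len(p) for p in self.lifted])
            f.create_dataset("paths_flat", data=np.concatenate(self.lifted))
            raw = f.create_group("raw")
            raw.create_dataset("path_lengths", data=[len(p) for p in self.paths])
            raw.create_dataset("paths_flat", data=np.concatenate(self.paths))
            coo = self.flows.tocoo()
            fl = f.create_group("flows")
            fl.create_dataset("row", data=coo.row)
            fl.create_dataset("col", data=coo.col)
            fl.create_dataset("data", data=coo.data)
            fl.attrs["shape"] = coo.shape
            f.create_dataset("embedding", data=self.embedding)
            if self.group_labels is not None:
                f.create_dataset("group_labels", data=self.group_labels)

    @classmethod
    def load_hdf5(cls, path: str) -> "PathEnsemble":
        import h5py

        with h5py.File(path, "r") as f:
            def unflatten(grp):
                lens = grp["path_lengths"][:]
                flat = grp["paths_flat"][:]
                return list(np.split(flat, np.cumsum(lens)[:-1]))

            flows = sp.coo_matrix(
                (f["flows/data"][:], (f["flows/row"][:], f["flows/col"][:])),
                shape=tuple(f["flows"].attrs["shape"]),
            ).tocsc()
            labels = f["group_labels"][:] if "group_labels" in f else None
            return cls(
                paths=unflatten(f["raw"]),
                lifted=unflatten(f),
                flows=flows,
                embedding=f["embedding"][:],
                group_labels=labels,
                seed=int(f.attrs["seed"]),
            )


def sample_random_walks(
    edges: np.ndarray,
    gradient: np.ndarray,
    pseudotime: np.ndarray,
    n: int = 10000,
    m_roots: int = 5,
    roots: np.ndarray | None = None,
    seed: int = 0,
    weighting: str = "uniform",
) -> list[np.ndarray]:
    """Preference random walks following positive pseudotime gradients.

    ``gradient[e]`` is the pseudotime difference head - tail of edge ``e``
    (oriented low -> high index).  From vertex v the walk steps only to
    neighbours with positive outgoing gradient and stops when none
    remains (a local pseudotime maximum).  With ``weighting="uniform"``
    (default) all ascending directions are equally likely, which keeps
    weak-gradient side branches populated; ``weighting="gradient"`` draws
    proportionally to the gradient magnitudes.  Start vertices are drawn
    uniformly from ``roots`` (default: the ``m_roots`` lowest-pseudotime
    cells).
    """
    if weighting not in ("uniform", "gradient"):
        raise ValueError("weighting must be 'uniform' or 'gradient'")
    if n < 1:
        raise ValueError("n must be >= 1")
    edges = np.asarray(edges, dtype=int)
    gradient = np.asarray(gradient, dtype=float)
    nv = int(pseudotime.shape[0])
    out_nbr: list[list[int]] = [[] for _ in range(nv)]
    out_w: list[list[float]] = [[] for _ in range(nv)]
    for (a, b), g in zip(edges, gradient):
        if g > 0:
            out_nbr[a].append(int(b))
            out_w[a].append(float(g))
        elif g < 0:
            out_nbr[b].append(int(a))
            out_w[b].append(float(-g))
    nbr_arr = [np.array(x, dtype=int) for x in out_nbr]
    if weighting == "uniform":
        cum_arr = [np.arange(1.0, len(w) + 1.0) for w in out_w]
    else:
        cum_arr = [np.cumsum(w) for w in out_w]
    if roots is None:
        roots = np.argsort(pseudotime)[: min(m_roots, nv)]
    roots = np.asarray(roots, dtype=int)
    rng = np.random.default_rng(seed)
    stuck = 0
    paths = []
    starts = rng.choice(roots, size=n)
    for start in starts:
        v = int(start)
        path = [v]
        while True:
            cw = cum_arr[v]
            if cw.size == 0:
                break
            r = rng.random() * cw[-1]
            v = int(nbr_arr[v][np.searchsorted(cw, r, side="right")])
            path.append(v)
        if len(path) == 1:
            stuck += 1
        paths.append(np.array(path, dtype=int))
    if stuck:
        warnings.warn(
            f"{stuck} walks started at a root with no positive out-gradient",
            stacklevel=2,
        )
    return paths


class _ScRouter:
    """Shortest-path router on the SC with per-source caching."""

    def __init__(self, sc: SimplicialComplex):
        self.sc = sc
        self.adj = sc.adjacency(weighted=True)
        self._pred: dict[int, np.ndarray] = {}

    def route(self, a: int, b: int) -> list[int] | None:
        if a not in self._pred:
            _, pred = dijkstra(
                self.adj, directed=False, indices=a, return_predecessors=True
            )
            self._pred[a] = pred
        pred = self._pred[a]
        if pred[b] < 0 and a != b:
            return None
        seq = [b]
        while seq[-1] != a:
            seq.append(int(pred[seq[-1]]))
        return seq[::-1]


def lift_to_complex(
    path: np.ndarray,
    sc: SimplicialComplex,
    router: _ScRouter | None = None,
) -> np.ndarray | None:
    """Replace steps missing from the SC by shortest paths within it.

    Detours can brush vertices the walk already visited; such loops are
    erased (truncate back to the first visit), so the lifted path is
    vertex-simple and traverses every edge at most once — which makes the
    cumulative prefix sums consistent with the clipped edge flow.
    Returns None (caller should drop the path) when the endpoints of a
    missing step lie in different components of the complex.
    """
    if router is None:
        router = _ScRouter(sc)
    out = [int(path[0])]
    seen = {int(path[0]): 0}
    for a, b in zip(path[:-1], path[1:]):
        a, b = int(a), int(b)
        if sc.has_edge(a, b):
            seg = [b]
        else:
            seg = router.route(a, b)
            if seg is None:
                return None
            seg = seg[1:]
        for v in seg:
            if v in seen:  # loop erasure
                for w in out[seen[v] + 1 :]:
                    del seen[w]
                del out[seen[v] + 1 :]
            else:
                out.append(v)
                seen[v] = len(out) - 1
    return np.array(out, dtype=int)


def edge_flow(path: np.ndarray, sc: SimplicialComplex) -> np.ndarray:
    """Signed net-traversal indicator of a lifted path.

    +1 where the path crosses an edge along its canonical (low -> high)
    orientation, -1 against it; repeated traversals are clipped to the
    sign of the net traversal count.
    """
    f = np.zeros(sc.n_edges)
    for a, b in zip(path[:-1], path[1:]):
        e = sc.edge_id(int(a), int(b))
        f[e] += 1.0 if a < b else -1.0
    return np.sign(f)


def flow_matrix(paths: list[np.ndarray], sc: SimplicialComplex) -> sp.csc_matrix:
    """Stack path edge flows into an (n_edges, n_paths) sparse matrix."""
    rows, cols, data = [], [], []
    for j, p in enumerate(paths):
        f = edge_flow(p, sc)
        nz = np.flatnonzero(f)
        rows.extend(nz.tolist())
        cols.extend([j] * len(nz))
        data.extend(f[nz].tolist())
    return sp.csc_matrix(
        (data, (rows, cols)), shape=(sc.n_edges, len(paths))
    )


def trajectory_embedding(F: sp.spmatrix | np.ndarray, H: np.ndarray) -> np.ndarray:
    """Project edge flows onto the harmonic basis: returns (n_paths, h).

    This is the transpose of H' F; each row is one trajectory's harmonic
    coordinates.
    """
    ht_f = H.T @ F
    if sp.issparse(ht_f):
        ht_f = ht_f.toarray()
    return np.asarray(ht_f).T


def cluster_trajectories(
    embedding: np.ndarray,
    eps: float | None = None,
    min_samples: int = 5,
    outlier_fraction: float = 0.005,
    terminal_groups_of_paths: np.ndarray | None = None,
) -> np.ndarray:
    """DBSCAN grouping of trajectories in harmonic space.

    ``eps`` defaults to the median 5-NN distance of the embedding.
    Clusters holding fewer than ``outlier_fraction`` of the paths are
    relabelled as outliers (-1), and clusters sharing the same dominant
    terminal group (when given) are merged, keeping the label of the
    larger cluster.
    """
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paths to cluster")
    if eps is None:
        # median 5-NN distance; identical short paths produce exact
        # duplicates, so zero distances are excluded and the estimate is
        # floored at a fraction of the embedding's overall spread
        kk = min(6, n)
        dist, _ = NearestNeighbors(n_neighbors=kk).fit(emb).kneighbors(emb)
        pos = dist[:, -1][dist[:, -1] > 0]
        knn_med = float(np.median(pos)) if pos.size else 0.0
        scale = float(np.median(np.linalg.norm(emb - emb.mean(axis=0), axis=1)))
        eps = max(knn_med, 0.15 * scale, 1e-6)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    if np.all(labels == -1):
        raise ValueError("DBSCAN labelled every path as noise; increase eps")
    # small clusters -> outliers
    min_size = outlier_fraction * n
    for lab in np.unique(labels):
        if lab == -1:
            continue
        if (labels == lab).sum() < min_size:
            labels[labels == lab] = -1
    # merge clusters ending at the same terminal group
    if terminal_groups_of_paths is not None:
        tg = np.asarray(terminal_groups_of_paths)
        dominant: dict[int, int] = {}
        for lab in np.unique(labels):
            if lab == -1:
                continue
            vals, counts = np.unique(tg[labels == lab], return_counts=True)
            dominant[int(lab)] = int(vals[np.argmax(counts)])
        by_terminal: dict[int, list[int]] = {}
        for lab, term in dominant.items():
            by_terminal.setdefault(term, []).append(lab)
        for term, labs in by_terminal.items():
            if len(labs) > 1:
                keep = max(labs, key=lambda L: (labels == L).sum())
                for L in labs:
                    if L != keep:
                        labels[labels == L] = keep
    # relabel compactly, ordered by decreasing cluster size
    final = np.full(n, -1, dtype=int)
    sizes = [
        (int((labels == lab).sum()), int(lab))
        for lab in np.unique(labels)
        if lab != -1
    ]
    for new, (_, lab) in enumerate(sorted(sizes, reverse=True)):
        final[labels == lab] = new
    return final


def build_ensemble(
    raw_paths: list[np.ndarray],
    sc: SimplicialComplex,
    H: np.ndarray,
    seed: int = 0,
    cluster: bool = False,
    allowed_ends: np.ndarray | None = None,
    **cluster_kw,
) -> PathEnsemble:
    """Lift raw walks onto the SC and embed them; optionally cluster.

    ``allowed_ends`` is a boolean mask over vertices: walks terminating
    outside it never reached a detected differentiation end state —
    typically they died at a spurious pseudotime maximum in the noise
    shell behind the root — and are discarded with a warning.
    """
    router = _ScRouter(sc)
    lifted, kept_raw, dropped, early = [], [], 0, 0
    for p in raw_paths:
        if allowed_ends is not None and not allowed_ends[int(p[-1])]:
            early += 1
            continue
        lp = lift_to_complex(p, sc, router)
        if lp is None:
            dropped += 1
            continue
        lifted.append(lp)
        kept_raw.append(p)
    if dropped:
        warnings.warn(
            f"dropped {dropped} paths crossing disconnected SC components",
            stacklevel=2,
        )
    if early:
        warnings.warn(
            f"discarded {early} walks terminating outside every detected "
            "terminal group",
            stacklevel=2,
        )
    flows = flow_matrix(lifted, sc)
    emb = trajectory_embedding(flows, H)
    ens = PathEnsemble(
        paths=kept_raw, lifted=lifted, flows=flows, embedding=emb, seed=seed
    )
    if cluster:
        ens.group_labels = cluster_trajectories(emb, **cluster_kw)
    return ens
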