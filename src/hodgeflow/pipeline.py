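"""End-to-end pipeline: embedding -> differentiation tree.

Stages: locally scaled diffusion kernel and root-seeded pseudotime;
incidence-based gradient smoothing on the pruned kNN graph; 2-D stress
layout; Delaunay complex with long-edge filtering and terminal-to-root
dummy links; harmonic basis of the normalized first-order Hodge
Laplacian; divergence-following walk sampling, harmonic embedding and
DBSCAN grouping; binned cumulative embedding, branching detection, tree
assembly and cell allocation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffusion_graph as dg
from . import hodge
from . import pseudotime_refine as pr
from . import simplicial_complex as scx
from . import trajectories as tj
from . import tree as treemod
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_tree"]


@dataclass
class FitResult:
    """Everything the pipeline computed, plus the resolved configuration."""

    config: RunConfig
    embedding: dg.EmbeddingMatrix
    graph: dg.CellGraph
    potential: np.ndarray  # diffusion potential u (sampled cells)
    pseudotime_raw: np.ndarray
    potential_smooth: np.ndarray  # refined u^s
    pseudotime: np.ndarray  # refined, min-max normalized, roots ~ 0
    gradient: np.ndarray  # per pruned edge, oriented low -> high
    layout: pr.Layout2D
    sc: scx.SimplicialComplex
    terminal_groups: list[np.ndarray]
    norm_l1: hodge.NormalizedL1
    basis: hodge.HarmonicBasis
    ensemble: tj.PathEnsemble
    cumulative: treemod.CumulativeEmbedding
    binned: treemod.BinnedGroups
    branch_bins: dict[tuple[int, int], int]
    tree: treemod.DifferentiationTree
    assignment: pd.DataFrame  # all cells (sampled + propagated)
    sampled_index: np.ndarray  # indices of cells the fit actually used
    visit_counts: pd.Series  # per sampled cell

    @property
    def n_trajectory_groups(self) -> int:
        labs = self.ensemble.group_labels
        return int(len(np.unique(labs[labs >= 0])))

    def cell_stats(self) -> pd.DataFrame:
        ids = [self.embedding.cell_ids[i] for i in self.sampled_index]
        df = pd.DataFrame(
            {
                "cell": ids,
                "pseudotime": self.pseudotime,
                "visits": self.visit_counts.to_numpy(),
            }
        )
        return df.merge(self.assignment, on="cell", how="left")

    def export(self, path) -> None:
        """Write tree, assignments, pseudotime and config under ``path``."""
        import os

        path = os.fspath(path)
        os.makedirs(path, exist_ok=True)
        treemod.export_tree(self.tree, path)
        self.cell_stats().to_csv(
            os.path.join(path, "cell_stats.tsv"), sep="\t", index=False
        )
        self.config.to_json(os.path.join(path, "config.json"))


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-22s %6.2f s", name, t1 - t0)
    return t1


def fit_tree(
    embedding,
    roots,
    config: RunConfig | None = None,
    cell_ids: list[str] | None = None,
) -> FitResult:
    """Infer a differentiation tree from a cell embedding.

    ``embedding`` is an :class:`EmbeddingMatrix` or a cells x dims array;
    ``roots`` a list of root cell identifiers (or integer indices for
    anonymous arrays).  All randomness derives from ``config.seed``.
    """
    cfg = config or RunConfig()
    if not isinstance(embedding, dg.EmbeddingMatrix):
        x = np.asarray(embedding, dtype=float)
        ids = cell_ids if cell_ids is not None else [f"c{i}" for i in range(len(x))]
        embedding = dg.EmbeddingMatrix(x, ids)
    root_idx = (
        np.asarray(roots, dtype=int)
        if np.issubdtype(np.asarray(roots).dtype, np.integer)
        else embedding.index_of(list(roots))
    )

    full = embedding
    if cfg.downsample_fraction is not None and cfg.downsample_fraction < 1:
        rng = np.random.default_rng(cfg.seed + 11)
        n_keep = max(int(round(full.n_cells * cfg.downsample_fraction)), 10)
        keep = rng.choice(full.n_cells, size=n_keep, replace=False)
        keep = np.unique(np.concatenate([keep, root_idx]))
        sampled_index = np.sort(keep)
    else:
        sampled_index = np.arange(full.n_cells)
    sub_ids = [full.cell_ids[i] for i in sampled_index]
    emb = dg.EmbeddingMatrix(full.values[sampled_index], sub_ids)
    pos_of = {int(i): p for p, i in enumerate(sampled_index)}
    roots_sub = np.array([pos_of[int(i)] for i in root_idx])

    t0 = time.perf_counter()
    graph = dg.local_scaling_kernel(emb, scale_neighbor=cfg.scale_neighbor)
    op = dg.transition_matrix(graph)
    u, pt_raw = dg.diffusion_pseudotime(op, roots_sub, steps=cfg.steps)
    # diffusion mass decays like exp(-d^2/4s) in graph distance d from the
    # roots (Varadhan regime), so sqrt(log u_max - log u) is ~linear in
    # distance; refining that potential keeps the pseudotime scale usable
    # for binning and persistence thresholds at every depth
    logu = np.log(np.clip(u, u[u > 0].min(), None))
    lu = -np.sqrt(logu.max() - logu)
    t0 = _stage("diffusion", t0)

    graph = dg.knn_prune(graph, k=cfg.knn_k, potential=lu)
    pair = pr.IncidencePair.from_edges(graph.knn_edges, emb.n_cells)
    div = pr.complete_graph_divergence(lu)
    w_p = pr.fit_pruned_gradients(pair, None, lam=cfg.lam, divergence=div)
    u_s, _ = pr.fit_potentials(pair, w_p, roots=roots_sub)
    rng_u = u_s.max() - u_s.min()
    pt = (u_s.max() - u_s) / (rng_u if rng_u > 0 else 1.0)
    grad_pt = pair.B1_pruned.T @ pt  # ascends differentiation
    t0 = _stage("pseudotime refine", t0)

    edge_len = np.linalg.norm(
        emb.values[graph.knn_edges[:, 0]] - emb.values[graph.knn_edges[:, 1]], axis=1
    )
    layout = pr.layout_2d(
        graph.knn_edges,
        emb.n_cells,
        weights=edge_len,
        seed=cfg.seed,
        max_iter=cfg.layout_max_iter,
        eps=cfg.layout_eps,
    )
    t0 = _stage("layout", t0)

    raw_paths = tj.sample_random_walks(
        graph.knn_edges,
        grad_pt,
        pt,
        n=cfg.n_paths,
        m_roots=cfg.m,
        seed=cfg.seed + 101,
    )
    ends = np.array([int(p[-1]) for p in raw_paths])
    t0 = _stage("walk sampling", t0)

    sc = scx.delaunay_complex(layout.coords, cell_ids=sub_ids)
    if cfg.edge_filter == "quantile":
        sc = scx.filter_edges_quantile(
            sc, factor=cfg.filter_factor, q=cfg.filter_quantile
        )
    else:
        thr = scx.ph0_radius_threshold(layout.coords, factor=cfg.radius_factor)
        sc = scx.filter_edges_radius(sc, thr.threshold)
    groups = scx.find_terminal_groups(
        graph.knn_edges,
        pt,
        persistence=cfg.terminal_persistence,
        min_peak_pt=cfg.terminal_min_peak_pt,
    )
    # keep groups absorbing a minimum share of the sampled differentiation
    # flux: spurious pseudotime maxima trap almost no walks.  Fractions are
    # over walks ending in any candidate group's basin.
    end_counts = np.bincount(ends, minlength=emb.n_cells)
    in_any = sum(int(end_counts[np.asarray(g)].sum()) for g in groups)
    if in_any and cfg.group_min_flux > 0:
        kept_groups = [
            g
            for g in groups
            if end_counts[np.asarray(g)].sum() / in_any >= cfg.group_min_flux
        ]
        if kept_groups:
            groups = kept_groups
    allowed_ends = np.zeros(emb.n_cells, dtype=bool)
    for g in groups:
        allowed_ends[np.asarray(g)] = True
    sc = scx.add_terminal_root_links(sc, pt, m=cfg.m, terminal_groups=groups)
    t0 = _stage("simplicial complex", t0)

    b1, b2 = scx.boundary_matrices(sc)
    norm = hodge.normalized_l1(b1, b2)
    basis = hodge.harmonic_basis(
        norm,
        tolerance=cfg.eigen_tolerance,
        k_max=max(2 * len(groups) + 6, 12),
        seed=cfg.seed,
    )
    t0 = _stage("harmonic basis", t0)

    ensemble = tj.build_ensemble(
        raw_paths,
        sc,
        basis.H,
        seed=cfg.seed + 101,
        allowed_ends=allowed_ends,
    )
    # terminal group of each walk end: nearest group peak in the layout,
    # used to merge DBSCAN clusters sharing an end state
    tg = None
    if groups:
        from sklearn.neighbors import NearestNeighbors

        peaks = np.array([g[np.argmax(pt[g])] for g in groups], dtype=int)
        nn = NearestNeighbors(n_neighbors=1).fit(layout.coords[peaks])
        ends = np.array([int(p[-1]) for p in ensemble.lifted])
        tg = nn.kneighbors(layout.coords[ends], return_distance=False)[:, 0]
    ensemble.group_labels = tj.cluster_trajectories(
        ensemble.embedding,
        eps=cfg.dbscan_eps,
        min_samples=cfg.dbscan_min_samples,
        outlier_fraction=cfg.outlier_fraction,
        terminal_groups_of_paths=tg,
    )
    t0 = _stage("trajectories", t0)

    cum = treemod.cumulative_embedding(ensemble.lifted, sc, basis.H)
    gcoords = treemod.group_edge_coordinates(cum, ensemble.group_labels, sc.n_edges)
    e_pt = treemod.edge_pseudotime(sc, pt)
    binned = treemod.bin_by_pseudotime(gcoords, e_pt, p=cfg.bins)
    branch_bins = treemod.detect_branching_points(binned, sigma=cfg.sigma)
    tree = treemod.assemble_tree(branch_bins, binned, sigma=cfg.sigma)
    assignment = treemod.allocate_cells(tree, binned, cum, ensemble, sc, pt)
    tree.cell_assignment = assignment
    t0 = _stage("tree", t0)

    visit = pd.Series(
        ensemble.visit_counts(emb.n_cells), index=sub_ids, name="visits"
    )

    if len(sampled_index) < full.n_cells:
        assignment = _propagate_assignment(
            assignment, full, sampled_index
        )
        tree.cell_assignment = assignment

    return FitResult(
        config=cfg,
        embedding=full,
        graph=graph,
        potential=u,
        pseudotime_raw=pt_raw,
        potential_smooth=u_s,
        pseudotime=pt,
        gradient=grad_pt,
        layout=layout,
        sc=sc,
        terminal_groups=groups,
        norm_l1=norm,
        basis=basis,
        ensemble=ensemble,
        cumulative=cum,
        binned=binned,
        branch_bins=branch_bins,
        tree=tree,
        assignment=assignment,
        sampled_index=sampled_index,
        visit_counts=visit,
    )


def _propagate_assignment(
    assignment: pd.DataFrame,
    full: dg.EmbeddingMatrix,
    sampled_index: np.ndarray,
) -> pd.DataFrame:
    """Give unsampled cells the branch of their nearest sampled neighbour."""
    from sklearn.neighbors import NearestNeighbors

    mask = np.zeros(full.n_cells, dtype=bool)
    mask[sampled_index] = True
    rest = np.flatnonzero(~mask)
    if rest.size == 0:
        return assignment
    nn = NearestNeighbors(n_neighbors=1).fit(full.values[sampled_index])
    _, idx = nn.kneighbors(full.values[rest])
    src = assignment.set_index("cell")
    rows = []
    for r, j in zip(rest, idx[:, 0]):
        donor = src.iloc[j]
        rows.append(
            {
                "cell": full.cell_ids[r],
                "group": donor["group"],
                "branch": donor["branch"],
                "position": donor["position"],
            }
        )
    out = pd.concat([assignment, pd.DataFrame(rows)], ignore_index=True)
    order = {c: i for i, c in enumerate(full.cell_ids)}
    return (
        out.assign(_o=out["cell"].map(order))
        .sort_values("_o")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
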