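"""Differentiation-tree inference from cumulative trajectory embeddings.

Each sampled path traces a curve in harmonic space through its prefix
sums (cumulative embedding); averaging the curve points that visit an
edge gives per-edge coordinates for every trajectory group.  Edges are
binned by pseudotime, each (group, bin) cell is summarized by a backbone
(mean coordinate) and compactness (mean pairwise distance), and two
groups branch at the last bin where their compactness-scaled backbones
are closer than a threshold sigma.  Merging group pairs bottom-up (the
highest branching bin first) assembles the differentiation tree; cells
are then allocated to branches by proximity to the group backbones.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simplicial_complex import SimplicialComplex
from .trajectories import PathEnsemble

__all__ = [
    "CumulativeEmbedding",
    "BinnedGroups",
    "Milestone",
    "Branch",
    "DifferentiationTree",
    "cumulative_embedding",
    "group_edge_coordinates",
    "edge_pseudotime",
    "bin_by_pseudotime",
    "group_distance",
    "detect_branching_points",
    "assemble_tree",
    "allocate_cells",
    "export_tree",
    "read_tree_json",
]


@dataclass
class CumulativeEmbedding:
    """Per-path prefix-sum curves in harmonic space.

    ``curves[i][s - 1]`` is v_s, the harmonic image of the first s signed
    step indicators of path i; the final row equals the path's trajectory
    embedding exactly.
    """

    curves: list[np.ndarray]  # each (S_i, h)
    step_edges: list[np.ndarray]  # each (S_i,) edge ids
    step_signs: list[np.ndarray]  # each (S_i,) +-1


def _path_steps(path: np.ndarray, sc: SimplicialComplex) -> tuple[np.ndarray, np.ndarray]:
    a, b = path[:-1], path[1:]
    eids = np.array([sc.edge_id(int(x), int(y)) for x, y in zip(a, b)], dtype=int)
    signs = np.where(a < b, 1.0, -1.0)
    return eids, signs


def cumulative_embedding(
    lifted_paths: list[np.ndarray], sc: SimplicialComplex, H: np.ndarray
) -> CumulativeEmbedding:
    """Prefix sums of signed step indicators, projected onto H."""
    curves, all_eids, all_signs = [], [], []
    for p in lifted_paths:
        eids, signs = _path_steps(p, sc)
        steps = H[eids] * signs[:, None]
        curves.append(np.cumsum(steps, axis=0))
        all_eids.append(eids)
        all_signs.append(signs)
    return CumulativeEmbedding(curves=curves, step_edges=all_eids, step_signs=all_signs)


def group_edge_coordinates(
    cum: CumulativeEmbedding,
    group_labels: np.ndarray,
    n_edges: int,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Mean cumulative coordinate of every edge, per trajectory group.

    Returns {group: (edge_ids, coords)} where ``coords[k]`` is the mean of
    the curve points v_s over all visits of edge ``edge_ids[k]`` by the
    group's paths.
    """
    h = cum.curves[0].shape[1] if cum.curves else 0
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for g in np.unique(group_labels):
        if g == -1:
            continue
        sums = np.zeros((n_edges, h))
        counts = np.zeros(n_edges)
        for i in np.flatnonzero(group_labels == g):
            np.add.at(sums, cum.step_edges[i], cum.curves[i])
            np.add.at(counts, cum.step_edges[i], 1.0)
        eids = np.flatnonzero(counts > 0)
        out[int(g)] = (eids, sums[eids] / counts[eids, None])
    return out


def edge_pseudotime(sc: SimplicialComplex, pseudotime: np.ndarray) -> np.ndarray:
    """Edge pseudotime: mean of the two endpoint pseudotimes."""
    pt = np.asarray(pseudotime, dtype=float)
    return 0.5 * (pt[sc.edges[:, 0]] + pt[sc.edges[:, 1]])


@dataclass
class BinnedGroups:
    """Per-(group, bin) edge coordinates with backbone and compactness."""

    p: int
    boundaries: np.ndarray  # (p + 1,) pseudotime bin edges
    groups: list[int]
    coords: dict[tuple[int, int], np.ndarray]  # (group, bin) -> (M, h)
    backbone: dict[tuple[int, int], np.ndarray]  # per-bin mean coordinate
    compactness: dict[tuple[int, int], float]  # mean pairwise distance
    last_bin: dict[int, int]  # highest populated bin per group
    clamped: int = 0  # edges outside the reference range

    def has(self, g: int, k: int) -> bool:
        return (g, k) in self.backbone


def bin_by_pseudotime(
    group_coords: dict[int, tuple[np.ndarray, np.ndarray]],
    edge_pt: np.ndarray,
    p: int = 10,
) -> BinnedGroups:
    """Bin each group's edges by pseudotime on a shared grid.

    One grid of ``p`` bins spans the union of all groups' edge
    pseudotimes, indexed in increasing pseudotime; every group populates
    only the bins its edges cover, and group-to-group distances are
    evaluated in co-populated bins.  (Anchoring the grid to the
    shortest trajectory group instead collapses everything beyond its
    range into the last bin, destroying branch resolution on deep trees.)
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not group_coords:
        raise ValueError("no trajectory groups to bin")
    all_pt = np.concatenate([edge_pt[eids] for eids, _ in group_coords.values()])
    lo, hi = float(all_pt.min()), float(all_pt.max())
    if hi <= lo:
        hi = lo + 1e-12
    boundaries = np.linspace(lo, hi, p + 1)
    coords: dict[tuple[int, int], np.ndarray] = {}
    backbone: dict[tuple[int, int], np.ndarray] = {}
    compactness: dict[tuple[int, int], float] = {}
    last_bin: dict[int, int] = {}
    clamped = 0
    for g, (eids, xy) in group_coords.items():
        pt = edge_pt[eids]
        k = np.searchsorted(boundaries, pt, side="right") - 1
        clamped += int(((pt < lo) | (pt > hi)).sum())
        k = np.clip(k, 0, p - 1)
        for kk in np.unique(k):
            sel = xy[k == kk]
            coords[(g, int(kk))] = sel
            backbone[(g, int(kk))] = sel.mean(axis=0)
            m = len(sel)
            if m == 1:
                compactness[(g, int(kk))] = 0.0
            else:
                d = np.sqrt(((sel[:, None, :] - sel[None, :, :]) ** 2).sum(-1))
                compactness[(g, int(kk))] = float(d.sum() / (m * m))
        last_bin[g] = int(k.max())
    if clamped:
        warnings.warn(
            f"{clamped} edges outside the reference pseudotime range were "
            "clamped to the end bins",
            stacklevel=2,
        )
    return BinnedGroups(
        p=p,
        boundaries=boundaries,
        groups=sorted(group_coords),
        coords=coords,
        backbone=backbone,
        compactness=compactness,
        last_bin=last_bin,
        clamped=clamped,
    )


def _safe_sigma(binned: BinnedGroups, g: int, k: int) -> float:
    s = binned.compactness[(g, k)]
    if s > 0:
        return s
    pos = [v for v in binned.compactness.values() if v > 0]
    sub = float(np.median(pos)) if pos else 1.0
    warnings.warn(
        f"singleton bin (group {g}, bin {k}); substituting global median "
        "compactness",
        stacklevel=3,
    )
    return sub


def group_distance(binned: BinnedGroups, i: int, j: int, k: int) -> float:
    """Compactness-scaled backbone distance between two groups at bin k."""
    if not (binned.has(i, k) and binned.has(j, k)):
        raise ValueError(f"groups {i}, {j} not both populated at bin {k}")
    bi = binned.backbone[(i, k)] / _safe_sigma(binned, i, k)
    bj = binned.backbone[(j, k)] / _safe_sigma(binned, j, k)
    return float(np.linalg.norm(bi - bj))


def detect_branching_points(
    binned: BinnedGroups, sigma: float = 1.0
) -> dict[tuple[int, int], int]:
    """Branching bin per group pair.

    Traversing bins in decreasing order, the branching bin is the first
    (largest) k at which the two groups are closer than ``sigma``; pairs
    that never come that close share only the root and branch at bin 0.
    """
    out: dict[tuple[int, int], int] = {}
    gs = binned.groups
    for a in range(len(gs)):
        for b in range(a + 1, len(gs)):
            i, j = gs[a], gs[b]
            bin_k = 0
            for k in range(binned.p - 1, -1, -1):
                if binned.has(i, k) and binned.has(j, k):
                    if group_distance(binned, i, j, k) < sigma:
                        bin_k = k
                        break
            out[(i, j)] = bin_k
    return out


@dataclass
class Milestone:
    id: str
    kind: str  # "root" | "branching" | "leaf"
    bin: int  # root = -1
    pseudotime: float


@dataclass
class Branch:
    id: str
    from_milestone: str
    to_milestone: str
    groups: tuple[int, ...]
    bin_lo: int  # first bin covered
    bin_hi: int  # last bin covered
    pt_lo: float
    pt_hi: float


@dataclass
class DifferentiationTree:
    """Milestone network with branch membership of trajectory groups."""

    milestones: list[Milestone]
    branches: list[Branch]
    sigma_threshold: float
    boundaries: np.ndarray
    cell_assignment: pd.DataFrame | None = None
    merge_order: list[tuple[tuple[int, ...], tuple[int, ...], int]] = field(
        default_factory=list
    )

    @property
    def n_leaves(self) -> int:
        return sum(1 for m in self.milestones if m.kind == "leaf")

    def milestone(self, mid: str) -> Milestone:
        return next(m for m in self.milestones if m.id == mid)

    def branch_of_group_bin(self, g: int, k: int) -> Branch | None:
        for br in self.branches:
            if g in br.groups and br.bin_lo <= k <= br.bin_hi:
                return br
        cands = [br for br in self.branches if g in br.groups]
        if not cands:
            return None
        return min(cands, key=lambda br: min(abs(k - br.bin_lo), abs(k - br.bin_hi)))

    def newick(self) -> str:
        children: dict[str, list[tuple[str, float]]] = {}
        root = next(m for m in self.milestones if m.kind == "root")
        for br in self.branches:
            length = max(br.pt_hi - br.pt_lo, 0.0)
            children.setdefault(br.from_milestone, []).append((br.to_milestone, length))

        def rec(mid: str) -> str:
            kids = children.get(mid, [])
            if not kids:
                return mid
            inner = ",".join(f"{rec(c)}:{ln:.6g}" for c, ln in kids)
            return f"({inner}){mid}"

        return rec(root.id) + ";"


def assemble_tree(
    branch_bins: dict[tuple[int, int], int],
    binned: BinnedGroups,
    sigma: float = 1.0,
) -> DifferentiationTree:
    """Bottom-up merge of trajectory groups into a differentiation tree.

    The pair of clusters with the highest branching bin merges first
    (maximum over cross-group pairs; ties break on the smallest group
    indices).  Each merge creates a branching milestone; every cluster
    becomes a branch running from the milestone that consumed it back up
    to the milestone (leaf or earlier merge) that created it.
    """
    groups = list(binned.groups)
    bnd = binned.boundaries

    def bin_end(k: int) -> float:
        return float(bnd[min(k + 1, len(bnd) - 1)])

    milestones: list[Milestone] = [Milestone("root", "root", -1, float(bnd[0]))]
    branches: list[Branch] = []
    merge_order: list[tuple[tuple[int, ...], tuple[int, ...], int]] = []

    # leaf milestone per group, at its last populated bin
    creation: dict[frozenset, tuple[str, int]] = {}
    for g in groups:
        lb = binned.last_bin[g]
        mid = f"leaf_{g}"
        milestones.append(Milestone(mid, "leaf", lb, bin_end(lb)))
        creation[frozenset([g])] = (mid, lb)

    clusters: list[frozenset] = [frozenset([g]) for g in groups]

    def pair_bin(ca: frozenset, cb: frozenset) -> int:
        return max(
            branch_bins[(min(i, j), max(i, j))] for i in ca for j in cb
        )

    n_merge = 0
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                b = pair_bin(clusters[x], clusters[y])
                key = (b, -min(clusters[x] | clusters[y]), -x, -y)
                if best is None or key > best[0]:
                    best = (key, x, y)
        _, x, y = best
        ca, cb = clusters[x], clusters[y]
        k = pair_bin(ca, cb)
        mid = f"branching_{n_merge}"
        n_merge += 1
        milestones.append(Milestone(mid, "branching", k, bin_end(k)))
        for c in (ca, cb):
            cmid, cbin = creation[c]
            branches.append(
                Branch(
                    id=f"b_{cmid}",
                    from_milestone=mid,
                    to_milestone=cmid,
                    groups=tuple(sorted(c)),
                    bin_lo=k + 1,
                    bin_hi=max(cbin, k + 1),
                    pt_lo=bin_end(k),
                    pt_hi=bin_end(cbin),
                )
            )
        merged = ca | cb
        creation[merged] = (mid, k)
        merge_order.append((tuple(sorted(ca)), tuple(sorted(cb)), k))
        clusters = [c for z, c in enumerate(clusters) if z not in (x, y)] + [merged]

    final = clusters[0]
    fmid, fbin = creation[final]
    branches.append(
        Branch(
            id="b_trunk",
            from_milestone="root",
            to_milestone=fmid,
            groups=tuple(sorted(final)),
            bin_lo=0,
            bin_hi=max(fbin, 0),
            pt_lo=float(bnd[0]),
            pt_hi=bin_end(fbin) if len(groups) > 1 else bin_end(fbin),
        )
    )
    return DifferentiationTree(
        milestones=milestones,
        branches=branches,
        sigma_threshold=sigma,
        boundaries=bnd,
        merge_order=merge_order,
    )


def allocate_cells(
    tree: DifferentiationTree,
    binned: BinnedGroups,
    cum: CumulativeEmbedding,
    ensemble: PathEnsemble,
    sc: SimplicialComplex,
    pseudotime: np.ndarray,
) -> pd.DataFrame:
    """Assign every cell to a branch of the tree.

    Each cell is first claimed by the trajectory group whose walks visit
    it most often (majority vote over the path ensemble).  Cells no walk
    visits are located at the mean cumulative coordinate of their
    incident (non-dummy) visited edges and fall to the group with the
    nearest backbone at their pseudotime bin; cells without even that
    inherit the branch of the nearest located cell in the layout.  The
    assigned branch is the tree edge carrying the chosen group over the
    cell's bin, with the within-branch position taken from pseudotime.
    """
    n = sc.n_vertices
    h = cum.curves[0].shape[1] if cum.curves else 1
    # overall per-edge mean cumulative coordinate (non-outlier paths)
    sums = np.zeros((sc.n_edges, h))
    counts = np.zeros(sc.n_edges)
    labels = ensemble.group_labels
    for i, (eids, curve) in enumerate(zip(cum.step_edges, cum.curves)):
        if labels is not None and labels[i] == -1:
            continue
        np.add.at(sums, eids, curve)
        np.add.at(counts, eids, 1.0)
    edge_coord = np.zeros((sc.n_edges, h))
    seen = counts > 0
    edge_coord[seen] = sums[seen] / counts[seen, None]

    # per-cell coordinates from incident non-dummy visited edges
    incid: list[list[int]] = [[] for _ in range(n)]
    for e, (a, b) in enumerate(sc.edges):
        if sc.dummy_edges[e] or not seen[e]:
            continue
        incid[a].append(e)
        incid[b].append(e)
    cell_coord = np.full((n, h), np.nan)
    dummy_only = 0
    for v in range(n):
        if incid[v]:
            cell_coord[v] = edge_coord[incid[v]].mean(axis=0)
        else:
            dummy_only += 1
    if dummy_only:
        warnings.warn(
            f"{dummy_only} cells have no visited non-dummy incident edge; "
            "assigning via nearest located cell",
            stacklevel=2,
        )

    pt = np.asarray(pseudotime, dtype=float)
    bnd = binned.boundaries
    kbin = np.clip(np.searchsorted(bnd, pt, side="right") - 1, 0, binned.p - 1)

    # majority vote of visiting walks
    n_groups = max(binned.groups) + 1 if binned.groups else 0
    votes = np.zeros((n, n_groups))
    for i, p in enumerate(ensemble.lifted):
        g = -1 if labels is None else int(labels[i])
        if g < 0 or g >= n_groups:
            continue
        votes[np.unique(p), g] += 1.0
    voted = votes.sum(axis=1) > 0
    group_of = np.full(n, -1, dtype=int)
    group_of[voted] = np.argmax(votes[voted], axis=1)

    located = np.flatnonzero(~voted & ~np.isnan(cell_coord[:, 0]))
    for v in located:
        k = int(kbin[v])
        best_g, best_d = -1, np.inf
        for g in binned.groups:
            kk = k
            if not binned.has(g, kk):
                avail = [q for q in range(binned.p) if binned.has(g, q)]
                if not avail:
                    continue
                kk = min(avail, key=lambda q: abs(q - k))
            d = float(np.linalg.norm(cell_coord[v] - binned.backbone[(g, kk)]))
            if d < best_d:
                best_d, best_g = d, g
        group_of[v] = best_g
    located = np.flatnonzero(group_of >= 0)
    if len(located) and sc.layout is not None:
        missing = np.flatnonzero(group_of < 0)
        if missing.size:
            from sklearn.neighbors import NearestNeighbors

            nn = NearestNeighbors(n_neighbors=1).fit(sc.layout[located])
            _, idx = nn.kneighbors(sc.layout[missing])
            group_of[missing] = group_of[located[idx[:, 0]]]

    rows = []
    ids = sc.cell_ids if sc.cell_ids is not None else [f"c{i}" for i in range(n)]
    for v in range(n):
        g = int(group_of[v])
        br = tree.branch_of_group_bin(g, int(kbin[v])) if g >= 0 else None
        if br is None:
            rows.append((ids[v], g, "unassigned", np.nan))
            continue
        span = br.pt_hi - br.pt_lo
        pos = 0.5 if span <= 0 else float(np.clip((pt[v] - br.pt_lo) / span, 0, 1))
        rows.append((ids[v], g, br.id, pos))
    df = pd.DataFrame(rows, columns=["cell", "group", "branch", "position"])
    return df


def export_tree(
    tree: DifferentiationTree,
    path: str | os.PathLike,
) -> None:
    """Write milestone network, cell tables, newick topology and JSON."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    net = pd.DataFrame(
        [
            {
                "from": br.from_milestone,
                "to": br.to_milestone,
                "length": max(br.pt_hi - br.pt_lo, 0.0),
                "branch": br.id,
            }
            for br in tree.branches
        ]
    )
    net.to_csv(os.path.join(path, "milestone_network.tsv"), sep="\t", index=False)
    if tree.cell_assignment is not None:
        ca = tree.cell_assignment
        ca.to_csv(os.path.join(path, "cell_branches.tsv"), sep="\t", index=False)
        rows = []
        bmap = {br.id: br for br in tree.branches}
        for _, r in ca.iterrows():
            br = bmap.get(r["branch"])
            if br is None or not np.isfinite(r["position"]):
                continue
            rows.append((r["cell"], br.from_milestone, 1.0 - r["position"]))
            rows.append((r["cell"], br.to_milestone, r["position"]))
        pd.DataFrame(rows, columns=["cell", "milestone", "percentage"]).to_csv(
            os.path.join(path, "milestone_percentages.tsv"), sep="\t", index=False
        )
    with open(os.path.join(path, "tree.newick"), "w") as f:
        f.write(tree.newick() + "\n")
    payload = {
        "sigma_threshold": tree.sigma_threshold,
        "boundaries": np.asarray(tree.boundaries).tolist(),
        "milestones": [
            {"id": m.id, "kind": m.kind, "bin": m.bin, "pseudotime": m.pseudotime}
            for m in tree.milestones
        ],
        "branches": [
            {
                "id": br.id,
                "from": br.from_milestone,
                "to": br.to_milestone,
                "groups": list(br.groups),
                "bin_lo": br.bin_lo,
                "bin_hi": br.bin_hi,
                "pt_lo": br.pt_lo,
                "pt_hi": br.pt_hi,
            }
            for br in tree.branches
        ],
    }
    with open(os.path.join(path, "tree.json"), "w") as f:
        json.dump(payload, f, indent=1)


def read_tree_json(path: str | os.PathLike) -> DifferentiationTree:
    """Load a tree written by :func:`export_tree` (without cell tables)."""
    with open(os.path.join(os.fspath(path), "tree.json")) as f:
        payload = json.load(f)
    milestones = [
        Milestone(m["id"], m["kind"], m["bin"], m["pseudotime"])
        for m in payload["milestones"]
    ]
    branches = [
        Branch(
            id=b["id"],
            from_milestone=b["from"],
            to_milestone=b["to"],
            groups=tuple(b["groups"]),
            bin_lo=b["bin_lo"],
            bin_hi=b["bin_hi"],
            pt_lo=b["pt_lo"],
            pt_hi=b["pt_hi"],
        )
        for b in payload["branches"]
    ]
    return DifferentiationTree(
        milestones=milestones,
        branches=branches,
        sigma_threshold=payload["sigma_threshold"],
        boundaries=np.asarray(payload["boundaries"]),
    )
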