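"""Synthetic tree-structured point clouds with known branch ground truth.

Two generators are provided: a diffusion-limited-aggregation (DLA) tree
generator producing multi-branch random-walk backbones in high-dimensional
feature space, and a geometric multifurcation cloud (a root segment fanning
into terminal arms) used for small, fully controlled pipeline tests.  A
fixed 8-vertex toy simplicial complex is included for boundary-operator
arithmetic checks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DlaTree",
    "ToyComplexFixture",
    "gen_dla_tree",
    "gen_bifurcation_cloud",
    "gen_multifurcation_cloud",
    "toy_complex",
    "ground_truth_export",
    "read_ground_truth",
]


@dataclass
class DlaTree:
    """A branching point cloud with per-point branch labels.

    ``points`` carries the observed (noisy) coordinates, ``backbone`` the
    noiseless walk positions.  ``branch_parent[b]`` is the branch a branch
    was grown from (−1 for the root branch) and ``attach_point[b]`` the
    index (into ``points``) of the attachment site.
    """

    points: np.ndarray
    branch_id: np.ndarray
    branch_parent: np.ndarray
    backbone: np.ndarray
    attach_point: np.ndarray
    seed: int
    noise_sd: float
    n_branch: int
    branch_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.branch_names:
            self.branch_names = [f"branch{b}" for b in range(self.n_branch)]

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]

    @property
    def root_index(self) -> int:
        """Index of the first point of the root branch (the walk origin)."""
        return int(np.flatnonzero(self.branch_id == 0)[0])

    @property
    def n_leaves(self) -> int:
        """Number of terminal branches (walk tips)."""
        return self.n_branch

    @property
    def n_segments(self) -> int:
        """Realized segment count after splitting parents at attachments.

        Each attachment at an interior point of a branch splits it in two,
        so a tree grown with ``n_branch`` walks typically realizes more
        segments than walks.
        """
        interior = 0
        for b in range(1, self.n_branch):
            at = self.attach_point[b]
            mask = np.flatnonzero(self.branch_id == self.branch_id[at])
            if at != mask[0] and at != mask[-1]:
                interior += 1
        return self.n_branch + interior

    def tip_indices(self) -> np.ndarray:
        """Index of the last (tip) point of every branch."""
        return np.array(
            [np.flatnonzero(self.branch_id == b)[-1] for b in range(self.n_branch)]
        )

    def realized_leaf_mask(self, separation: float = 1.5) -> np.ndarray:
        """Which branch tips are resolvable as distinct terminal states.

        A later branch attaching near a parent's tip absorbs that tip: the
        remaining stub is buried inside the noise ball and no longer a
        distinct end state.  A tip counts as a realized leaf when the
        backbone displacement from the last attachment point on its branch
        to the tip exceeds ``separation`` x the pairwise-noise scale
        noise_sd * sqrt(2 * n_features) (the typical distance between two
        noisy copies of the same backbone point).  With zero noise every
        tip with a non-degenerate stub is a leaf.
        """
        thr = separation * self.noise_sd * np.sqrt(2.0 * self.n_features)
        tips = self.tip_indices()
        mask = np.ones(self.n_branch, dtype=bool)
        for b in range(self.n_branch):
            att = [
                int(self.attach_point[c])
                for c in range(self.n_branch)
                if self.branch_parent[c] == b
            ]
            if not att:
                continue
            last = max(att)
            disp = float(
                np.linalg.norm(self.backbone[tips[b]] - self.backbone[last])
            )
            mask[b] = disp > thr
        return mask

    def n_realized_leaves(self, separation: float = 1.5) -> int:
        return int(self.realized_leaf_mask(separation).sum())

    def realized_branch_labels(self, separation: float = 1.5) -> np.ndarray:
        """Per-point labels of the realized tree's branches.

        A realized branch is a maximal stretch of the backbone whose
        downstream set of realized leaves (see :meth:`realized_leaf_mask`)
        is constant — i.e. the segments between consecutive realized
        branching events, with degree-2 joints contracted.  Points on an
        absorbed tip stub inherit the label of the stretch just below
        their last attachment (they are indistinguishable from the
        attaching child's start).  Walk-level branch ids are a misleading
        comparison target whenever stubs are absorbed: an exactly
        recovered realized tree still mixes walk ids on contracted
        stretches.
        """
        mask = self.realized_leaf_mask(separation)
        L = self.n_points // self.n_branch
        children: dict[int, list[tuple[int, int]]] = {b: [] for b in range(self.n_branch)}
        for c in range(1, self.n_branch):
            b = int(self.branch_parent[c])
            children[b].append((int(self.attach_point[c]) % L, c))
        reach_sets: list[frozenset | None] = [None] * self.n_branch
        labels_per_branch: list[np.ndarray] = [None] * self.n_branch  # type: ignore
        keys: dict[frozenset, int] = {}

        def key_of(s: frozenset) -> int:
            if s not in keys:
                keys[s] = len(keys)
            return keys[s]

        # children always have a larger branch index than their parent
        for b in range(self.n_branch - 1, -1, -1):
            acc = frozenset([b]) if mask[b] else frozenset()
            att = sorted(children[b], reverse=True)
            lab = np.empty(L, dtype=int)
            pos = L - 1
            pending_empty_hi = pos if not mask[b] else -1
            for q, c in att:
                child_set = reach_sets[c]
                for i in range(pos, q - 1, -1):
                    lab[i] = key_of(acc)
                pos = q - 1
                acc = acc | child_set
                if pending_empty_hi >= 0:
                    # absorbed stub: relabel with the post-attachment set
                    lab[q : pending_empty_hi + 1] = key_of(acc)
                    pending_empty_hi = -1
            for i in range(pos, -1, -1):
                lab[i] = key_of(acc)
            reach_sets[b] = acc
            labels_per_branch[b] = lab
        return np.concatenate(labels_per_branch)


@dataclass(frozen=True)
class ToyComplexFixture:
    """The fixed 8-vertex / 10-edge / 3-triangle reference complex."""

    vertices: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    triangles: tuple[tuple[int, int, int], ...]


def gen_dla_tree(
    n_branch: int,
    branch_length: int,
    n_features: int = 100,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> DlaTree:
    """Grow a DLA tree: branches are cumulative standard-normal walks.

    The root branch starts at the origin.  Every further branch starts from
    a uniformly chosen point of a uniformly chosen existing branch and
    performs ``branch_length`` steps of an i.i.d. standard-normal random
    walk in ``n_features`` dimensions.  Isotropic Gaussian noise with
    standard deviation ``noise_sd`` is then added to every coordinate.

    Identical arguments and seed give bit-identical output.
    """
    if n_branch < 1:
        raise ValueError("n_branch must be >= 1")
    if branch_length < 2:
        raise ValueError("branch_length must be >= 2")
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    rng = np.random.default_rng(seed)
    branches: list[np.ndarray] = []
    parent = np.full(n_branch, -1, dtype=int)
    attach = np.full(n_branch, -1, dtype=int)
    offsets = [0]
    for b in range(n_branch):
        if b == 0:
            start = np.zeros(n_features)
        else:
            pb = int(rng.integers(b))
            pi = int(rng.integers(branch_length))
            parent[b] = pb
            attach[b] = offsets[pb] + pi
            start = branches[pb][pi]
        steps = rng.standard_normal((branch_length, n_features))
        walk = start + np.cumsum(steps, axis=0)
        branches.append(walk)
        offsets.append(offsets[-1] + branch_length)
    backbone = np.vstack(branches)
    branch_id = np.repeat(np.arange(n_branch), branch_length)
    noise = rng.standard_normal(backbone.shape) * noise_sd if noise_sd > 0 else 0.0
    return DlaTree(
        points=backbone + noise,
        branch_id=branch_id,
        branch_parent=parent,
        backbone=backbone,
        attach_point=attach,
        seed=seed,
        noise_sd=noise_sd,
        n_branch=n_branch,
    )


def gen_multifurcation_cloud(
    n_points: int,
    n_arms: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_dims: int = 2,
) -> DlaTree:
    """A root segment splitting into ``n_arms`` straight terminal arms.

    The root runs from the origin to (0, 1); arms of unit length fan out
    from the split point with equal angular spacing.  Points are spread
    uniformly along each segment and perturbed by isotropic Gaussian noise.
    Ground-truth labels are branch 0 (root) and branches 1..n_arms.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    rng = np.random.default_rng(seed)
    n_branch = n_arms + 1
    per = n_points // n_branch
    counts = [n_points - per * n_arms] + [per] * n_arms
    split = np.zeros(n_dims)
    split[1] = 1.0
    segs = []
    branch_id = []
    # arms fan over a 120 degree cone around "up"
    angles = (
        [np.pi / 2]
        if n_arms == 1
        else np.linspace(np.pi / 2 - np.pi / 3, np.pi / 2 + np.pi / 3, n_arms)
    )
    for b, c in enumerate(counts):
        t = (np.arange(c) + 0.5) / c
        seg = np.zeros((c, n_dims))
        if b == 0:
            seg[:, 1] = t
        else:
            a = angles[b - 1]
            seg[:, 0] = split[0] + np.cos(a) * t
            seg[:, 1] = split[1] + np.sin(a) * t
        segs.append(seg)
        branch_id.extend([b] * c)
    backbone = np.vstack(segs)
    noise = rng.standard_normal(backbone.shape) * noise_sd if noise_sd > 0 else 0.0
    parent = np.full(n_branch, -1, dtype=int)
    parent[1:] = 0
    attach = np.full(n_branch, -1, dtype=int)
    attach[1:] = counts[0] - 1
    names = ["root"] + (
        ["armA", "armB", "armC", "armD"][:n_arms]
        if n_arms <= 4
        else [f"arm{i}" for i in range(n_arms)]
    )
    return DlaTree(
        points=backbone + noise,
        branch_id=np.asarray(branch_id),
        branch_parent=parent,
        backbone=backbone,
        attach_point=attach,
        seed=seed,
        noise_sd=noise_sd,
        n_branch=n_branch,
        branch_names=names,
    )


def gen_bifurcation_cloud(
    n_points: int, noise_sd: float = 0.05, seed: int = 0, n_dims: int = 2
) -> DlaTree:
    """Two-fate system: one root segment splitting into two terminal arms."""
    return gen_multifurcation_cloud(
        n_points, n_arms=2, noise_sd=noise_sd, seed=seed, n_dims=n_dims
    )


_TOY_EDGES = (
    (1, 2), (2, 3), (2, 4), (2, 5), (3, 4),
    (4, 5), (4, 6), (4, 7), (6, 7), (7, 8),
)
_TOY_TRIANGLES = ((2, 3, 4), (2, 4, 5), (4, 6, 7))


def toy_complex() -> ToyComplexFixture:
    """The fixed 8-vertex, 10-edge, 3-triangle reference complex."""
    return ToyComplexFixture(
        vertices=tuple(range(1, 9)), edges=_TOY_EDGES, triangles=_TOY_TRIANGLES
    )


def ground_truth_export(tree: DlaTree, path: str | os.PathLike) -> None:
    """Write milestone network, branch labels and milestone percentages.

    ``milestone_network.tsv`` holds one row per parent->child branch link;
    ``branch_labels.tsv`` the per-point branch id; ``milestone_percentages.tsv``
    a distance-ratio soft assignment of every point to its two nearest
    branch-tip milestones (percentages per point sum to 1).
    """
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    links = [
        {"from": tree.branch_names[tree.branch_parent[b]], "to": tree.branch_names[b]}
        for b in range(tree.n_branch)
        if tree.branch_parent[b] >= 0
    ]
    pd.DataFrame(links, columns=["from", "to"]).to_csv(
        os.path.join(path, "milestone_network.tsv"), sep="\t", index=False
    )
    labels = pd.DataFrame(
        {
            "point_id": [f"p{i}" for i in range(tree.n_points)],
            "branch": [tree.branch_names[b] for b in tree.branch_id],
        }
    )
    labels.to_csv(os.path.join(path, "branch_labels.tsv"), sep="\t", index=False)

    tips = tree.backbone[tree.tip_indices()]
    d = np.linalg.norm(tree.points[:, None, :] - tips[None, :, :], axis=2)
    order = np.argsort(d, axis=1)
    rows = []
    for i in range(tree.n_points):
        a, b = order[i, 0], (order[i, 1] if tree.n_branch > 1 else order[i, 0])
        if tree.n_branch == 1:
            pcts = [(a, 1.0)]
        else:
            da, db = d[i, a], d[i, b]
            tot = da + db
            if tot == 0:
                pcts = [(a, 0.5), (b, 0.5)]
            else:
                # closer milestone gets the larger share
                pcts = [(a, db / tot), (b, da / tot)]
        for m, p in pcts:
            rows.append(
                {
                    "point_id": f"p{i}",
                    "milestone": tree.branch_names[m],
                    "percentage": p,
                }
            )
    pd.DataFrame(rows).to_csv(
        os.path.join(path, "milestone_percentages.tsv"), sep="\t", index=False
    )


def read_ground_truth(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read back the three tables written by :func:`ground_truth_export`."""
    path = os.fspath(path)
    return {
        name: pd.read_csv(os.path.join(path, f"{name}.tsv"), sep="\t")
        for name in ("milestone_network", "branch_labels", "milestone_percentages")
    }
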