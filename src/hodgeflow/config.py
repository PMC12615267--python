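"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Pipeline defaults.

    Graph: ``scale_neighbor`` local-scaling neighbour for the Gaussian
    kernel; ``steps`` diffusion steps; ``knn_k`` pruned-graph degree;
    ``lam`` gradient-ridge penalty (None = 0.01 x the largest eigenvalue
    of the pruned Gram matrix).  Complex: ``edge_filter`` "quantile"
    (factor x Q_q of edge lengths) or "radius" (PH0 single-component
    radius x radius_factor); ``m`` terminal/root cells linked per group;
    ``terminal_persistence`` the minimum pseudotime persistence for a
    peak to count as a distinct end state; ``group_min_flux`` the minimum
    share of sampled walks a terminal group must absorb.
    Harmonics: ``eigen_tolerance`` relative zero-eigenvalue cut.
    Trajectories: ``n_paths`` sampled walks; DBSCAN ``eps`` (None =
    median 5-NN distance) / ``min_samples``; ``outlier_fraction`` minimum
    cluster share.  Tree: ``bins`` pseudotime bins; ``sigma`` branching
    threshold.  Markers: ``top_bin_fraction``, smoothing ``window``.
    ``downsample_fraction`` runs the fit on a seeded cell subsample and
    assigns the remaining cells to the branch of their nearest sampled
    neighbour.
    """

    scale_neighbor: int = 7
    steps: int = 100
    knn_k: int = 15
    lam: float | None = None
    edge_filter: str = "quantile"
    filter_factor: float = 3.0
    filter_quantile: float = 0.75
    radius_factor: float = 1.2
    m: int = 5
    terminal_persistence: float = 0.025
    terminal_min_peak_pt: float = 0.02
    group_min_flux: float = 0.005
    eigen_tolerance: float = 1e-8
    n_paths: int = 10000
    dbscan_eps: float | None = None
    dbscan_min_samples: int = 5
    outlier_fraction: float = 0.005
    bins: int = 10
    sigma: float = 1.0
    top_bin_fraction: float = 0.5
    window: int = 5
    seed: int = 0
    downsample_fraction: float | None = None
    layout_max_iter: int = 300
    layout_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.edge_filter not in ("quantile", "radius"):
            raise ValueError("edge_filter must be 'quantile' or 'radius'")
        if self.terminal_persistence <= 0:
            raise ValueError("terminal_persistence must be > 0")
        if self.downsample_fraction is not None and not (
            0 < self.downsample_fraction <= 1
        ):
            raise ValueError("downsample_fraction must be in (0, 1]")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.n_paths < 1:
            raise ValueError("n_paths must be >= 1")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as f:
            json.dump(asdict(self), f, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "RunConfig":
        with open(os.fspath(path)) as f:
            return cls(**json.load(f))

    def replace(self, **kw) -> "RunConfig":
        d = asdict(self)
        d.update(kw)
        return RunConfig(**d)
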