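"""Branch-specific marker tests and regulator ranking.

Markers: cells from the terminal half of each branch's pseudotime bins
are contrasted gene-by-gene with a visit-frequency-weighted Welch t-test
(each cell weighted by the number of sampled trajectories visiting it)
on log1p library-normalized counts, with Benjamini-Hochberg correction.

Regulators: along a branch, per-bin mean TF expression is smoothed by a
moving-average convolution and correlated (Pearson) with the per-bin
mean TF activity; concordant TFs rank first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BranchContrast",
    "RegulatorScore",
    "select_branch_cells",
    "branch_de_test",
    "regulator_rank",
]


@dataclass
class BranchContrast:
    """Two branch cell sets and the per-gene test results."""

    cells_a: np.ndarray
    cells_b: np.ndarray
    test: str
    results: pd.DataFrame  # gene, statistic, log_fc, pvalue, padj, rank


@dataclass
class RegulatorScore:
    tf: str
    correlation: float
    rank: int


def _normalize_log(counts: np.ndarray, target: float = 1e4) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target)


def _weighted_welch(
    xa: np.ndarray, xb: np.ndarray, wa: np.ndarray, wb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted Welch t-test per column.

    Weights are relative importances (normalized upstream so each group
    keeps its nominal sample size); rescaling all weights by a constant
    leaves every statistic unchanged.
    """
    na, nb = wa.sum(), wb.sum()
    ma = (wa[:, None] * xa).sum(0) / na
    mb = (wb[:, None] * xb).sum(0) / nb
    va = (wa[:, None] * (xa - ma) ** 2).sum(0) / max(na - 1.0, 1.0)
    vb = (wb[:, None] * (xb - mb) ** 2).sum(0) / max(nb - 1.0, 1.0)
    se2 = va / na + vb / nb
    se2[se2 == 0] = np.inf
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (
        (va / na) ** 2 / max(na - 1.0, 1.0) + (vb / nb) ** 2 / max(nb - 1.0, 1.0)
    )
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def select_branch_cells(
    assignment: pd.DataFrame,
    branch: str | list[str],
    top_bin_fraction: float = 0.5,
) -> np.ndarray:
    """Cells in the terminal ``top_bin_fraction`` of a branch (or sub-tree).

    A list of branch ids is merged into a single branch before selection,
    with positions pooled.
    """
    branches = [branch] if isinstance(branch, str) else list(branch)
    sel = assignment[assignment["branch"].isin(branches)]
    if sel.empty:
        raise ValueError(f"no cells assigned to branch(es) {branches}")
    cut = sel["position"].quantile(1.0 - top_bin_fraction)
    return sel.loc[sel["position"] >= cut, "cell"].to_numpy()


def branch_de_test(
    counts: pd.DataFrame,
    assignment: pd.DataFrame,
    branch_a: str | list[str],
    branch_b: str | list[str],
    visit_counts: pd.Series | None = None,
    top_bin_fraction: float = 0.5,
    test: str = "t",
) -> BranchContrast:
    """Differential expression between the terminal halves of two branches.

    ``counts`` is cells x genes (raw counts); ``assignment`` the per-cell
    branch table from tree allocation; ``visit_counts`` the per-cell
    trajectory visit counts used as frequency weights (uniform when
    omitted).  ``test`` is "t" (weighted Welch) or "wilcoxon"
    (rank-sum, unweighted).
    """
    cells_a = select_branch_cells(assignment, branch_a, top_bin_fraction)
    cells_b = select_branch_cells(assignment, branch_b, top_bin_fraction)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError(
            f"need >= 3 selected cells per branch (got {len(cells_a)}, {len(cells_b)})"
        )
    if set(cells_a) & set(cells_b):
        raise ValueError("branch cell sets overlap")
    xa = _normalize_log(counts.loc[cells_a].to_numpy(dtype=float))
    xb = _normalize_log(counts.loc[cells_b].to_numpy(dtype=float))
    if visit_counts is None:
        wa = np.ones(len(cells_a))
        wb = np.ones(len(cells_b))
    else:
        wa = visit_counts.reindex(cells_a).fillna(0).to_numpy(dtype=float)
        wb = visit_counts.reindex(cells_b).fillna(0).to_numpy(dtype=float)
        wa[wa == 0] = wa[wa > 0].min() if (wa > 0).any() else 1.0
        wb[wb == 0] = wb[wb > 0].min() if (wb > 0).any() else 1.0
        # relative importance weights: each group keeps its nominal sample
        # size, so uniform visits reduce exactly to the unweighted test and
        # rescaling all visits by a constant changes nothing
        wa = wa * len(wa) / wa.sum()
        wb = wb * len(wb) / wb.sum()
    if test == "t":
        stat, p = _weighted_welch(xa, xb, wa, wb)
    elif test == "wilcoxon":
        stat = np.zeros(xa.shape[1])
        p = np.ones(xa.shape[1])
        for g in range(xa.shape[1]):
            try:
                res = stats.mannwhitneyu(xa[:, g], xb[:, g], alternative="two-sided")
                stat[g], p[g] = res.statistic, res.pvalue
            except ValueError:  # all-identical values
                stat[g], p[g] = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    log_fc = (wa[:, None] * xa).sum(0) / wa.sum() - (wb[:, None] * xb).sum(0) / wb.sum()
    padj = stats.false_discovery_control(np.clip(p, 0, 1), method="bh")
    res = pd.DataFrame(
        {
            "gene": counts.columns,
            "statistic": stat,
            "log_fc": log_fc,
            "pvalue": p,
            "padj": padj,
        }
    )
    res = res.sort_values(["padj", "pvalue"], kind="stable").reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return BranchContrast(cells_a=cells_a, cells_b=cells_b, test=test, results=res)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1 or x.size < 2:
        return x.astype(float)
    half = window // 2
    pad = np.concatenate([x[half:0:-1], x, x[-2 : -2 - half : -1]])
    kernel = np.ones(window) / window
    return np.convolve(pad, kernel, mode="valid")


def regulator_rank(
    expression: pd.DataFrame,
    activity: pd.DataFrame,
    cell_bins: pd.Series,
    window: int = 5,
    candidates: list[str] | None = None,
) -> list[RegulatorScore]:
    """Rank TFs by expression-activity concordance along a branch.

    ``expression`` and ``activity`` are cells x TFs tables sharing TF
    identifiers; ``cell_bins`` maps each branch cell to its pseudotime
    bin.  Per-bin mean expression (smoothed by a width-``window`` moving
    average, reflect-padded) is Pearson-correlated with per-bin mean
    activity; TFs (optionally restricted to ``candidates``, e.g. the
    branch-test hits) are ranked by decreasing correlation.  TFs with a
    constant profile are dropped with a warning.
    """
    tfs = [t for t in expression.columns if t in set(activity.columns)]
    if candidates is not None:
        cand = set(candidates)
        tfs = [t for t in tfs if t in cand]
    if not tfs:
        raise ValueError("no shared TF identifiers to rank")
    cells = cell_bins.index
    bins = sorted(cell_bins.unique())
    if len(bins) < 3:
        raise ValueError("need >= 3 populated bins along the branch")
    expr_bin = np.vstack(
        [
            expression.loc[cells[cell_bins == b], tfs].mean(axis=0).to_numpy()
            for b in bins
        ]
    )
    act_bin = np.vstack(
        [activity.loc[cells[cell_bins == b], tfs].mean(axis=0).to_numpy() for b in bins]
    )
    scores = []
    dropped = []
    for i, tf in enumerate(tfs):
        e = _moving_average(expr_bin[:, i], min(window, 2 * (len(bins) // 2) + 1))
        a = act_bin[:, i]
        if np.std(e) == 0 or np.std(a) == 0:
            dropped.append(tf)
            continue
        r = float(np.corrcoef(e, a)[0, 1])
        scores.append((tf, r))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} TFs with constant profiles: {dropped[:5]}",
            stacklevel=2,
        )
    scores.sort(key=lambda x: -x[1])
    return [RegulatorScore(tf=t, correlation=r, rank=i + 1) for i, (t, r) in enumerate(scores)]
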