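"""Hodge Laplacians and the harmonic edge basis.

The k-th Hodge Laplacian L_k = B_k' B_k + B_{k+1} B_{k+1}' generalizes the
graph Laplacian (k = 0) to act on k-simplex signals.  For edge flows
(k = 1) we use the degree-normalized form

    L1n = D2 B1' D1^{-1} B1 + B2 D3 B2' D2^{-1}

with D2 = max(diag(|B2| 1), I) the adjusted triangle-degree of each edge,
D1 = diag(|B1| D2 1) the D2-weighted vertex degrees and D3 = I/3.  Its
kernel (the harmonic space) has dimension equal to the first Betti number
of the complex; the eigenproblem is solved on the symmetric conjugate
L1s = D2^{-1/2} L1n D2^{1/2}, which shares eigenvalues, and eigenvectors
are mapped back through U = D2^{1/2} Q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "NormalizedL1",
    "HarmonicBasis",
    "hodge_laplacian",
    "normalized_l1",
    "harmonic_basis",
]


def hodge_laplacian(
    Bk: sp.spmatrix | np.ndarray | None,
    Bk1: sp.spmatrix | np.ndarray | None,
) -> sp.csr_matrix:
    """Unnormalized k-th Hodge Laplacian  L_k = Bk' Bk + Bk1 Bk1'."""
    if Bk is None and Bk1 is None:
        raise ValueError("at least one boundary operator is required")
    parts = []
    if Bk is not None:
        bk = sp.csr_matrix(Bk, dtype=float)
        parts.append(bk.T @ bk)
    if Bk1 is not None:
        bk1 = sp.csr_matrix(Bk1, dtype=float)
        parts.append(bk1 @ bk1.T)
    if len(parts) == 2 and parts[0].shape != parts[1].shape:
        raise ValueError(
            f"incompatible boundary operators: {parts[0].shape} vs {parts[1].shape}"
        )
    out = parts[0]
    for p in parts[1:]:
        out = out + p
    return out.tocsr()


@dataclass
class NormalizedL1:
    """Degree-normalized first-order Hodge Laplacian and its symmetric form."""

    operator: sp.csr_matrix
    symmetric_form: sp.csr_matrix
    D1: np.ndarray  # weighted vertex degrees (diagonal)
    D2: np.ndarray  # adjusted edge degrees (diagonal, >= 1)
    D3: float  # scalar: D3 = D3_value * I

    @property
    def n_edges(self) -> int:
        return self.operator.shape[0]


def normalized_l1(
    B1: sp.spmatrix, B2: sp.spmatrix, d1_scale: float = 1.0
) -> NormalizedL1:
    """Assemble the normalized first-order Hodge Laplacian.

    ``d1_scale`` rescales D1 (some published variants carry a factor 2);
    the kernel dimension is invariant to any positive diagonal rescaling.
    """
    b1 = sp.csc_matrix(B1, dtype=float)
    b2 = sp.csc_matrix(B2, dtype=float)
    if b1.shape[1] != b2.shape[0]:
        raise ValueError("B1 and B2 do not share an edge dimension")
    m = b1.shape[1]
    d2 = np.maximum(np.asarray(abs(b2) @ np.ones(b2.shape[1])).ravel(), 1.0)
    d1 = d1_scale * np.asarray(abs(b1) @ d2).ravel()
    if np.any(d1 <= 0):
        raise ValueError("vertex with zero weighted degree (isolated vertex?)")
    d3 = 1.0 / 3.0
    D2 = sp.diags(d2)
    D1i = sp.diags(1.0 / d1)
    D2i = sp.diags(1.0 / d2)
    lower = (b1.T @ D1i @ b1).tocsr()
    upper = (b2 @ b2.T).tocsr() * d3
    op = (D2 @ lower + upper @ D2i).tocsr()
    s2 = sp.diags(np.sqrt(d2))
    s2i = sp.diags(1.0 / np.sqrt(d2))
    sym = (s2 @ lower @ s2 + s2i @ upper @ s2i).tocsr()
    sym = ((sym + sym.T) * 0.5).tocsr()
    return NormalizedL1(operator=op, symmetric_form=sym, D1=d1, D2=d2, D3=d3)


@dataclass
class HarmonicBasis:
    """Near-null eigenvectors of the normalized L1, mapped to edge space."""

    H: np.ndarray  # (n_edges, h)
    eigenvalues: np.ndarray  # all computed eigenvalues, ascending
    h: int
    eigenvalue_tolerance: float


def _dense_eig(sym: sp.spmatrix) -> tuple[np.ndarray, np.ndarray]:
    evals, q = np.linalg.eigh(sym.toarray())
    return evals, q


def _sparse_small_eig(
    sym: sp.spmatrix, k: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Smallest-k eigenpairs via shift-invert at a small negative shift."""
    n = sym.shape[0]
    k = min(k, n - 2)
    v0 = np.random.default_rng(seed).standard_normal(n)
    evals, q = spla.eigsh(sym.tocsc(), k=k, sigma=-1e-3, which="LM", v0=v0)
    order = np.argsort(evals)
    return evals[order], q[:, order]


def harmonic_basis(
    norm: NormalizedL1,
    tolerance: float = 1e-8,
    k_max: int | None = None,
    dense_cutoff: int = 2000,
    seed: int = 0,
) -> HarmonicBasis:
    """Extract the harmonic eigenvectors (eigenvalue ~ 0) of L1n.

    Eigenvalues below ``tolerance`` x lambda_max are counted as zero.  Up
    to ``dense_cutoff`` edges the full dense spectrum is used; beyond
    that, the ``k_max`` smallest eigenpairs come from a sparse
    shift-invert solve (enlarged and retried if all of them are null).
    The symmetric-form eigenvectors Q are mapped back to edge space as
    U = D2^{1/2} Q, sorted by increasing eigenvalue.
    """
    sym = norm.symmetric_form
    m = sym.shape[0]
    if m <= dense_cutoff:
        evals, q = _dense_eig(sym)
        lam_max = float(evals[-1])
    else:
        k = k_max if k_max is not None else 20
        lam_max = float(
            spla.eigsh(sym, k=1, which="LA", return_eigenvectors=False)[0]
        )
        evals, q = _sparse_small_eig(sym, k, seed=seed)
        while np.all(np.abs(evals) < tolerance * lam_max) and k < m - 2:
            k = min(2 * k, m - 2)
            evals, q = _sparse_small_eig(sym, k, seed=seed)
    thr = tolerance * lam_max
    null = np.abs(evals) < thr
    h = int(null.sum())
    if h == 0:
        warnings.warn(
            "no zero eigenvalue found: the complex has no holes "
            "(were terminal-root dummy edges added?)",
            stacklevel=2,
        )
    elif h < len(evals) and evals[h] < 10 * thr:
        warnings.warn(
            f"weak spectral gap after the harmonic space "
            f"(lambda_{h + 1} = {evals[h]:.3e}, threshold {thr:.3e})",
            stacklevel=2,
        )
    u = np.sqrt(norm.D2)[:, None] * q[:, :h]
    return HarmonicBasis(
        H=u, eigenvalues=np.asarray(evals), h=h, eigenvalue_tolerance=tolerance
    )
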