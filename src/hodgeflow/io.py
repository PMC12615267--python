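"""File I/O: embeddings, count matrices, root lists, simplicial complexes.

Delimited text conventions are documented in docs/FORMATS.md: embeddings
and counts are cells x columns tables with the cell identifier in the
first column and a header row; Matrix Market inputs carry sidecar row /
column label files (one label per line).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .diffusion_graph import EmbeddingMatrix
from .simplicial_complex import SimplicialComplex

__all__ = [
    "read_embedding",
    "read_matrix",
    "read_roots",
    "write_embedding",
    "save_complex",
    "load_complex",
    "save_harmonic_basis",
]


def _read_labels(path: str) -> list[str]:
    with open(path) as f:
        return [line.strip().split("\t")[0] for line in f if line.strip()]


def read_matrix(
    path: str | os.PathLike,
    row_labels: str | os.PathLike | None = None,
    col_labels: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Read a cells x features table from CSV/TSV or Matrix Market.

    Delimited files must carry a header row and cell ids in the first
    column; ``.mtx`` files need the two sidecar label files.
    """
    path = os.fspath(path)
    if path.endswith(".mtx"):
        if row_labels is None or col_labels is None:
            raise ValueError("Matrix Market input needs row and column label files")
        m = sio.mmread(path)
        if sp.issparse(m):
            m = m.toarray()
        return pd.DataFrame(
            np.asarray(m),
            index=_read_labels(os.fspath(row_labels)),
            columns=_read_labels(os.fspath(col_labels)),
        )
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    try:
        return pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, UnicodeDecodeError) as e:
        raise ValueError(f"could not parse {path}: {e}") from None


def read_embedding(
    path: str | os.PathLike,
    row_labels: str | os.PathLike | None = None,
    col_labels: str | os.PathLike | None = None,
) -> EmbeddingMatrix:
    """Read a cells x dims embedding into an :class:`EmbeddingMatrix`."""
    df = read_matrix(path, row_labels, col_labels)
    return EmbeddingMatrix(df.to_numpy(dtype=float), [str(i) for i in df.index])


def write_embedding(emb: EmbeddingMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(
        emb.values,
        index=emb.cell_ids,
        columns=[f"dim{i}" for i in range(emb.values.shape[1])],
    ).to_csv(os.fspath(path))


def read_roots(path: str | os.PathLike) -> list[str]:
    """Read root cell identifiers, one per line."""
    roots = _read_labels(os.fspath(path))
    if not roots:
        raise ValueError(f"no root cell identifiers found in {path}")
    return roots


def save_complex(sc: SimplicialComplex, path: str | os.PathLike) -> None:
    """Serialize an SC as TSV tables plus Matrix Market boundary operators."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    ids = sc.cell_ids if sc.cell_ids is not None else [f"c{i}" for i in range(sc.n_vertices)]
    vert = pd.DataFrame({"index": np.arange(sc.n_vertices), "cell": ids})
    if sc.layout is not None:
        vert["x"], vert["y"] = sc.layout[:, 0], sc.layout[:, 1]
    vert.to_csv(os.path.join(path, "vertices.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {
            "tail": sc.edges[:, 0],
            "head": sc.edges[:, 1],
            "dummy": sc.dummy_edges.astype(int),
        }
    ).to_csv(os.path.join(path, "edges.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {
            "a": sc.triangles[:, 0],
            "b": sc.triangles[:, 1],
            "c": sc.triangles[:, 2],
            "dummy": sc.dummy_triangles.astype(int),
        }
    ).to_csv(os.path.join(path, "triangles.tsv"), sep="\t", index=False)
    b1, b2 = sc.B1, sc.B2
    sio.mmwrite(os.path.join(path, "B1.mtx"), b1)
    sio.mmwrite(os.path.join(path, "B2.mtx"), b2)


def save_harmonic_basis(
    sc: SimplicialComplex, H: np.ndarray, path: str | os.PathLike
) -> None:
    """Write the edges x h harmonic basis as CSV keyed by edge tuples."""
    df = pd.DataFrame(
        np.asarray(H),
        columns=[f"h{i}" for i in range(np.asarray(H).shape[1])],
    )
    df.insert(0, "tail", sc.edges[:, 0])
    df.insert(1, "head", sc.edges[:, 1])
    df.to_csv(os.fspath(path), index=False)


def load_complex(path: str | os.PathLike) -> SimplicialComplex:
    path = os.fspath(path)
    vert = pd.read_csv(os.path.join(path, "vertices.tsv"), sep="\t")
    edges = pd.read_csv(os.path.join(path, "edges.tsv"), sep="\t")
    tris = pd.read_csv(os.path.join(path, "triangles.tsv"), sep="\t")
    layout = (
        vert[["x", "y"]].to_numpy(dtype=float) if "x" in vert.columns else None
    )
    return SimplicialComplex(
        n_vertices=len(vert),
        edges=edges[["tail", "head"]].to_numpy(dtype=int),
        triangles=tris[["a", "b", "c"]].to_numpy(dtype=int),
        layout=layout,
        dummy_edges=edges["dummy"].to_numpy(dtype=bool),
        dummy_triangles=tris["dummy"].to_numpy(dtype=bool),
        cell_ids=[str(c) for c in vert["cell"]],
    )
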