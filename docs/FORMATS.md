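# File formats

All delimited files are UTF-8 with LF line endings. CSV/TSV is chosen by
extension (`.csv` comma, `.tsv`/`.txt` tab).

## Inputs

**Embedding** (`hodgeflow fit --embedding`): cells × dims table with a
header row and the cell identifier in the first column; or a Matrix
Market `.mtx` with sidecar label files (`--row-labels`, `--col-labels`,
one label per line, first tab-separated field used).

**Roots** (`--roots`): one root cell identifier per line.

**Counts** (`hodgeflow markers --counts`): cells × genes raw counts,
same conventions as the embedding (CSV/TSV or `.mtx` + sidecars).

**TF expression / activity** (`hodgeflow regulators`): cells × TFs
tables sharing TF column names; activities are produced upstream (e.g.
motif-accessibility scoring) and are never computed here.

## Outputs of `fit`

| file | columns |
|---|---|
| `milestone_network.tsv` | `from`, `to` (milestone ids), `length` (pseudotime span), `branch` |
| `cell_branches.tsv` | `cell`, `group` (trajectory group), `branch`, `position` (0–1 within branch) |
| `milestone_percentages.tsv` | `cell`, `milestone`, `percentage` (sums to 1 per cell) |
| `cell_stats.tsv` | `cell`, `pseudotime`, `visits` (walk visit count), plus the assignment columns |
| `tree.newick` | milestone topology; branch lengths are pseudotime spans |
| `tree.json` | milestones (id, kind, bin, pseudotime), branches (endpoints, groups, bin/pseudotime spans), bin boundaries, σ |
| `config.json` | the resolved `RunConfig`; re-running `fit` from it reproduces the outputs bit-for-bit |

`cell_stats.tsv` covers the cells the fit actually used (the subsample
when `--downsample` is set); `cell_branches.tsv` always covers every
input cell.

## Simulation outputs (`simulate`)

`points.csv` (points × features, ids `p0…`), `roots.txt`, and a
`ground_truth/` directory with `milestone_network.tsv` (parent→child
branch links), `branch_labels.tsv` (`point_id`, `branch`) and
`milestone_percentages.tsv` (`point_id`, `milestone`, `percentage`;
distance-ratio soft assignment to the two nearest branch-tip milestones).

## Library-level serialization

`hodgeflow.io.save_complex` writes a simplicial complex as
`vertices.tsv` (index, cell, layout x/y), `edges.tsv` (tail, head, dummy
flag), `triangles.tsv` (a, b, c, dummy flag) and the boundary operators
`B1.mtx` / `B2.mtx` in Matrix Market format.
`PathEnsemble.save_hdf5` stores the walk ensemble (ragged paths, sparse
flows, embedding, group labels) in one HDF5 container.
`hodgeflow.io.save_harmonic_basis` writes the edges × h harmonic basis
as CSV with `tail`, `head` edge columns followed by `h0…h{h-1}`.
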