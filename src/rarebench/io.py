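"""Plain-text I/O for count tables, trees, depth vectors and results.

Count tables are TSV with the sample id in the first column and OTU ids in
the header, or MatrixMarket coordinate triplets with sidecar row/column id
files.  Trees are Newick with branch lengths.  Depth vectors are one integer
per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from skbio import TreeNode

from .normalize import NormalizedTable
from .simulate import CountTable


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = pd.DataFrame(table.counts, index=table.sample_ids,
                      columns=table.otu_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    side = pd.DataFrame({"sample_id": table.sample_ids,
                         "group": table.groups,
                         "depth": table.depths})
    side.to_csv(Path(path).with_suffix(".samples.tsv"), sep="\t", index=False)


def read_count_table(path: str | Path,
                     effect_size: float = 1.0) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    side_path = Path(path).with_suffix(".samples.tsv")
    if side_path.exists():
        side = pd.read_csv(side_path, sep="\t").set_index("sample_id")
        groups = side.loc[df.index, "group"].to_numpy()
    else:
        groups = np.array(["A"] * (len(df) // 2)
                          + ["B"] * (len(df) - len(df) // 2))
    return CountTable(counts=df.to_numpy(dtype=np.int64), groups=groups,
                      otu_ids=list(df.columns), sample_ids=list(df.index),
                      effect_size=effect_size)


def write_count_table_mtx(table: CountTable, prefix: str | Path) -> None:
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx",
                     scipy.sparse.coo_matrix(table.counts))
    Path(str(prefix) + ".samples.txt").write_text(
        "\n".join(table.sample_ids) + "\n")
    Path(str(prefix) + ".otus.txt").write_text(
        "\n".join(table.otu_ids) + "\n")


def read_count_table_mtx(prefix: str | Path) -> CountTable:
    prefix = Path(prefix)
    counts = np.asarray(
        scipy.io.mmread(str(prefix) + ".mtx").todense()).astype(np.int64)
    sample_ids = Path(str(prefix) + ".samples.txt").read_text().split()
    otu_ids = Path(str(prefix) + ".otus.txt").read_text().split()
    half = len(sample_ids) // 2
    groups = np.array(["A"] * half + ["B"] * (len(sample_ids) - half))
    return CountTable(counts=counts, groups=groups, otu_ids=otu_ids,
                      sample_ids=sample_ids)


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_depths(depths: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(int(d)) for d in depths) + "\n")


def read_depths(path: str | Path) -> np.ndarray:
    return np.array([int(line) for line in
                     Path(path).read_text().split()], dtype=np.int64)


def write_normalized(norm: NormalizedTable, path: str | Path) -> None:
    """Normalized matrix as TSV plus a JSON sidecar with its provenance."""
    df = pd.DataFrame(norm.values, index=norm.sample_ids, columns=norm.otu_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    meta = {"method": norm.method,
            "threshold_quantile": norm.threshold_quantile,
            "removed_samples": list(norm.removed_samples),
            "n_iterations": norm.n_iterations}
    Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_distance_matrix(dm, path: str | Path) -> None:
    """Square tab-delimited matrix with id header row and column."""
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    df.to_csv(path, sep="\t")
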