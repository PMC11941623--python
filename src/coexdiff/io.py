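"""Readers and writers for the pipeline's plain-text artifact formats.

Counts travel as gene x sample TSV (or MatrixMarket with sidecar row/column
name files), designs as TSV, gene sets as GMT, networks as edge-list TSV or
GraphML, partitions as two-column TSV, and reports as JSON.  Every
reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .coexnet import CoexpressionNetwork
from .genesets import GeneSetCollection, read_gmt, write_gmt  # noqa: F401 (re-export)
from .mapeq import Partition
from .normdge import CountMatrix
from .synthdata import CohortDesign

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "write_partition",
    "read_partition",
    "write_json",
]


def read_counts(path: str | PathLike, design: CohortDesign | None = None) -> CountMatrix:
    """Read a gene x sample TSV (first column gene ids) or MatrixMarket trio."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = sp.coo_matrix(spio.mmread(path)).toarray()
        genes = path.with_suffix(".genes.txt").read_text().split()
        samples = path.with_suffix(".samples.txt").read_text().split()
        df = pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.dtypes[~df.dtypes.map(pd.api.types.is_integer_dtype)]
        if len(bad):
            raise ValueError(f"{path}: non-integer count column(s): {list(bad.index)}")
        df.index = df.index.astype(str)
        df.index.name = None
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dupes[:5]}")
    return CountMatrix(df, design)


def write_counts(cm: CountMatrix, path: str | PathLike) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(path, sp.coo_matrix(cm.counts.to_numpy()))
        path.with_suffix(".genes.txt").write_text("\n".join(cm.genes) + "\n")
        path.with_suffix(".samples.txt").write_text("\n".join(cm.samples) + "\n")
    else:
        cm.counts.to_csv(path, sep="\t", index_label="gene")


def read_design(path: str | PathLike, cutoff: float = 70.0) -> CohortDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: design needs columns {sorted(required)}")
    if not set(df["group"]) <= {"early", "late"}:
        raise ValueError(f"{path}: group labels must be 'early' or 'late'")
    ages = df["age_at_diagnosis"] if "age_at_diagnosis" in df else pd.Series(
        [cutoff - 1.0 if g == "early" else cutoff + 1.0 for g in df["group"]]
    )
    return CohortDesign(
        sample_id=tuple(df["sample_id"]),
        age_at_diagnosis=tuple(float(a) for a in ages),
        group=tuple(df["group"]),
        cutoff=cutoff,
    )


def write_design(design: CohortDesign, path: str | PathLike) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def write_edgelist(network: CoexpressionNetwork, path: str | PathLike) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_edgelist(path: str | PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(graph, path: str | PathLike) -> None:
    """GraphML export; accepts a CoexpressionNetwork or any networkx graph."""
    if isinstance(graph, CoexpressionNetwork):
        g = graph.graph()
        g.graph["threshold_value"] = graph.threshold_value
        g.graph["percentile"] = graph.percentile
        g.graph["n_samples"] = graph.n_samples
    else:
        g = graph
    nx.write_graphml(g, path)


def write_partition(partition: Partition, path: str | PathLike) -> None:
    pd.DataFrame(
        {"node": list(partition.module_of), "module_id": list(partition.module_of.values())}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | PathLike) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    module_of = dict(zip(df["node"], df["module_id"].astype(int)))
    return Partition(
        module_of=module_of,
        n_modules=len(set(module_of.values())),
        description_length=float("nan"),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(record: dict, path: str | PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
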