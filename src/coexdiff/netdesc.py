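"""Network descriptors and cohort-comparison statistics.

Degree distributions of the two cohort networks are compared as a 2 x B
contingency table (network x degree bin) with Pearson's chi-square
homogeneity test and Cramer's V effect size,
V = sqrt(chi2 / (n_total * (min(rows, cols) - 1))).
Sparse tail bins are pooled upward until every expected count is at least 5,
the classical validity rule for the chi-square approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .coexnet import CoexpressionNetwork
from .mapeq import Partition
from scipy import stats

__all__ = [
    "DegreeHistogram",
    "DistributionComparison",
    "degree_distribution",
    "compare_degree_distributions",
    "summarize_network",
]


@dataclass
class DegreeHistogram:
    degrees: np.ndarray  # distinct degree values, ascending
    counts: np.ndarray
    n_nodes: int

    def as_dict(self) -> dict[int, int]:
        return {int(d): int(c) for d, c in zip(self.degrees, self.counts)}


@dataclass
class DistributionComparison:
    chi2: float
    df: int
    p: float
    cramers_v: float
    n_total: int


def _as_graph(network) -> nx.Graph:
    if isinstance(network, CoexpressionNetwork):
        return network.graph()
    return network


def degree_distribution(network) -> DegreeHistogram:
    """Histogram of unweighted node degrees (one bin per distinct degree)."""
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = np.array([d for _, d in g.degree()], dtype=np.int64)
    values, counts = np.unique(degs, return_counts=True)
    return DegreeHistogram(degrees=values, counts=counts, n_nodes=int(degs.size))


def _pool_sparse_bins(table: np.ndarray, min_expected: float = 5.0) -> np.ndarray:
    """Merge sparse degree bins with a neighbour until expected counts >= 5.

    The highest sparse bin is merged first (tail pooling), falling back to
    the lower neighbour at the right edge, so adjacent degree classes stay
    adjacent after pooling.
    """
    table = table.astype(float)
    while table.shape[1] > 1:
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        sparse = np.where(expected.min(axis=0) < min_expected)[0]
        if sparse.size == 0:
            break
        j = int(sparse[-1])
        target = j - 1 if j == table.shape[1] - 1 else j + 1
        table[:, target] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def compare_degree_distributions(
    h1: DegreeHistogram, h2: DegreeHistogram, min_expected: float = 5.0
) -> DistributionComparison:
    """Chi-square homogeneity test and Cramer's V on two degree histograms.

    Histograms are aligned on the union of observed degrees, sparse tail
    bins pooled, then the Pearson statistic computed on the 2 x B table with
    df = B - 1 (rows fixed by the two-cohort design).
    """
    if h1.n_nodes == 0 or h2.n_nodes == 0:
        raise ValueError("cannot compare an empty histogram")
    degrees = np.union1d(h1.degrees, h2.degrees)
    d1, d2 = h1.as_dict(), h2.as_dict()
    table = np.array(
        [[d1.get(int(d), 0) for d in degrees], [d2.get(int(d), 0) for d in degrees]],
        dtype=float,
    )
    table = _pool_sparse_bins(table, min_expected)
    n_total = int(table.sum())
    b = table.shape[1]
    if b < 2:
        return DistributionComparison(chi2=0.0, df=0, p=1.0, cramers_v=0.0, n_total=n_total)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n_total
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = (table - expected) ** 2 / expected
    chi2 = float(np.nansum(contrib))
    df = b - 1
    p = float(stats.chi2.sf(chi2, df))
    v = float(np.sqrt(chi2 / (n_total * (min(2, b) - 1))))
    return DistributionComparison(chi2=chi2, df=df, p=p, cramers_v=min(v, 1.0), n_total=n_total)


def summarize_network(network, partition: Partition | None = None) -> dict:
    """Macro descriptors: size, density, components, module sizes."""
    g = _as_graph(network)
    n, e = g.number_of_nodes(), g.number_of_edges()
    summary = {
        "n_nodes": n,
        "n_edges": e,
        "density": nx.density(g) if n > 1 else 0.0,
        "component_sizes": sorted((len(c) for c in nx.connected_components(g)), reverse=True),
    }
    if partition is not None:
        sizes = partition.module_sizes()
        summary["n_modules"] = partition.n_modules
        summary["module_sizes"] = sorted(sizes.values(), reverse=True)
        summary["description_length_bits"] = partition.description_length
    return summary
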