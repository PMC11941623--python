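"""Mutual-information co-expression networks.

Expression profiles are discretized into equal-frequency bins (default
``floor(sqrt(n_samples))`` bins), pairwise mutual information is estimated
with the plug-in (maximum-likelihood) estimator in bits, and the network
keeps the pairs above a percentile of the full MI distribution (the study
design uses the 99th percentile).  An analytic per-edge p-value comes from
the identity between MI and the likelihood-ratio G statistic:
``G = 2 * n * ln(2) * I_bits`` is chi-square with (r-1)(c-1) degrees of
freedom under independence.  P-values are provenance only; thresholding is
by percentile.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiscretizedMatrix",
    "CoexpressionNetwork",
    "discretize_equal_frequency",
    "mutual_information",
    "pairwise_mi",
    "mi_significance",
    "threshold_at_percentile",
    "infer_network",
]

LN2 = float(np.log(2.0))


@dataclass
class DiscretizedMatrix:
    """Gene x sample bin labels from equal-frequency discretization."""

    bins: np.ndarray  # int, genes x samples
    n_bins: int
    genes: list[str]
    scheme: str = "equal-frequency"

    @property
    def n_samples(self) -> int:
        return self.bins.shape[1]


@dataclass
class CoexpressionNetwork:
    """Thresholded undirected MI network with threshold provenance."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: gene_a, gene_b, mi_bits, p_value
    threshold_value: float
    percentile: float
    n_samples: int
    n_bins: int = 0

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=row.mi_bits, p_value=row.p_value)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def discretize_equal_frequency(
    expr: pd.DataFrame | np.ndarray, n_bins: int | None = None
) -> DiscretizedMatrix:
    """Rank-based assignment of each gene's samples into near-equal bins.

    Ties are broken by stable input order; sample s with stable rank k goes
    to bin ``floor(k * n_bins / n_samples)``.  A constant gene collapses to a
    single occupied bin (bin 0), which makes its MI with anything zero.
    """
    if isinstance(expr, pd.DataFrame):
        genes = list(expr.index)
        values = expr.to_numpy(dtype=float)
    else:
        values = np.asarray(expr, dtype=float)
        genes = [f"row{i}" for i in range(values.shape[0])]
    n_samples = values.shape[1]
    if n_bins is None:
        n_bins = max(2, int(np.floor(np.sqrt(n_samples))))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_samples < n_bins:
        raise ValueError("need at least as many samples as bins")

    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    row_idx = np.arange(values.shape[0])[:, None]
    ranks[row_idx, order] = np.arange(n_samples)[None, :]
    bins = (ranks * n_bins) // n_samples

    constant = np.ptp(values, axis=1) == 0
    bins[constant, :] = 0
    return DiscretizedMatrix(bins=bins.astype(np.int64), n_bins=int(n_bins), genes=genes)


def mutual_information(
    x_bins, y_bins, n_bins: int | None = None, miller_madow: bool = False
) -> float:
    """Plug-in MI estimate in bits from two integer label vectors.

    ``miller_madow`` adds the small-sample bias correction
    (m_x + m_y - m_xy - 1) / (2 n ln 2) over occupied bin counts.
    """
    x = np.asarray(x_bins, dtype=np.int64)
    y = np.asarray(y_bins, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("label vectors must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations")
    b = int(n_bins) if n_bins is not None else int(max(x.max(), y.max())) + 1
    joint = np.bincount(x * b + y, minlength=b * b).reshape(b, b).astype(float)
    mi = _mi_from_table(joint)
    if miller_madow:
        mx = int((joint.sum(axis=1) > 0).sum())
        my = int((joint.sum(axis=0) > 0).sum())
        mxy = int((joint > 0).sum())
        mi += (mx + my - mxy - 1) / (2.0 * n * LN2)
    return mi


def _mi_from_table(joint: np.ndarray) -> float:
    n = joint.sum()
    r = joint.sum(axis=1)
    c = joint.sum(axis=0)
    nz = joint > 0
    terms = joint[nz] * np.log2(joint[nz] * n / np.outer(r, c)[nz])
    return float(max(terms.sum() / n, 0.0))


def _xlogx_table(n: int) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = k * np.log2(k)
    t[0] = 0.0
    return t


def pairwise_mi(
    binned: DiscretizedMatrix, chunk: int = 256, miller_madow: bool = False
) -> np.ndarray:
    """MI in bits for all unordered gene pairs (condensed upper triangle).

    Works blockwise on one-hot indicators: for bin pair (k, l) the joint
    counts over all gene pairs are a single matrix product, so the full
    g*(g-1)/2 computation is a few hundred BLAS calls plus a table lookup
    for x*log2(x).
    """
    bins = binned.bins
    g, n = bins.shape
    if g < 2:
        raise ValueError("need at least two genes")
    b = binned.n_bins
    xlogx = _xlogx_table(n)

    # one-hot indicators per bin value: (b, g, n)
    onehot = np.stack([(bins == k).astype(np.float64) for k in range(b)])
    margins = onehot.sum(axis=2)  # (b, g) per-gene bin occupancy
    h_marg = xlogx[margins.astype(np.int64)].sum(axis=0) / n  # (g,)
    m_marg = (margins > 0).sum(axis=0)  # occupied bins per gene

    out = np.empty(g * (g - 1) // 2)
    starts = list(range(0, g, chunk))

    def block_s(rows_a: slice, rows_b: slice):
        shape = (rows_a.stop - rows_a.start, rows_b.stop - rows_b.start)
        s = np.zeros(shape)
        occ = np.zeros(shape)
        for k in range(b):
            a_k = onehot[k, rows_a]
            for l in range(b):
                counts = np.rint(a_k @ onehot[l, rows_b].T).astype(np.int64)
                s += xlogx[counts]
                if miller_madow:
                    occ += counts > 0
        return s / n, occ

    log2n = np.log2(n)
    for ia, a0 in enumerate(starts):
        a1 = min(a0 + chunk, g)
        for b0 in starts[ia:]:
            b1 = min(b0 + chunk, g)
            s, occ = block_s(slice(a0, a1), slice(b0, b1))
            mi = np.maximum(s + log2n - h_marg[a0:a1, None] - h_marg[None, b0:b1], 0.0)
            if miller_madow:
                mi += (
                    m_marg[a0:a1, None] + m_marg[None, b0:b1] - occ - 1.0
                ) / (2.0 * n * LN2)
            for i in range(a0, a1):
                j_lo = max(b0, i + 1)
                if j_lo >= b1:
                    continue
                # condensed index of pair (i, j) for j in [j_lo, b1)
                base = i * g - i * (i + 1) // 2 - i - 1
                out[base + j_lo : base + b1] = mi[i - a0, j_lo - b0 : b1 - b0]
    return out


def mi_significance(mi_bits, n: int, r: int = 2, c: int = 2):
    """Upper-tail chi-square p-value for MI via the G identity.

    G = 2*n*ln(2)*I_bits is asymptotically chi-square with (r-1)(c-1)
    degrees of freedom under independence.
    """
    if n <= 0:
        raise ValueError("sample count must be positive")
    if r < 2 or c < 2:
        raise ValueError("need at least 2 bins per margin")
    g_stat = 2.0 * n * LN2 * np.asarray(mi_bits, dtype=float)
    return stats.chi2.sf(g_stat, (r - 1) * (c - 1))


def _condensed_pairs(g: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(g, k=1)
    return i, j


def threshold_at_percentile(
    genes: list[str],
    mi_values: np.ndarray,
    percentile: float = 99.0,
    n_samples: int = 0,
    n_bins: int = 0,
) -> CoexpressionNetwork:
    """Keep pairs with MI >= the stated percentile of all pair values.

    The percentile uses linear interpolation between order statistics and the
    tie rule is inclusive, so a degenerate all-equal distribution keeps every
    edge.  Each cohort's network is thresholded on its own MI distribution.
    """
    mi_values = np.asarray(mi_values, dtype=float)
    if mi_values.size == 0:
        raise ValueError("no MI values to threshold")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    thr = float(np.percentile(mi_values, percentile, method="linear"))
    ii, jj = _condensed_pairs(len(genes))
    keep = mi_values >= thr
    gene_arr = np.asarray(genes, dtype=object)
    mi_kept = mi_values[keep]
    if n_samples >= 2 and n_bins >= 2:
        pvals = mi_significance(mi_kept, n_samples, n_bins, n_bins)
    else:
        pvals = np.full(mi_kept.size, np.nan)
    edges = pd.DataFrame(
        {
            "gene_a": gene_arr[ii[keep]],
            "gene_b": gene_arr[jj[keep]],
            "mi_bits": mi_kept,
            "p_value": pvals,
        }
    )
    return CoexpressionNetwork(
        nodes=list(genes),
        edges=edges,
        threshold_value=thr,
        percentile=float(percentile),
        n_samples=int(n_samples),
        n_bins=int(n_bins),
    )


def infer_network(
    expr: pd.DataFrame,
    n_bins: int | None = None,
    percentile: float = 99.0,
) -> CoexpressionNetwork:
    """Discretize, compute all pairwise MI, and threshold — one cohort."""
    binned = discretize_equal_frequency(expr, n_bins=n_bins)
    mi = pairwise_mi(binned)
    return threshold_at_percentile(
        binned.genes, mi, percentile=percentile, n_samples=binned.n_samples, n_bins=binned.n_bins
    )
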