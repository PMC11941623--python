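"""Hypergeometric over-representation of modules and the bipartite
module-function network.

Each module (at least ``min_module_size`` genes inside the universe) is
tested against every annotation term with the upper-tail hypergeometric
probability P(X >= k); Benjamini-Hochberg adjustment is applied jointly
across all module x term tests, and significant pairs (q below threshold)
become the edges of a two-layer module-term graph.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection
from .mapeq import Partition
from .normdge import bh_adjust

__all__ = ["hypergeometric_pvalue", "enrich_modules", "build_bipartite"]


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: term size, n: module size, k: overlap.  The tail is
    summed directly from pmf terms rather than via 1 - cdf, which keeps full
    relative precision in small tails.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    return float(min(stats.hypergeom.pmf(support, N, K, n).sum(), 1.0))


def enrich_modules(
    partition: Partition,
    catalogue: GeneSetCollection,
    universe: set[str],
    min_module_size: int = 10,
    q_threshold: float = 0.05,
    bh_scope: str = "global",
) -> pd.DataFrame:
    """Test every sufficiently large module against every catalogue term.

    Catalogue sets are intersected with the universe before testing and BH is
    applied jointly across all tests (``bh_scope="global"``, the default) or
    within each module (``bh_scope="per_module"``).  Returns a tidy
    DataFrame with columns
    module_id, term_id, k, n, K, N, p, q, significant; modules entirely
    outside the universe are listed in ``result.attrs['skipped_modules']``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    restricted = catalogue.restricted_to(universe)
    members: dict[int, set[str]] = {}
    for gene, mod in partition.module_of.items():
        if gene in universe:
            members.setdefault(mod, set()).add(gene)
    skipped = sorted(set(partition.module_of.values()) - set(members))

    N = len(universe)
    rows = []
    for mod in sorted(members):
        mod_genes = members[mod]
        n = len(mod_genes)
        if n < min_module_size:
            continue
        for term, term_genes in restricted.sets.items():
            K = len(term_genes)
            k = len(mod_genes & term_genes)
            rows.append(
                {
                    "module_id": mod,
                    "term_id": term,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": hypergeometric_pvalue(k, K, n, N),
                }
            )
    if bh_scope not in ("global", "per_module"):
        raise ValueError("bh_scope must be 'global' or 'per_module'")
    table = pd.DataFrame(rows, columns=["module_id", "term_id", "k", "n", "K", "N", "p"])
    if not table.empty:
        if bh_scope == "global":
            table["q"] = bh_adjust(table["p"].to_numpy())
        else:
            table["q"] = table.groupby("module_id")["p"].transform(
                lambda p: bh_adjust(p.to_numpy())
            )
        table["significant"] = table["q"] < q_threshold
    else:
        table["q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    table.attrs["skipped_modules"] = skipped
    return table


def build_bipartite(enrichment: pd.DataFrame, q_threshold: float = 0.05) -> nx.Graph:
    """Two-layer graph of modules and the terms they are enriched for.

    Nodes carry a ``layer`` attribute in {"module", "term"}; edges are the
    enrichment rows with q < q_threshold and carry the q-value.
    """
    g = nx.Graph()
    if enrichment.empty:
        return g
    sig = enrichment[enrichment["q"] < q_threshold]
    for row in sig.itertuples(index=False):
        mod_node = f"module:{row.module_id}"
        term_node = f"term:{row.term_id}"
        g.add_node(mod_node, layer="module")
        g.add_node(term_node, layer="term")
        g.add_edge(mod_node, term_node, q=float(row.q))
    return g
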