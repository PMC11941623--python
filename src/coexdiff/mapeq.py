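"""Two-level map-equation community detection (Infomap-style).

The map equation scores a partition M of an undirected weighted network by
the expected per-step description length of a random walk encoded with a
two-level codebook:

    L(M) = q * H(Q) + sum_i p_i * H(P^i)

where q = sum_i q_i is the total module-switch rate (q_i: flow on edges
leaving module i), H(Q) the entropy of the normalized exit rates, p_i =
q_i + sum_{alpha in i} p_alpha the rate of use of module i's codebook, and
H(P^i) the entropy over the module's exit event and its nodes' visit rates.
For an undirected graph visit rates are exactly degree-proportional
(strength / 2W), so no teleportation is needed.

Optimization is a multi-trial Louvain-style schedule on L: repeated greedy
node-to-neighbouring-module moves followed by module aggregation, with the
best of ``n_trials`` independent random-order trials kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from ._mapeq_kernel import local_move
from .coexnet import CoexpressionNetwork

__all__ = ["Partition", "MapScore", "visit_rates", "map_equation_length", "optimize_partition"]


@dataclass
class Partition:
    """Node-to-module assignment with its map-equation description length."""

    module_of: dict
    n_modules: int
    description_length: float

    def labels_for(self, nodes) -> np.ndarray:
        return np.asarray([self.module_of[v] for v in nodes], dtype=np.int64)

    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.module_of.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes


@dataclass
class MapScore:
    total: float
    index_term: float
    module_terms: dict[int, float]
    visit_rates: dict
    exit_rates: dict[int, float]


def _as_graph(network) -> nx.Graph:
    if isinstance(network, CoexpressionNetwork):
        return network.graph()
    if isinstance(network, nx.Graph):
        return network
    raise TypeError("expected a CoexpressionNetwork or networkx Graph")


def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def visit_rates(network) -> dict:
    """Stationary visit rates of the random walk: strength / (2 * total weight).

    Isolated nodes get rate 0 (with a warning) — they carry no flow.
    """
    g = _as_graph(network)
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges")
    strength = dict(g.degree(weight="weight"))
    two_w = sum(strength.values())
    rates = {v: strength[v] / two_w for v in g.nodes}
    if any(s == 0 for s in strength.values()):
        warnings.warn("isolated nodes have visit rate 0", stacklevel=2)
    return rates


def map_equation_length(network, partition: Partition | dict) -> MapScore:
    """Evaluate the two-level map equation for a given partition, in bits."""
    g = _as_graph(network)
    module_of = partition.module_of if isinstance(partition, Partition) else partition
    missing = [v for v in g.nodes if v not in module_of]
    if missing:
        raise ValueError(f"partition is missing {len(missing)} network node(s)")

    p_node = visit_rates(g)
    strength = dict(g.degree(weight="weight"))
    two_w = sum(strength.values())

    modules = sorted(set(module_of[v] for v in g.nodes))
    q: dict[int, float] = {m: 0.0 for m in modules}
    for u, v, w in g.edges(data="weight", default=1.0):
        if module_of[u] != module_of[v]:
            q[module_of[u]] += w / two_w
            q[module_of[v]] += w / two_w

    q_tot = sum(q.values())
    if q_tot > 0:
        index_term = float(-sum(_plogp(np.array([q[m] / q_tot for m in modules]))) * q_tot)
    else:
        index_term = 0.0

    module_terms: dict[int, float] = {}
    for m in modules:
        p_in = [p_node[v] for v in g.nodes if module_of[v] == m]
        p_circ = q[m] + sum(p_in)
        if p_circ <= 0:
            module_terms[m] = 0.0
            continue
        probs = np.array([q[m]] + p_in) / p_circ
        module_terms[m] = float(-_plogp(probs).sum() * p_circ)

    total = index_term + sum(module_terms.values())
    return MapScore(
        total=total,
        index_term=index_term,
        module_terms=module_terms,
        visit_rates=p_node,
        exit_rates=q,
    )


def _csr_arrays(a: sp.csr_array | sp.csr_matrix):
    return (
        a.indptr.astype(np.int64),
        a.indices.astype(np.int64),
        a.data.astype(np.float64),
    )


def _one_trial(a_off, selfflow, pnode, node_term, rng) -> tuple[np.ndarray, float]:
    """One Louvain-style trial; returns original-node labels and L in bits."""
    n0 = a_off.shape[0]
    node_to_level = np.arange(n0, dtype=np.int64)
    level_a = a_off
    level_p = pnode.copy()
    final_L = None
    while True:
        n = level_a.shape[0]
        indptr, indices, w = _csr_arrays(level_a)
        text = np.asarray(level_a.sum(axis=1)).ravel()
        labels = np.arange(n, dtype=np.int64)
        q = text.copy()
        p = level_p.copy()
        qtot = np.array([q.sum()])
        order = rng.permutation(n).astype(np.int64)
        moves = local_move(indptr, indices, w, text, level_p, labels, q, p, qtot, order)
        final_L = float(
            _plogp(np.array([qtot[0]]))[0]
            - 2.0 * _plogp(q).sum()
            + _plogp(q + p).sum()
            - node_term
        )
        uniq = np.unique(labels)
        k = uniq.size
        inv = np.empty(n, dtype=np.int64)
        inv[uniq] = np.arange(k, dtype=np.int64)
        new_labels = inv[labels]
        node_to_level = new_labels[node_to_level]
        if moves == 0 or k == n:
            break
        # aggregate modules into supernodes
        proj = sp.csr_array(
            (np.ones(n), (np.arange(n), new_labels)), shape=(n, k)
        )
        a2 = (proj.T @ level_a @ proj).tocsr()
        diag = a2.diagonal()
        selfflow = np.asarray(proj.T @ selfflow).ravel() + diag / 2.0
        a2.setdiag(0.0)
        a2.eliminate_zeros()
        level_a = a2
        level_p = np.asarray(proj.T @ level_p).ravel()
    return node_to_level, final_L


def optimize_partition(
    network,
    n_trials: int = 1000,
    seed: int = 0,
) -> Partition:
    """Minimize the map equation by multi-trial greedy search.

    Each trial runs greedy node moves in an independent random node order,
    aggregates modules, and repeats until no move lowers L; the best
    partition over all trials is returned.  Deterministic given
    ``(seed, n_trials)``.  Isolated nodes are dropped before optimization.
    """
    g = _as_graph(network)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if g.number_of_edges() == 0:
        # no flow anywhere: a single module at zero description length
        module_of = {v: 0 for v in g.nodes}
        return Partition(module_of=module_of, n_modules=1, description_length=0.0)

    isolated = [v for v in g.nodes if g.degree(v) == 0]
    if isolated:
        warnings.warn(f"dropping {len(isolated)} isolated node(s)", stacklevel=2)
        g = g.subgraph([v for v in g.nodes if g.degree(v) > 0]).copy()

    nodes = list(g.nodes)
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr").astype(float)
    diag = a.diagonal()
    a.setdiag(0.0)
    a.eliminate_zeros()
    two_w = a.sum() + 2.0 * diag.sum()
    a_off = (a / two_w).tocsr()
    selfflow = diag / two_w
    pnode = np.asarray(a_off.sum(axis=1)).ravel() + 2.0 * selfflow
    node_term = float(_plogp(pnode).sum())

    best_labels = None
    best_L = np.inf
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    for ss in streams:
        labels, length = _one_trial(a_off, selfflow.copy(), pnode, node_term, np.random.default_rng(ss))
        if length < best_L - 1e-12:
            best_L = length
            best_labels = labels

    # contiguous module ids in order of first appearance along the node list
    remap: dict[int, int] = {}
    module_of = {}
    for v, lab in zip(nodes, best_labels):
        if lab not in remap:
            remap[lab] = len(remap)
        module_of[v] = remap[lab]

    score = map_equation_length(g, module_of)
    return Partition(
        module_of=module_of,
        n_modules=len(remap),
        description_length=score.total,
    )
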