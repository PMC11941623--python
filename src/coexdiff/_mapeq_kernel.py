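"""Numba kernel for the greedy map-equation local-move phase.

All flows are normalized: edge weights are divided by twice the total edge
weight, so node visit rates and module exit rates are probabilities.  The
two-level map equation for a partition with module exit rates q_i and module
visit sums p_i decomposes as

    L = plogp(sum q_i) - 2 sum plogp(q_i) + sum plogp(q_i + p_i)
        - sum_alpha plogp(p_alpha)

with plogp(x) = x log2 x; the last term does not depend on the partition, so
single-node moves only touch the modules they enter and leave.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def _plogp(x: float) -> float:
    if x <= 0.0:
        return 0.0
    return x * np.log2(x)


@njit(cache=False)
def local_move(indptr, indices, w, text, pnode, labels, q, p, qtot_io, order):
    """Sweep nodes in `order`, greedily moving each to the neighbouring module
    that most lowers L, until a full sweep makes no move.

    labels/q/p are updated in place (modules indexed by initial singleton
    ids); qtot_io is a length-1 array holding sum(q).  Ties between equally
    good destination modules break toward the lowest module id.  Returns the
    number of accepted moves.
    """
    n = labels.size
    cand_mod = np.empty(n, dtype=np.int64)
    cand_w = np.empty(n, dtype=np.float64)
    pos = np.full(n, -1, dtype=np.int64)
    qtot = qtot_io[0]
    total_moves = 0
    improved = True
    while improved:
        improved = False
        for oi in range(n):
            v = order[oi]
            cm = labels[v]
            ncand = 0
            for e in range(indptr[v], indptr[v + 1]):
                m = labels[indices[e]]
                if pos[m] == -1:
                    pos[m] = ncand
                    cand_mod[ncand] = m
                    cand_w[ncand] = 0.0
                    ncand += 1
                cand_w[pos[m]] += w[e]
            if ncand == 0:
                continue
            tv = text[v]
            pv = pnode[v]
            e_cm = cand_w[pos[cm]] if pos[cm] != -1 else 0.0
            q_cm_new = q[cm] - tv + 2.0 * e_cm
            p_cm_new = p[cm] - pv
            base = (
                -2.0 * (_plogp(q_cm_new) - _plogp(q[cm]))
                + _plogp(q_cm_new + p_cm_new)
                - _plogp(q[cm] + p[cm])
            )
            dq_cm = q_cm_new - q[cm]
            best_dl = -1e-10
            best_mod = -1
            best_qm = 0.0
            best_dq = 0.0
            for ci in range(ncand):
                m = cand_mod[ci]
                if m == cm:
                    continue
                em = cand_w[ci]
                q_m_new = q[m] + tv - 2.0 * em
                dq = dq_cm + (q_m_new - q[m])
                dl = (
                    _plogp(qtot + dq)
                    - _plogp(qtot)
                    + base
                    - 2.0 * (_plogp(q_m_new) - _plogp(q[m]))
                    + _plogp(q_m_new + p[m] + pv)
                    - _plogp(q[m] + p[m])
                )
                take = False
                if dl < best_dl - 1e-12:
                    take = True
                elif best_mod != -1 and dl <= best_dl + 1e-12 and m < best_mod:
                    take = True
                if take:
                    if dl < best_dl:
                        best_dl = dl
                    best_mod = m
                    best_qm = q_m_new
                    best_dq = dq
            # reset scratch before applying the move
            for ci in range(ncand):
                pos[cand_mod[ci]] = -1
            if best_mod != -1:
                q[cm] = q_cm_new
                p[cm] = p_cm_new
                q[best_mod] = best_qm
                p[best_mod] += pv
                qtot += best_dq
                labels[v] = best_mod
                improved = True
                total_moves += 1
    qtot_io[0] = qtot
    return total_moves
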