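"""Generally applicable gene-set enrichment on per-gene fold changes.

Each gene set is compared against the all-gene background with a two-sample
t statistic on log2 fold changes, with separate one-sided tests for
up- and down-regulation so that sets whose members move in opposing
directions are still detectable direction by direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genesets import GeneSetCollection
from .normdge import bh_adjust
from .synthdata import CohortDesign

__all__ = ["gene_fold_changes", "gage_set_test", "gage"]


def gene_fold_changes(log_expr: pd.DataFrame, design: CohortDesign) -> pd.Series:
    """Difference of group means on the log2 scale, late minus early."""
    early = [s for s, g in zip(design.sample_id, design.group) if g == "early"]
    late = [s for s, g in zip(design.sample_id, design.group) if g == "late"]
    if len(early) == 0 or len(late) == 0:
        raise ValueError("both cohorts need at least one sample")
    return log_expr[late].mean(axis=1) - log_expr[early].mean(axis=1)


def _welch(set_vals: np.ndarray, bg_vals: np.ndarray) -> tuple[float, float]:
    m, n = set_vals.size, bg_vals.size
    v1, v2 = set_vals.var(ddof=1), bg_vals.var(ddof=1)
    se2 = v1 / m + v2 / n
    if se2 == 0:
        return 0.0, float(m + n - 2)
    t = (set_vals.mean() - bg_vals.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / m) ** 2 / (m - 1) + (v2 / n) ** 2 / (n - 1))
    return float(t), float(df)


def gage_set_test(
    fold_changes: pd.Series,
    gene_set: set[str],
    exclusive_background: bool = False,
) -> dict | None:
    """One gene set against the background: t statistic and one-sided p-values.

    Returns None when fewer than two set members are measured.  By default
    the background includes the set's own genes (the original method's
    convention); ``exclusive_background`` removes them.
    """
    members = fold_changes.index.intersection(sorted(gene_set))
    if len(members) < 2:
        return None
    set_vals = fold_changes.loc[members].to_numpy(dtype=float)
    if exclusive_background:
        bg = fold_changes.drop(members).to_numpy(dtype=float)
    else:
        bg = fold_changes.to_numpy(dtype=float)
    if bg.size < 2:
        return None
    t, df = _welch(set_vals, bg)
    p_up = float(stats.t.sf(t, df))
    p_down = float(stats.t.cdf(t, df))
    return {"t_stat": t, "df": df, "p_up": p_up, "p_down": p_down, "set_size_used": len(members)}


def _stouffer(p_values: np.ndarray) -> float:
    z = stats.norm.isf(np.clip(p_values, 1e-300, 1 - 1e-16))
    return float(stats.norm.sf(z.sum() / np.sqrt(z.size)))


def gage(
    fold_changes: pd.Series | pd.DataFrame,
    collection: GeneSetCollection,
    exclusive_background: bool = False,
    paired_columns: bool = False,
) -> pd.DataFrame:
    """Run the set test over a catalogue, BH-adjusting per direction.

    ``fold_changes`` is a Series of per-gene log2 fold changes (group-mean
    mode, the default), or with ``paired_columns=True`` a DataFrame whose
    columns are per-sample-pair fold changes; each column is tested and the
    one-sided p-values combined by Stouffer's method.

    Returns one row per usable set with columns t_stat, p_up, p_down, q_up,
    q_down and set_size_used; skipped sets (fewer than 2 measured genes)
    are recorded in ``result.attrs['skipped']``.
    """
    rows: dict[str, dict] = {}
    skipped: list[str] = []
    for term, gene_set in collection.sets.items():
        if paired_columns and isinstance(fold_changes, pd.DataFrame):
            per_col = [
                gage_set_test(fold_changes[c], gene_set, exclusive_background)
                for c in fold_changes.columns
            ]
            per_col = [r for r in per_col if r is not None]
            if not per_col:
                skipped.append(term)
                continue
            rows[term] = {
                "t_stat": float(np.mean([r["t_stat"] for r in per_col])),
                "p_up": _stouffer(np.array([r["p_up"] for r in per_col])),
                "p_down": _stouffer(np.array([r["p_down"] for r in per_col])),
                "set_size_used": per_col[0]["set_size_used"],
            }
        else:
            res = gage_set_test(fold_changes, gene_set, exclusive_background)
            if res is None:
                skipped.append(term)
                continue
            rows[term] = {k: res[k] for k in ("t_stat", "p_up", "p_down", "set_size_used")}

    result = pd.DataFrame.from_dict(rows, orient="index")
    if not result.empty:
        result["q_up"] = bh_adjust(result["p_up"].to_numpy())
        result["q_down"] = bh_adjust(result["p_down"].to_numpy())
    result.attrs["skipped"] = skipped
    return result
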