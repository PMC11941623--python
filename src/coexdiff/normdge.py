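"""TMM normalization and negative-binomial exact-test differential expression.

The between-sample normalization is the trimmed mean of M-values: per sample,
log expression ratios against a reference sample are doubly trimmed (by M and
by average log abundance A) and combined with inverse-variance precision
weights; the antilog is the sample's scaling factor.  Differential expression
between the two cohorts uses a common-dispersion NB exact test conditional on
the per-gene total count, with Benjamini-Hochberg control of the FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .synthdata import CohortDesign

__all__ = [
    "CountMatrix",
    "NormalizationFactors",
    "filter_low_expression",
    "compute_tmm_factors",
    "cpm",
    "estimate_common_dispersion",
    "exact_test",
    "bh_adjust",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with an attached cohort design."""

    counts: pd.DataFrame
    design: CohortDesign | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.design is not None and list(self.counts.columns) != list(self.design.sample_id):
            raise ValueError("count columns and design samples disagree")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_columns(self, group: str) -> np.ndarray:
        if self.design is None:
            raise ValueError("no design attached")
        return np.asarray([g == group for g in self.design.group])


@dataclass
class NormalizationFactors:
    library_size: pd.Series
    tmm_factor: pd.Series
    reference_sample: str

    @property
    def effective_library(self) -> pd.Series:
        return self.library_size * self.tmm_factor


def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int | None = None
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples.

    The boundary is inclusive; min_samples defaults to the smaller cohort
    size (or the sample count if no design is attached).  Gene order is
    preserved.
    """
    counts = cm.counts
    if min_samples is None:
        if cm.design is not None:
            sizes = [len(cm.design.samples_in(g)) for g in ("early", "late")]
            min_samples = min(s for s in sizes if s > 0)
        else:
            min_samples = counts.shape[1]
    if min_samples > counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    cpm_mat = 1e6 * counts.to_numpy(dtype=float) / lib[None, :]
    keep = (cpm_mat >= min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene", stacklevel=2)
    return CountMatrix(counts.loc[keep], cm.design)


def _choose_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    # sample whose upper-quartile CPM is closest to the mean of those quartiles
    uq = np.quantile(1e6 * counts / lib[None, :], 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def compute_tmm_factors(
    cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors, recentred to geometric mean 1.

    For sample k against the reference r, over genes positive in both:
    M_g = log2((y_gk/N_k)/(y_gr/N_r)), A_g = 0.5*log2((y_gk/N_k)(y_gr/N_r)).
    The top and bottom ``trim_m`` of genes by M and ``trim_a`` by A are
    discarded and the factor is 2**(weighted mean of the surviving M), with
    inverse approximate-variance weights
    1/w_g = (N_k-y_gk)/(N_k*y_gk) + (N_r-y_gr)/(N_r*y_gr).
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    n_samples = counts.shape[1]
    ref = _choose_reference(counts, lib)
    yr, nr = counts[:, ref], lib[ref]

    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        if k == ref:
            continue
        yk, nk = counts[:, k], lib[k]
        both = (yk > 0) & (yr > 0)
        if not both.any():
            warnings.warn(
                f"sample {cm.samples[k]} shares no positive genes with the "
                "reference; TMM factor set to 1",
                stacklevel=2,
            )
            continue
        fk, fr = yk[both] / nk, yr[both] / nr
        m = np.log2(fk / fr)
        a = 0.5 * np.log2(fk * fr)
        if np.allclose(m, m[0]):
            # all ratios identical; nothing to trim
            log_factors[k] = float(m[0])
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = m.argsort(kind="stable").argsort(kind="stable") + 1
        rank_a = a.argsort(kind="stable").argsort(kind="stable") + 1
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        ykb, yrb = yk[both][keep], yr[both][keep]
        inv_w = (nk - ykb) / (nk * ykb) + (nr - yrb) / (nr * yrb)
        w = 1.0 / inv_w
        log_factors[k] = float(np.sum(w * m[keep]) / np.sum(w))

    log_factors -= log_factors.mean()  # geometric mean 1
    return NormalizationFactors(
        library_size=pd.Series(lib, index=cm.samples),
        tmm_factor=pd.Series(2.0**log_factors, index=cm.samples),
        reference_sample=cm.samples[ref],
    )


def cpm(
    cm: CountMatrix,
    factors: NormalizationFactors | None = None,
    log: bool = False,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Counts per million of the effective (TMM-scaled) library.

    The log variant follows the usual convention of a library-size-scaled
    prior count so zeros map to a finite value.
    """
    counts = cm.counts.to_numpy(dtype=float)
    if factors is None:
        eff = counts.sum(axis=0)
    else:
        eff = factors.effective_library.reindex(cm.samples).to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("zero or negative effective library size")
    if not log:
        vals = 1e6 * counts / eff[None, :]
    else:
        # scale the prior with relative library size, as edgeR's cpm does
        prior = prior_count * eff / eff.mean()
        adj_lib = eff + 2.0 * prior
        vals = np.log2((counts + prior[None, :]) / adj_lib[None, :] * 1e6)
    return pd.DataFrame(vals, index=cm.genes, columns=cm.samples)


def _normalized_counts(cm: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    """Counts linearly rescaled to the geometric-mean effective library."""
    eff = factors.effective_library.reindex(cm.samples).to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    return cm.counts.to_numpy(dtype=float) * (common / eff)[None, :]


def estimate_common_dispersion(
    cm: CountMatrix, factors: NormalizationFactors
) -> float:
    """Single NB dispersion phi by the method of moments.

    Per gene and group, (s^2 - mu)/mu^2 estimates phi; values are pooled over
    genes weighted by within-group degrees of freedom and the result floored
    at zero.  This is a deliberately simple stand-in for likelihood-based
    dispersion estimation; it is accurate when a common dispersion holds.
    """
    if cm.design is None:
        raise ValueError("dispersion estimation requires a cohort design")
    norm = _normalized_counts(cm, factors)
    num = 0.0
    den = 0.0
    for group in ("early", "late"):
        cols = cm.group_columns(group)
        n = int(cols.sum())
        if n < 2:
            raise ValueError(f"group {group!r} has fewer than 2 samples")
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = mu > 0
        num += np.sum((n - 1) * (s2[ok] - mu[ok]) / mu[ok] ** 2)
        den += np.sum(ok * (n - 1))
    if den == 0:
        return 0.0
    return float(max(num / den, 0.0))


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi == 0.0:
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of equal means given the total s1 + s2.

    The sum of n iid NB(mu, phi) is NB(n*mu, phi/n).  Conditional on the
    total t, the probability of each split (k, t-k) is evaluated and the
    p-value is the total conditional probability of outcomes no more likely
    than the observed one.
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    k = np.arange(t + 1, dtype=float)
    logp = _nb_logpmf(k, n1 * mu, phi / n1) + _nb_logpmf(k[::-1], n2 * mu, phi / n2)
    logp -= logsumexp(logp)
    log_obs = logp[s1]
    mask = logp <= log_obs + 1e-10
    return float(min(np.exp(logsumexp(logp[mask])), 1.0))


def exact_test(
    cm: CountMatrix,
    factors: NormalizationFactors,
    dispersion: float,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB exact test of late- vs early-onset cohorts.

    Counts are first rescaled to a common effective library so group sums are
    comparable.  Returns a DataFrame with columns ``logFC`` (late over
    early, log2), ``logCPM``, ``PValue`` and ``FDR``; the orientation is
    recorded in ``df.attrs['orientation']``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if cm.design is None:
        raise ValueError("exact test requires a cohort design")
    early = cm.group_columns("early")
    late = cm.group_columns("late")
    n1, n2 = int(early.sum()), int(late.sum())
    if n1 < 1 or n2 < 1:
        raise ValueError("both cohorts need at least one sample")

    norm = _normalized_counts(cm, factors)
    pseudo = np.rint(norm).astype(np.int64)
    s_early = pseudo[:, early].sum(axis=1)
    s_late = pseudo[:, late].sum(axis=1)

    pvals = np.array(
        [
            _exact_nb_pvalue(int(se), int(sl), n1, n2, dispersion)
            for se, sl in zip(s_early, s_late)
        ]
    )

    mean_early = norm[:, early].mean(axis=1)
    mean_late = norm[:, late].mean(axis=1)
    logfc = np.log2(mean_late + prior_count) - np.log2(mean_early + prior_count)

    common = np.exp(np.mean(np.log(factors.effective_library.to_numpy(dtype=float))))
    log_cpm = np.log2((norm.mean(axis=1) + prior_count) / common * 1e6)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": log_cpm,
            "PValue": pvals,
            "FDR": bh_adjust(pvals),
        },
        index=cm.genes,
    )
    table.attrs["orientation"] = "late_over_early"
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
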