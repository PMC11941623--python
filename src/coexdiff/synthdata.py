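"""Synthetic two-cohort RNA-seq data with known ground truth.

Real early-/late-onset cohort data are controlled-access, so every downstream
stage of the pipeline is exercised against generated count matrices in which
the co-expression modules, differentially expressed genes, perturbed gene
sets and functional annotation are planted and therefore recoverable.

The generative model: each planted module m has one latent factor per sample,
``z[m, s] ~ N(0, 1)``, shared by all of the module's genes with loading
``rho``.  Gene g in sample s has negative-binomial mean

    mu[g, s] = L_s * exp(log_mu_g + rho * z[m(g), s] + delta_g * x_s) / Z_s

where ``L_s`` is the sample's library size, ``x_s`` the cohort indicator,
``delta_g`` the planted natural-log fold change, and ``Z_s`` normalises the
per-sample means to the library scale.  Counts are drawn NB with dispersion
``phi`` (``phi = 0`` reduces to Poisson).  All draws are pure functions of
``(params, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

__all__ = [
    "CohortDesign",
    "SimParams",
    "SyntheticTruth",
    "assign_cohorts",
    "simulate_design",
    "simulate_truth",
    "simulate_counts",
    "simulate_annotation",
]

BACKGROUND = "background"
LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CohortDesign:
    """Sample-to-cohort assignment via an age-at-diagnosis cutoff."""

    sample_id: tuple[str, ...]
    age_at_diagnosis: tuple[float, ...]
    group: tuple[str, ...]  # "early" | "late"
    cutoff: float = 70.0

    def __post_init__(self) -> None:
        if not (len(self.sample_id) == len(self.age_at_diagnosis) == len(self.group)):
            raise ValueError("design fields must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.sample_id)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_id, self.group) if g == group]

    def indicator(self) -> np.ndarray:
        """1 for late-onset samples, 0 for early-onset."""
        return np.asarray([1.0 if g == "late" else 0.0 for g in self.group])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "age_at_diagnosis": self.age_at_diagnosis,
                "group": self.group,
            }
        )


def assign_cohorts(
    ages: Sequence[float],
    cutoff: float = 70.0,
    sample_ids: Sequence[str] | None = None,
) -> CohortDesign:
    """Split samples into early (< cutoff) and late (>= cutoff) onset cohorts.

    A diagnosis at exactly the cutoff age is late-onset.
    """
    ages = list(ages)
    if len(ages) == 0:
        raise ValueError("empty design: at least one sample age is required")
    if any(a <= 0 for a in ages):
        raise ValueError("ages at diagnosis must be positive")
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(len(ages))]
    if len(sample_ids) != len(ages):
        raise ValueError("sample_ids and ages must have equal length")
    groups = tuple("early" if a < cutoff else "late" for a in ages)
    return CohortDesign(tuple(sample_ids), tuple(float(a) for a in ages), groups, float(cutoff))


@dataclass(frozen=True)
class SimParams:
    """Generator knobs.

    Cohort sizes default to the 47 early / 174 late imbalance of the study
    cohort.  ``factor_loading`` (rho) controls network-recovery difficulty;
    ``dispersion`` is the NB dispersion phi (variance mu + phi*mu^2).
    """

    n_genes: int = 2000
    n_modules: int = 10
    module_size: int = 50
    n_early: int = 47
    n_late: int = 174
    baseline_logmean_range: tuple[float, float] = (0.0, 4.0)
    factor_loading: float = 0.5
    dispersion: float = 0.1
    de_fraction: float = 0.05
    de_log2fc: float = 1.0
    libsize_range: tuple[float, float] = (1.0e6, 2.0e6)
    n_true_terms: int = 10
    n_decoy_terms: int = 40
    n_perturbed_sets: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_true_terms > 0 and self.n_modules == 0:
            raise ValueError("true terms require at least one module")
        if self.n_perturbed_sets > self.n_true_terms:
            raise ValueError("n_perturbed_sets cannot exceed n_true_terms")


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated experiment.

    ``de_genes`` holds the alternating-sign differential-expression planting;
    ``perturbed_genes`` holds the coherent up-shift applied to the source
    modules of ``perturbed_sets`` (the gene-set analysis ground truth).  The
    effective expression shift of a gene is the sum of the two.
    """

    genes: list[str]
    module_of: dict[str, str]
    de_genes: dict[str, float]
    perturbed_sets: list[str]
    perturbed_genes: dict[str, float]
    library_sizes: np.ndarray
    annotation: dict[str, set[str]]

    def module_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.genes:
            m = self.module_of[g]
            if m != BACKGROUND:
                out.setdefault(m, []).append(g)
        return out

    def effective_log2fc(self) -> dict[str, float]:
        lfc = dict(self.de_genes)
        for g, d in self.perturbed_genes.items():
            lfc[g] = lfc.get(g, 0.0) + d
        return lfc


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_design(params: SimParams) -> CohortDesign:
    """Draw ages around the cutoff yielding exactly n_early / n_late samples."""
    params.validate()
    (rng,) = _rng_streams(params.seed, 4)[3:]
    early_ages = rng.uniform(55.0, 69.9, size=params.n_early)
    late_ages = rng.uniform(70.0, 90.0, size=params.n_late)
    ages = np.concatenate([early_ages, late_ages])
    return assign_cohorts(ages, cutoff=70.0)


def simulate_truth(params: SimParams) -> SyntheticTruth:
    """Plant modules, DE genes, perturbed sets and an annotation catalogue.

    The first ``n_modules * module_size`` genes are partitioned into
    contiguous modules.  A fraction ``de_fraction`` of genes, evenly spaced
    across the gene list, receives +/- ``de_log2fc`` with deterministically
    alternating sign.  Each true annotation term copies one planted module's
    membership; decoy terms are uniform random gene sets.
    """
    params.validate()
    rng_truth, rng_lib, _, _ = _rng_streams(params.seed, 4)

    width = max(5, len(str(params.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(params.n_genes)]

    module_of: dict[str, str] = {}
    module_ids = [f"mod{m:02d}" for m in range(params.n_modules)]
    for i, g in enumerate(genes):
        m = i // params.module_size if params.module_size > 0 else params.n_modules
        module_of[g] = module_ids[m] if m < params.n_modules else BACKGROUND

    n_de = int(round(params.de_fraction * params.n_genes))
    de_genes: dict[str, float] = {}
    if n_de > 0:
        step = params.n_genes // n_de
        for j in range(n_de):
            sign = 1.0 if j % 2 == 0 else -1.0
            de_genes[genes[j * step]] = sign * params.de_log2fc

    annotation: dict[str, set[str]] = {}
    members = {m: set() for m in module_ids}
    for g, m in module_of.items():
        if m != BACKGROUND:
            members[m].add(g)
    true_terms = []
    for t in range(params.n_true_terms):
        src = module_ids[t % params.n_modules]
        term = f"true_{src}_{t:02d}"
        annotation[term] = set(members[src])
        true_terms.append(term)
    for d in range(params.n_decoy_terms):
        size = params.module_size if params.module_size > 0 else 20
        annotation[f"decoy{d:03d}"] = set(
            rng_truth.choice(genes, size=min(size, params.n_genes), replace=False)
        )

    perturbed_sets = true_terms[: params.n_perturbed_sets]
    perturbed_genes: dict[str, float] = {}
    for term in perturbed_sets:
        for g in annotation[term]:
            perturbed_genes[g] = params.de_log2fc

    n_samples = params.n_early + params.n_late
    lo, hi = params.libsize_range
    library_sizes = np.exp(rng_lib.uniform(np.log(lo), np.log(hi), size=n_samples))

    return SyntheticTruth(
        genes=genes,
        module_of=module_of,
        de_genes=de_genes,
        perturbed_sets=perturbed_sets,
        perturbed_genes=perturbed_genes,
        library_sizes=library_sizes,
        annotation=annotation,
    )


def simulate_counts(
    truth: SyntheticTruth, design: CohortDesign, params: SimParams
) -> pd.DataFrame:
    """Draw the gene x sample count matrix under the latent-factor NB model.

    Returns an integer DataFrame indexed by gene id with sample-id columns.
    """
    params.validate()
    if design.n_samples != len(truth.library_sizes):
        raise ValueError("design and truth disagree on sample count")
    _, _, rng_counts, _ = _rng_streams(params.seed, 4)

    n_genes = len(truth.genes)
    n_samples = design.n_samples
    rho = params.factor_loading
    phi = params.dispersion

    log_mu = rng_counts.uniform(*params.baseline_logmean_range, size=n_genes)

    module_ids = sorted({m for m in truth.module_of.values() if m != BACKGROUND})
    mod_index = {m: i for i, m in enumerate(module_ids)}
    gene_mod = np.array(
        [mod_index.get(truth.module_of[g], -1) for g in truth.genes], dtype=np.int64
    )
    z = rng_counts.standard_normal(size=(max(len(module_ids), 1), n_samples))

    lfc = truth.effective_log2fc()
    delta = np.array([LN2 * lfc.get(g, 0.0) for g in truth.genes])
    x = design.indicator()

    eta = log_mu[:, None] + delta[:, None] * x[None, :]
    in_module = gene_mod >= 0
    eta[in_module, :] += rho * z[gene_mod[in_module], :]

    w = np.exp(eta)
    mean = truth.library_sizes[None, :] * w / w.sum(axis=0, keepdims=True)

    if phi == 0.0:
        counts = rng_counts.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng_counts.negative_binomial(r, r / (r + mean))

    return pd.DataFrame(counts.astype(np.int64), index=truth.genes, columns=design.sample_id)


def simulate_annotation(truth: SyntheticTruth) -> GeneSetCollection:
    """Package the planted annotation as a GMT-writable gene-set collection."""
    if not truth.annotation:
        raise ValueError("truth carries no annotation terms")
    descriptions = {
        t: ("planted module copy" if t.startswith("true_") else "decoy term")
        for t in truth.annotation
    }
    return GeneSetCollection(
        sets={t: set(g) for t, g in truth.annotation.items()},
        descriptions=descriptions,
    )
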