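"""Incidence-based beta-diversity partitioning into turnover and nestedness.

Total Sørensen dissimilarity splits additively into a turnover component
(Simpson-based: species replacement between sites) and a nestedness-resultant
component (ordered species loss, poorer sites being subsets of richer ones).

For a site pair with ``a`` shared features and ``b``, ``c`` features unique
to each site::

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_nes = beta_sor - beta_sim

The multi-site forms summarize all sites of a metacommunity at once rather
than averaging pairs.  With ``S_i`` the richness of site ``i``, ``S_T`` the
pooled richness, and ``b_ij`` the number of features in site ``i`` absent
from site ``j``::

    beta_SIM = sum_min / ((sum_i S_i - S_T) + sum_min)
    beta_SOR = (sum_min + sum_max) / (2 (sum_i S_i - S_T) + sum_min + sum_max)
    beta_NES = beta_SOR - beta_SIM

where ``sum_min`` and ``sum_max`` run over ``min(b_ij, b_ji)`` and
``max(b_ij, b_ji)`` for all unordered pairs.  On two sites the multi-site
forms coincide exactly with the pairwise ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortDesign, FeatureTable

__all__ = [
    "BetaPartition",
    "ResampledPartition",
    "pairwise_partition",
    "multisite_partition",
    "cohort_partitions",
]


@dataclass(frozen=True)
class BetaPartition:
    """Multi-site Sørensen dissimilarity and its turnover/nestedness split."""

    beta_sor: float
    beta_sim: float
    beta_nes: float
    n_sites: int

    @property
    def nestedness_turnover_ratio(self) -> float:
        """beta_NES / beta_SIM; NaN when turnover is zero."""
        if self.beta_sim == 0:
            return math.nan
        return self.beta_nes / self.beta_sim


@dataclass(frozen=True)
class ResampledPartition:
    """Mean and SD of multi-site components over site resamples of equal size."""

    mean: BetaPartition
    sd_sor: float
    sd_sim: float
    sd_nes: float
    n_resampled_sites: int
    n_repetitions: int


def pairwise_partition(a: set, b: set) -> tuple[float, float, float]:
    """Pairwise (beta_sor, beta_sim, beta_nes) for two feature sets."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both feature sets are empty")
    shared = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    beta_sor = (only_a + only_b) / (2 * shared + only_a + only_b)
    m = min(only_a, only_b)
    beta_sim = m / (shared + m) if (shared + m) else 0.0
    return beta_sor, beta_sim, beta_sor - beta_sim


def multisite_partition(incidence: np.ndarray | pd.DataFrame) -> BetaPartition:
    """Multi-site partition of a binary ``[site, feature]`` matrix.

    Features absent from every site are removed first; every site must retain
    at least one feature.  The result is invariant to site and feature order.
    """
    if isinstance(incidence, pd.DataFrame):
        site_names = [str(s) for s in incidence.index]
        mat = incidence.to_numpy()
    else:
        mat = np.asarray(incidence)
        site_names = [str(i) for i in range(mat.shape[0])]
    mat = (mat > 0).astype(np.int64)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("multisite_partition requires at least 2 sites")
    mat = mat[:, mat.sum(axis=0) > 0]
    richness = mat.sum(axis=1)
    empty = np.flatnonzero(richness == 0)
    if empty.size:
        raise ValueError(f"site {site_names[empty[0]]!r} has no features")
    n = mat.shape[0]
    shared = mat @ mat.T  # shared[i, j] = features common to sites i and j
    b = richness[:, None] - shared  # b[i, j] = features in i absent from j
    iu = np.triu_indices(n, k=1)
    sum_min = float(np.minimum(b[iu], b.T[iu]).sum())
    sum_max = float(np.maximum(b[iu], b.T[iu]).sum())
    pooled = int((mat.sum(axis=0) > 0).sum())
    excess = float(richness.sum() - pooled)  # sum_i S_i - S_T
    denom_sim = excess + sum_min
    beta_sim = sum_min / denom_sim if denom_sim else 0.0
    denom_sor = 2 * excess + sum_min + sum_max
    beta_sor = (sum_min + sum_max) / denom_sor if denom_sor else 0.0
    return BetaPartition(
        beta_sor=beta_sor,
        beta_sim=beta_sim,
        beta_nes=beta_sor - beta_sim,
        n_sites=n,
    )


def _cohort_incidence(table: FeatureTable, samples: list[str]) -> pd.DataFrame:
    sub = table.subset_samples(samples, drop_empty_features=True)
    return sub.incidence()


def cohort_partitions(
    table: FeatureTable,
    design: CohortDesign,
    resample_n: int | None = None,
    resample_reps: int = 100,
    seed: int | None = None,
) -> dict[str, BetaPartition | ResampledPartition]:
    """Multi-site partition per cohort, on cohort-restricted incidence.

    With ``resample_n`` set, each cohort is summarized by the mean and SD of
    the partition over ``resample_reps`` random subsets of ``resample_n``
    samples, equalizing site numbers across cohorts of unequal size.
    """
    out: dict[str, BetaPartition | ResampledPartition] = {}
    rng = np.random.default_rng(seed)
    for cohort in design.cohorts:
        samples = design.samples_of(cohort)
        if len(samples) < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")
        inc = _cohort_incidence(table, samples)
        if resample_n is None:
            out[cohort] = multisite_partition(inc)
            continue
        if resample_n < 2 or resample_n > len(samples):
            raise ValueError(
                f"resample_n must be in [2, {len(samples)}] for cohort {cohort!r}"
            )
        triples = np.empty((resample_reps, 3))
        for r in range(resample_reps):
            pick = rng.choice(len(samples), size=resample_n, replace=False)
            p = multisite_partition(inc.iloc[pick])
            triples[r] = (p.beta_sor, p.beta_sim, p.beta_nes)
        mean = triples.mean(axis=0)
        sd = triples.std(axis=0)
        out[cohort] = ResampledPartition(
            mean=BetaPartition(mean[0], mean[1], mean[2], n_sites=resample_n),
            sd_sor=float(sd[0]),
            sd_sim=float(sd[1]),
            sd_nes=float(sd[2]),
            n_resampled_sites=resample_n,
            n_repetitions=resample_reps,
        )
    return out
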