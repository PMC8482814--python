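"""Null-model quantification of stochastic versus deterministic assembly.

For every pair of samples in a cohort, the observed Bray–Curtis similarity
``C`` is compared with the similarity ``E`` expected under a null model that
reassembles the cohort from its regional feature pool while preserving each
sample's total reads, drawing per-sample richness and feature identity
proportionally to the observed richness and occurrence frequencies.

The normalized gap between observed and expected similarity is the selection
strength::

    SS = (C - E) / C          when C >= E  (homogenizing selection)
    SS = (D - E_D) / D        when C < E, with D = 1 - C, E_D = 1 - E
                              (diverging selection)

so ``SS`` lies in [0, 1] whichever direction determinism acts.  The
stochasticity ratio ``ST = 1 - SS`` is the fraction of community structuring
attributed to stochastic processes; cohort summaries are reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

from .io import CohortDesign, FeatureTable

__all__ = [
    "NullModelConfig",
    "StochasticityResult",
    "bray_curtis",
    "null_community",
    "expected_similarity",
    "selection_strength",
    "stochasticity_ratio",
]


@dataclass(frozen=True)
class NullModelConfig:
    """Constraints and replication settings for the community null model.

    ``richness_constraint="proportional"`` draws per-sample richness with
    expectation proportional to the observed richness; ``"fixed"`` keeps each
    sample's observed richness exactly.  ``frequency_constraint`` weights
    feature selection by regional occurrence frequency (``"proportional"``)
    or uniformly (``"equiprobable"``).
    """

    n_randomizations: int = 1000
    richness_constraint: str = "proportional"
    frequency_constraint: str = "proportional"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.richness_constraint not in ("proportional", "fixed"):
            raise ValueError(f"unknown richness constraint {self.richness_constraint!r}")
        if self.frequency_constraint not in ("proportional", "equiprobable"):
            raise ValueError(f"unknown frequency constraint {self.frequency_constraint!r}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.n_randomizations < 100:
            warnings.warn(
                f"n_randomizations={self.n_randomizations} is below 100; "
                "expected-similarity estimates will be noisy",
                stacklevel=2,
            )


@dataclass
class StochasticityResult:
    """Per-pair selection strengths and the cohort-level summary.

    ``pairs`` has one row per unordered sample pair with columns
    ``sample_i, sample_j, observed, expected, selection_strength,
    stochasticity``.  ``mean_st_pct`` / ``sd_st_pct`` summarize the
    stochasticity ratio over pairs in percent (population SD).
    """

    cohort: str
    pairs: pd.DataFrame
    mean_st_pct: float
    sd_st_pct: float
    n_randomizations: int = field(default=0)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity ``sum |x - y| / sum (x + y)`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(braycurtis(x, y))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Indices of ``k`` items drawn successively without replacement, with
    inclusion at each step proportional to the remaining weights.

    Uses the Gumbel-top-k equivalence: perturb log-weights with Gumbel noise
    and keep the largest ``k`` keys, which reproduces the successive
    weighted-sampling distribution in one vectorized pass.
    """
    keys = np.log(weights) + rng.gumbel(size=weights.shape)
    return np.argpartition(keys, -k)[-k:]


def _null_matrix(
    counts: np.ndarray,
    rng: np.random.Generator,
    richness_constraint: str,
    frequency_constraint: str,
) -> np.ndarray:
    """One randomized cohort matrix on the cohort's regional pool.

    ``counts`` is the cohort block, already restricted to features with at
    least one count (the regional pool).  Per-sample totals are conserved
    exactly; every selected feature receives at least one read, and the
    remaining reads are allocated multinomially with weights equal to the
    regional mean relative abundances renormalized over the selected features.
    """
    counts = np.asarray(counts)
    n, f = counts.shape
    totals = counts.sum(axis=1).astype(np.int64)
    richness = (counts > 0).sum(axis=1).astype(np.int64)
    occurrence = (counts > 0).sum(axis=0).astype(float)  # regional occurrence counts
    rel = counts / totals[:, None]
    mean_rel = rel.mean(axis=0)

    if richness_constraint == "fixed":
        target = richness.copy()
    else:
        total_occ = int(richness.sum())
        alloc = rng.multinomial(total_occ, richness / richness.sum())
        target = np.clip(alloc, 1, f)
    over = target > totals
    if np.any(over):
        warnings.warn(
            "null richness capped at sample total reads for "
            f"{int(over.sum())} sample(s)",
            stacklevel=2,
        )
        target = np.minimum(target, totals)

    if frequency_constraint == "proportional":
        weights = occurrence
    else:
        weights = np.ones(f)

    null = np.zeros((n, f), dtype=np.int64)
    for i in range(n):
        k = int(target[i])
        chosen = _weighted_sample_without_replacement(rng, weights, k)
        null[i, chosen] = 1
        remainder = int(totals[i]) - k
        if remainder > 0:
            p = mean_rel[chosen]
            null[i, chosen] += rng.multinomial(remainder, p / p.sum())
    return null


def _draw_rng(seed: int, draw_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(draw_index)]))


def _cohort_block(table: FeatureTable, cohort_samples: list[str]) -> FeatureTable:
    if len(cohort_samples) < 2:
        raise ValueError("a cohort needs at least 2 samples for the null model")
    block = table.subset_samples(cohort_samples, drop_empty_features=True)
    totals = block.data.sum(axis=1)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total count")
    return block


def null_community(
    table: FeatureTable,
    cohort_samples: list[str],
    config: NullModelConfig,
    draw_index: int = 0,
) -> FeatureTable:
    """One randomized cohort table, reproducible from ``(config.seed, draw_index)``."""
    block = _cohort_block(table, cohort_samples)
    rounded = np.rint(block.counts)
    if not np.allclose(block.counts, rounded, atol=1e-9):
        raise ValueError("the null model requires integer-valued counts")
    rng = _draw_rng(config.seed, draw_index)
    null = _null_matrix(
        rounded.astype(np.int64),
        rng,
        config.richness_constraint,
        config.frequency_constraint,
    )
    data = pd.DataFrame(null.astype(float), index=block.sample_ids, columns=block.feature_ids)
    return FeatureTable(data=data, feature_kind=block.feature_kind, lineages=block.lineages)


def expected_similarity(
    table: FeatureTable,
    cohort_samples: list[str],
    config: NullModelConfig,
) -> dict[tuple[str, str], float]:
    """Mean null Bray–Curtis similarity per unordered sample pair."""
    block = _cohort_block(table, cohort_samples)
    rounded = np.rint(block.counts)
    if not np.allclose(block.counts, rounded, atol=1e-9):
        raise ValueError("the null model requires integer-valued counts")
    base = rounded.astype(np.int64)
    n = base.shape[0]
    acc = np.zeros(n * (n - 1) // 2)
    for d in range(config.n_randomizations):
        rng = _draw_rng(config.seed, d)
        null = _null_matrix(
            base, rng, config.richness_constraint, config.frequency_constraint
        )
        acc += 1.0 - pdist(null.astype(float), metric="braycurtis")
    acc /= config.n_randomizations
    ids = block.sample_ids
    out: dict[tuple[str, str], float] = {}
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[(ids[i], ids[j])] = float(acc[idx])
            idx += 1
    return out


def selection_strength(C: float, E: float) -> float:
    """Normalized observed-vs-expected similarity gap in [0, 1].

    Homogenizing selection (``C >= E``) is scored on the similarity scale;
    diverging selection (``C < E``) on the dissimilarity scale, so both
    directions of determinism register symmetrically.
    """
    if not (0 <= C <= 1 and 0 <= E <= 1):
        raise ValueError("similarities must lie in [0, 1]")
    if C >= E:
        return (C - E) / C if C > 0 else 0.0
    D, E_D = 1.0 - C, 1.0 - E
    return (D - E_D) / D


def stochasticity_ratio(
    table: FeatureTable,
    design: CohortDesign,
    config: NullModelConfig,
) -> dict[str, StochasticityResult]:
    """Per-cohort stochasticity ratios over all unordered sample pairs.

    Works identically for taxon and pathway tables; each cohort's samples
    share one regional pool (the features observed anywhere in the cohort).
    """
    results: dict[str, StochasticityResult] = {}
    for cohort in design.cohorts:
        samples = design.samples_of(cohort)
        block = _cohort_block(table, samples)
        obs = squareform(1.0 - pdist(block.counts, metric="braycurtis"))
        expected = expected_similarity(table, samples, config)
        rows = []
        ids = block.sample_ids
        for (si, sj), e_ij in expected.items():
            c_ij = float(obs[ids.index(si), ids.index(sj)])
            ss = selection_strength(c_ij, e_ij)
            rows.append(
                {
                    "sample_i": si,
                    "sample_j": sj,
                    "observed": c_ij,
                    "expected": e_ij,
                    "selection_strength": ss,
                    "stochasticity": 1.0 - ss,
                }
            )
        pairs = pd.DataFrame(rows)
        st = pairs["stochasticity"].to_numpy()
        results[cohort] = StochasticityResult(
            cohort=cohort,
            pairs=pairs,
            mean_st_pct=float(st.mean() * 100.0),
            sd_st_pct=float(st.std() * 100.0),
            n_randomizations=config.n_randomizations,
        )
    return results
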