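"""Synthetic multi-cohort microbiome datasets with controllable ecology.

The generator emulates denoised, species-annotated amplicon count tables:
a regional pool with a log-normal rank–abundance distribution, per-sample
read depths in a realistic sequencing range, and four independently tunable
layers of ecological structure:

* **assembly** — ``neutral`` samples are plain multinomial draws from the
  regional pool (pure stochastic assembly); ``filtered`` samples draw from
  cohort-specific weights ``pool_t * exp(w * e_tc)`` with fixed
  standard-normal taxon-by-cohort effects ``e_tc``, so the filter strength
  ``w`` is the only knob controlling deterministic selection.
* **structure** — ``turnover`` assigns samples round-robin to disjoint
  blocks of the pool (species replacement dominates); ``nestedness`` gives
  each sample a random-size top slice of the abundance-ranked pool (poorer
  samples are approximate subsets of richer ones).
* **core targets** — a designated set of taxa is forced to a target
  prevalence per cohort, planting a recoverable core microbiome.
* **planted signatures** — selected moderately abundant taxa are enriched by
  a fold change in one cohort, planting recoverable differential features.

A taxa-to-pathway trait matrix with tunable redundancy (how many taxa carry
each pathway) supports the taxonomy-versus-function contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortDesign, FeatureTable, TraitMatrix

__all__ = [
    "SyntheticSpec",
    "make_pool",
    "sample_cohort",
    "make_traits",
    "make_dataset",
    "planted_core_features",
    "planted_signature_features",
]

# Defaults mirror the emulated study conditions: three cohorts of 27/21/27
# saliva samples, 40k-60k reads per sample, a few hundred detectable species.
DEFAULT_COHORTS: tuple[tuple[str, int], ...] = (("normal", 27), ("OVH", 21), ("OSCC", 27))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort dataset.

    ``core_target`` is ``(n_core, prevalence)``; ``planted_signatures`` is
    ``(cohort_label, n_features, fold_change)``.
    """

    n_pool: int = 600
    abundance_lognormal: tuple[float, float] = (0.0, 2.0)
    cohorts: tuple[tuple[str, int], ...] = DEFAULT_COHORTS
    depth_range: tuple[int, int] = (40_000, 60_000)
    assembly: str = "neutral"
    filter_strength: float = 0.0
    structure: str = "none"
    core_target: tuple[int, float] | None = None
    n_pathways: int = 300
    redundancy: int = 3
    planted_signatures: tuple[str, int, float] | None = None
    n_turnover_blocks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pool < 2:
            raise ValueError("n_pool must be >= 2")
        if self.assembly not in ("neutral", "filtered"):
            raise ValueError(f"unknown assembly mode {self.assembly!r}")
        if self.structure not in ("none", "turnover", "nestedness"):
            raise ValueError(f"unknown structure mode {self.structure!r}")
        if self.filter_strength < 0:
            raise ValueError("filter_strength must be >= 0")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth_range")
        if self.core_target is not None and not (0 < self.core_target[1] <= 1):
            raise ValueError("core prevalence target must lie in (0, 1]")
        if any(n < 1 for _, n in self.cohorts):
            raise ValueError("every cohort needs at least 1 sample")

    @property
    def cohort_labels(self) -> list[str]:
        return [label for label, _ in self.cohorts]


def _rng(spec: SyntheticSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), *stream]))


def make_pool(spec: SyntheticSpec) -> np.ndarray:
    """Regional relative-abundance vector: normalized log-normal draws."""
    mu, sigma = spec.abundance_lognormal
    x = np.exp(_rng(spec, 0).normal(mu, sigma, spec.n_pool))
    return x / x.sum()


def _filter_effects(spec: SyntheticSpec) -> np.ndarray:
    """Fixed taxon-by-cohort selection effects, drawn once per dataset seed."""
    return _rng(spec, 1).standard_normal((spec.n_pool, len(spec.cohorts)))


def planted_core_features(spec: SyntheticSpec, cohort_index: int) -> list[int]:
    """Indices of the taxa planted as the cohort's core (empty if none)."""
    if spec.core_target is None:
        return []
    n_core, _ = spec.core_target
    rng = _rng(spec, 3, cohort_index)
    # draw cores from the upper half of the abundance ranking so that planted
    # members are detectable at realistic depths
    pool = make_pool(spec)
    ranked = np.argsort(pool)[::-1]
    upper = ranked[: max(n_core, spec.n_pool // 2)]
    return sorted(rng.choice(upper, size=n_core, replace=False).tolist())


def planted_signature_features(spec: SyntheticSpec) -> list[int]:
    """Indices of the taxa planted as differential signatures (empty if none)."""
    if spec.planted_signatures is None:
        return []
    _, n_feat, _ = spec.planted_signatures
    pool = make_pool(spec)
    # plant in a moderate-abundance window (~200-800 ppm): abundant enough
    # for the enrichment to be detectable at sequencing depth, small enough
    # that compositional closure barely perturbs the rest of the community
    window = np.flatnonzero((pool >= 3.5e-4) & (pool <= 8e-4))
    if window.size < n_feat:
        order = np.argsort(np.abs(pool - 5e-4))
        window = order[: max(n_feat, 20)]
    rng = _rng(spec, 4)
    return sorted(rng.choice(window, size=n_feat, replace=False).tolist())


def sample_cohort(pool: np.ndarray, spec: SyntheticSpec, cohort_index: int) -> np.ndarray:
    """Count block ``[sample, taxon]`` for one cohort.

    All randomness flows through a cohort-specific stream, so ``filtered``
    assembly at ``w = 0`` reproduces the ``neutral`` tables bit for bit.
    """
    label, n_samples = spec.cohorts[cohort_index]
    rng = _rng(spec, 2, cohort_index)
    weights = np.asarray(pool, dtype=float).copy()
    if spec.assembly == "filtered":
        effects = _filter_effects(spec)[:, cohort_index]
        weights = weights * np.exp(spec.filter_strength * effects)
    if spec.planted_signatures is not None and spec.planted_signatures[0] == label:
        idx = planted_signature_features(spec)
        weights[idx] *= spec.planted_signatures[2]
    weights = weights / weights.sum()

    ranked = np.argsort(pool)[::-1]
    core_idx = planted_core_features(spec, cohort_index)
    core_prev = spec.core_target[1] if spec.core_target else 0.0

    counts = np.zeros((n_samples, spec.n_pool), dtype=np.int64)
    for j in range(n_samples):
        depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        w = weights
        if spec.structure == "turnover":
            block = (cohort_index + j) % spec.n_turnover_blocks
            members = np.arange(spec.n_pool) % spec.n_turnover_blocks == block
            w = np.where(members, weights, 0.0)
            w = w / w.sum()
        elif spec.structure == "nestedness":
            # cohort-level pool shrinks with cohort index; each sample keeps a
            # random-size top slice, making poorer samples subsets of richer
            f_cohort = max(0.3, 1.0 - 0.15 * cohort_index)
            frac = rng.uniform(0.25, 1.0) * f_cohort
            k = max(2, int(np.ceil(frac * spec.n_pool)))
            keep = ranked[:k]
            mask = np.zeros(spec.n_pool, dtype=bool)
            mask[keep] = True
            w = np.where(mask, weights, 0.0)
            w = w / w.sum()
        row = rng.multinomial(depth, w)
        if core_idx:
            donor_pool = np.flatnonzero(w > 0)
            for t in core_idx:
                if row[t] == 0 and rng.random() < core_prev:
                    boost = 1 + int(rng.poisson(2.0))
                    donor = donor_pool[np.argmax(row[donor_pool])]
                    boost = min(boost, int(row[donor]) - 1)
                    if boost > 0:
                        row[t] += boost
                        row[donor] -= boost
        counts[j] = row
    return counts


def make_traits(spec: SyntheticSpec) -> TraitMatrix:
    """Trait matrix where every pathway is carried by ``redundancy`` taxa.

    Carriers are assigned by slicing a cycled random permutation of the pool,
    so each pathway has exactly ``redundancy`` distinct carriers and, when
    ``n_pathways * redundancy >= n_pool``, every taxon carries at least one
    pathway.  Copy numbers are uniform on {1, 2, 3}.
    """
    r = spec.redundancy
    if r < 1 or spec.n_pathways < 1:
        raise ValueError("redundancy and n_pathways must be >= 1")
    if r > spec.n_pool:
        raise ValueError(f"redundancy {r} exceeds pool size {spec.n_pool}")
    if spec.n_pathways * r < spec.n_pool:
        warnings.warn(
            "n_pathways * redundancy < n_pool: some taxa will carry no pathway",
            stacklevel=2,
        )
    rng = _rng(spec, 5)
    perm = rng.permutation(spec.n_pool)
    slots = perm[np.arange(spec.n_pathways * r) % spec.n_pool].reshape(spec.n_pathways, r)
    mat = np.zeros((spec.n_pool, spec.n_pathways), dtype=float)
    copies = rng.integers(1, 4, size=slots.shape)
    for p in range(spec.n_pathways):
        mat[slots[p], p] = copies[p]
    data = pd.DataFrame(
        mat,
        index=_taxon_ids(spec.n_pool),
        columns=[f"pwy{p:04d}" for p in range(spec.n_pathways)],
    )
    return TraitMatrix(data=data)


def _taxon_ids(n: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(n)]


def _lineage(i: int) -> tuple[str, ...]:
    return (
        "Bacteria",
        f"Phylum{i % 8}",
        f"Class{i % 16}",
        f"Order{i % 32}",
        f"Family{i % 60}",
        f"Genus{i % 150}",
        f"Species sp{i:04d}",
    )


def make_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, CohortDesign, TraitMatrix]:
    """Assemble the full multi-cohort dataset, design and trait matrix."""
    pool = make_pool(spec)
    blocks = []
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    for c, (label, n_samples) in enumerate(spec.cohorts):
        blocks.append(sample_cohort(pool, spec, c))
        for j in range(n_samples):
            sid = f"{label}_{j:03d}"
            sample_ids.append(sid)
            assignments[sid] = label
    counts = np.vstack(blocks)
    taxa = _taxon_ids(spec.n_pool)
    data = pd.DataFrame(counts.astype(float), index=sample_ids, columns=taxa)
    # the observable table holds only taxa detected somewhere
    data = data.loc[:, data.sum(axis=0) > 0]
    lineages = {f: _lineage(int(f[2:])) for f in data.columns}
    table = FeatureTable(data=data, feature_kind="taxon", lineages=lineages)
    design = CohortDesign(assignments=assignments, cohort_order=list(spec.cohort_labels))
    traits = make_traits(spec)
    return table, design, traits
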