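"""Count-table transforms and prevalence-based core-microbiome analysis.

Rarefaction subsamples every sample's reads without replacement to a common
depth so that richness-sensitive statistics are comparable across samples.
The core microbiome of a cohort is the set of features whose prevalence
(fraction of samples where the feature is detected) meets a threshold,
conventionally 75%.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.diversity.alpha import pielou_e, shannon

from .io import CohortDesign, FeatureTable

__all__ = [
    "CoreSet",
    "rarefy",
    "to_relative",
    "collapse_rank",
    "prevalence",
    "core_sets",
    "alpha_diversity",
]

VENN_SEP = "∩"


def rarefy(
    table: FeatureTable,
    depth: int,
    seed: int,
    on_shallow: str = "drop",
) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning
    (``on_shallow="drop"``) or raise (``"error"``).  Features left with zero
    counts everywhere are removed.  The draw is a multivariate hypergeometric
    per sample, i.e. equivalent to drawing ``depth`` reads from the sample's
    read urn, and is reproducible from ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if on_shallow not in ("drop", "error"):
        raise ValueError(f"on_shallow must be 'drop' or 'error', got {on_shallow!r}")
    counts = table.counts
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-9):
        raise ValueError("rarefy requires integer-valued counts")
    rounded = rounded.astype(np.int64)
    rng = np.random.default_rng(seed)
    kept_rows = []
    kept_ids = []
    for i, sample in enumerate(table.sample_ids):
        total = int(rounded[i].sum())
        if total < depth:
            if on_shallow == "error":
                raise ValueError(f"sample {sample!r} has {total} reads < depth {depth}")
            warnings.warn(
                f"sample {sample!r} dropped: {total} reads < rarefaction depth {depth}",
                stacklevel=2,
            )
            continue
        kept_rows.append(rng.multivariate_hypergeometric(rounded[i], depth))
        kept_ids.append(sample)
    if not kept_ids:
        raise ValueError("no sample reaches the rarefaction depth")
    data = pd.DataFrame(np.asarray(kept_rows, dtype=float), index=kept_ids, columns=table.feature_ids)
    data = data.loc[:, data.sum(axis=0) > 0]
    lineages = None
    if table.lineages is not None:
        lineages = {f: table.lineages[f] for f in data.columns}
    return FeatureTable(data=data, feature_kind=table.feature_kind, lineages=lineages)


def to_relative(table: FeatureTable) -> FeatureTable:
    """Normalize each sample to relative abundances summing to 1."""
    totals = table.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    data = table.data.div(totals, axis=0)
    return FeatureTable(data=data, feature_kind=table.feature_kind, lineages=table.lineages)


def collapse_rank(table: FeatureTable, rank_index: int) -> FeatureTable:
    """Aggregate features to the taxonomic rank at position ``rank_index``.

    Features whose lineage is shorter than ``rank_index + 1`` or whose rank
    slot is empty are pooled under ``"Unclassified_at_rank"``.  Per-sample
    totals are conserved exactly.
    """
    if rank_index < 0:
        raise ValueError("rank_index must be non-negative")
    if table.lineages is None:
        raise ValueError("table has no lineages; cannot collapse by rank")
    groups: dict[str, list[str]] = {}
    group_lineage: dict[str, tuple[str, ...]] = {}
    for f in table.feature_ids:
        lin = table.lineages[f]
        if len(lin) > rank_index and lin[rank_index]:
            name = lin[rank_index]
            trunc = lin[: rank_index + 1]
        else:
            name = "Unclassified_at_rank"
            trunc = ("Unclassified_at_rank",)
        groups.setdefault(name, []).append(f)
        group_lineage.setdefault(name, trunc)
    cols = {name: table.data[members].sum(axis=1) for name, members in groups.items()}
    data = pd.DataFrame(cols, index=table.data.index)
    return FeatureTable(data=data, feature_kind=table.feature_kind, lineages=group_lineage)


def prevalence(table: FeatureTable, samples: list[str] | None = None) -> pd.Series:
    """Fraction of the given samples in which each feature is detected."""
    sub = table.data if samples is None else table.subset_samples(samples).data
    if sub.shape[0] == 0:
        raise ValueError("prevalence requires a non-empty sample subset")
    return (sub > 0).sum(axis=0) / sub.shape[0]


@dataclass
class CoreSet:
    """Per-cohort core features, their Venn decomposition and core fractions.

    ``venn`` maps a region label such as ``"normal∩OSCC"`` to the features
    core in exactly those cohorts; the regions are disjoint and jointly cover
    the union of all cores.  ``core_fraction`` divides the core count by the
    cohort's gamma richness (features observed anywhere in the cohort).
    """

    threshold: float
    inclusive: bool
    per_cohort_core: dict[str, set[str]] = field(default_factory=dict)
    venn: dict[str, set[str]] = field(default_factory=dict)
    core_fraction: dict[str, float] = field(default_factory=dict)


def core_sets(
    table: FeatureTable,
    design: CohortDesign,
    threshold: float = 0.75,
    inclusive: bool = True,
) -> CoreSet:
    """Compute cohort core microbiomes at a prevalence threshold.

    ``inclusive=True`` admits features at exactly the threshold (prevalence
    >= threshold); ``inclusive=False`` requires strictly greater prevalence.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    cores: dict[str, set[str]] = {}
    fractions: dict[str, float] = {}
    for cohort in design.cohorts:
        samples = design.samples_of(cohort)
        if not samples:
            raise ValueError(f"cohort {cohort!r} has no samples")
        prev = prevalence(table, samples)
        if inclusive:
            core = set(prev.index[prev >= threshold])
        else:
            core = set(prev.index[prev > threshold])
        cores[cohort] = core
        richness = int((table.subset_samples(samples).data.sum(axis=0) > 0).sum())
        fractions[cohort] = len(core) / richness if richness else 0.0
    venn: dict[str, set[str]] = {}
    labels = design.cohorts
    for k in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            inside = set.intersection(*(cores[c] for c in combo))
            for other in labels:
                if other not in combo:
                    inside = inside - cores[other]
            venn[VENN_SEP.join(combo)] = inside
    return CoreSet(
        threshold=threshold,
        inclusive=inclusive,
        per_cohort_core=cores,
        venn=venn,
        core_fraction=fractions,
    )


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Observed richness, Shannon entropy (nats) and Pielou evenness per sample."""
    rows = {}
    for sample in table.sample_ids:
        counts = table.data.loc[sample].to_numpy(dtype=float)
        present = counts[counts > 0]
        obs = int(present.size)
        h = float(shannon(counts, base=math.e)) if obs else 0.0
        rows[sample] = {
            "observed_features": obs,
            "shannon": h,
            "pielou_evenness": float(pielou_e(counts)) if obs > 1 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
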