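"""Signature-feature screening: Kruskal–Wallis plus LDA effect size.

The screen follows the two-stage logic of effect-size-based differential
abundance analysis: features are first filtered by a Kruskal–Wallis rank test
across cohorts at a significance level alpha, then each surviving feature is
scored by a bootstrap linear-discriminant effect size on relative abundances
scaled to a per-sample total of one million.  A feature is reported as a
cohort signature when its log10 effect size exceeds the cutoff
(conventionally 3, i.e. an effect of 10^3 on the million scale).

This is a deliberate simplification of the published LEfSe tool: there is no
subclass (Wilcoxon) stage, and the multi-class contrast is one-vs-rest with
the enriched class defined as the cohort with the highest mean relative
abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import rarefy, to_relative
from .io import CohortDesign, FeatureTable

__all__ = [
    "EffectSizeRecord",
    "kruskal_wallis",
    "lda_effect_size",
    "signature_features",
]

MILLION = 1e6
RIDGE = 1e-6  # scale factor for the trace-scaled ridge on the within-class scatter


@dataclass
class EffectSizeRecord:
    feature_id: str
    kw_statistic: float
    p_value: float
    enriched_cohort: str
    lda_score: float
    passes: bool


def kruskal_wallis(values: np.ndarray, classes: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p-value.

    When every observation is identical the statistic is degenerate; the
    convention here is ``(0.0, 1.0)``.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    labels = pd.unique(classes)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis needs at least 2 classes")
    groups = []
    for lab in labels:
        g = values[classes == lab]
        if g.size == 0:
            raise ValueError(f"class {lab!r} has no samples")
        groups.append(g)
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _bootstrap_indices(
    rng: np.random.Generator, labels: np.ndarray, fraction: float
) -> np.ndarray:
    """Per-class subsample without replacement, at least 2 samples per class."""
    keep: list[np.ndarray] = []
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        k = max(2, math.ceil(fraction * idx.size))
        keep.append(rng.choice(idx, size=min(k, idx.size), replace=False))
    return np.concatenate(keep)


def lda_effect_size(
    data: pd.DataFrame,
    design: CohortDesign,
    candidates: list[str],
    n_boot: int = 30,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> dict[str, float]:
    """log10 LDA effect sizes for candidate features.

    ``data`` holds relative abundances scaled to a per-sample total of 1e6
    (samples as rows).  For each enriched cohort a one-vs-rest
    ridge-regularized linear discriminant is fitted ``n_boot`` times on
    class-balanced subsamples; a feature's effect is the mean over rounds of
    half the sum of its raw between-class mean difference and its share of
    the class-mean difference along the discriminant axis.  Effects below 1
    are floored to a score of 0.
    """
    if not candidates:
        return {}
    labels = np.array([design.assignments[s] for s in data.index])
    for lab in pd.unique(labels):
        if (labels == lab).sum() < 3:
            raise ValueError(f"cohort {lab!r} has fewer than 3 samples")
    x_all = data[candidates].to_numpy(dtype=float)
    means = {
        lab: x_all[labels == lab].mean(axis=0) for lab in pd.unique(labels)
    }
    stacked = np.vstack([means[lab] for lab in pd.unique(labels)])
    enriched_idx = stacked.argmax(axis=0)
    cohort_of = {f: pd.unique(labels)[enriched_idx[i]] for i, f in enumerate(candidates)}

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    effects = np.zeros((n_boot, len(candidates)))
    contrast_of = np.array([list(pd.unique(labels)).index(cohort_of[f]) for f in candidates])
    for b in range(n_boot):
        idx = _bootstrap_indices(rng, labels, subsample_fraction)
        x = x_all[idx]
        y = labels[idx]
        for ci, lab in enumerate(pd.unique(labels)):
            mask = contrast_of == ci
            if not mask.any():
                continue
            pos = x[y == lab]
            neg = x[y != lab]
            m1 = pos.mean(axis=0)
            m0 = neg.mean(axis=0)
            centered = np.vstack([pos - m1, neg - m0])
            sw = centered.T @ centered
            tr = np.trace(sw)
            d = sw.shape[0]
            sw[np.diag_indices(d)] += RIDGE * (tr / d if tr > 0 else 1.0)
            w = np.linalg.solve(sw, m1 - m0)
            norm = np.linalg.norm(w)
            if norm > 0:
                w = w / norm
            raw = np.abs(m1 - m0)
            # feature f's share of the projected class-mean gap is its own
            # term in w . (m1 - m0); bounded by raw since |w_f| <= 1
            axis = np.abs(w * (m1 - m0))
            effects[b, mask] = 0.5 * (raw + axis)[mask]
    mean_effect = effects.mean(axis=0)
    scores = {}
    for i, f in enumerate(candidates):
        e = mean_effect[i]
        scores[f] = math.log10(e) if e >= 1.0 else 0.0
    return scores


def signature_features(
    table: FeatureTable,
    design: CohortDesign,
    alpha: float = 0.05,
    lda_cutoff: float = 3.0,
    rarefy_depth: int | None = None,
    seed: int = 0,
    n_boot: int = 30,
    strategy: str = "one_vs_rest",
) -> list[EffectSizeRecord]:
    """Full screening pipeline: rarefy, normalize, test, score, filter.

    Returns one record per feature that passes the Kruskal–Wallis stage,
    sorted by descending LDA score; ``passes`` marks features clearing both
    ``p < alpha`` and ``lda_score > lda_cutoff``.

    ``strategy="strict"`` additionally requires each candidate's enriched
    cohort to differ significantly (pairwise Kruskal–Wallis, ``p < alpha``)
    from every other cohort, not just from the pooled rest.  This suppresses
    compositional-shadow signals: when one cohort's true enrichment depresses
    every other feature's relative abundance, the shadow feature looks
    "enriched" in the untouched cohorts yet cannot separate them from each
    other.
    """
    if strategy not in ("one_vs_rest", "strict"):
        raise ValueError(f"unknown strategy {strategy!r}")
    work = table
    if rarefy_depth is not None:
        work = rarefy(work, rarefy_depth, seed=seed)
    rel = to_relative(work)
    # canonical sample order so the bootstrap stream is order-invariant
    scaled = (rel.data * MILLION).sort_index(axis=0)
    labels = np.array([design.assignments[s] for s in scaled.index])

    records: list[EffectSizeRecord] = []
    kw: dict[str, tuple[float, float]] = {}
    for f in scaled.columns:
        kw[f] = kruskal_wallis(scaled[f].to_numpy(), labels)
    candidates = [f for f in scaled.columns if kw[f][1] < alpha]
    cohort_means = scaled.groupby(labels).mean()
    if strategy == "strict" and len(cohort_means.index) > 2:
        kept = []
        for f in candidates:
            enriched = str(cohort_means[f].idxmax())
            vals = scaled[f].to_numpy()
            ok = True
            for other in cohort_means.index:
                if other == enriched:
                    continue
                mask = (labels == enriched) | (labels == other)
                _, p_pair = kruskal_wallis(vals[mask], labels[mask])
                if p_pair >= alpha:
                    ok = False
                    break
            if ok:
                kept.append(f)
        candidates = kept
    scores = lda_effect_size(scaled, design, candidates, n_boot=n_boot, seed=seed)
    for f in candidates:
        h, p = kw[f]
        enriched = str(cohort_means[f].idxmax())
        score = scores[f]
        records.append(
            EffectSizeRecord(
                feature_id=f,
                kw_statistic=h,
                p_value=p,
                enriched_cohort=enriched,
                lda_score=score,
                passes=(p < alpha and score > lda_cutoff),
            )
        )
    records.sort(key=lambda r: (-r.lda_score, r.feature_id))
    return records
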