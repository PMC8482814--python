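# Methods

This note documents the models and procedures implemented in `comecol`, the
defaults and why they were chosen, the synthetic generator's assumptions,
and the numerical decisions that were genuinely open.

## Feature tables and transforms

The pipeline's currency is a sample-by-feature matrix of non-negative
abundances. Counts are stored as floats because pathway tables produced by
community-wide functional projection are fractional. Taxonomic lineages are
plain semicolon-delimited rank lists; the `g__`/`s__` prefixed dialect is
accepted by stripping two-letter prefixes, and lineages are otherwise used
verbatim (no re-annotation of "Unclassified" placeholders).

Rarefaction draws each sample's reads without replacement to a common depth
(a multivariate hypergeometric draw per sample), the convention of the
QIIME-family tools; samples below depth are dropped with a warning by
default. The hypergeometric draw is unbiased, which the test suite checks
by Monte-Carlo against the input proportions. Rank collapsing sums member
features and conserves per-sample totals exactly; features lacking the
requested rank are pooled under `Unclassified_at_rank`.

Core microbiomes use a prevalence threshold, default 0.75. Both the
inclusive (≥) and strict (>) readings circulate in the literature; the flag
`inclusive` exposes both and defaults to inclusive. With the emulated
cohort sizes (27/21/27) the distinction cannot bite — no prevalence equals
exactly 0.75 — so the default is cosmetic but explicit. Core fractions
divide by cohort gamma richness (features observed anywhere in the
cohort).

## Beta-diversity partition

The pairwise and multi-site Sørensen/Simpson partitions follow the standard
additive framework: total dissimilarity = turnover (replacement) +
nestedness-resultant (ordered loss). The multi-site quantities are computed
from the matched-pairs sums `Σmin`, `Σmax` and the richness excess
`ΣS_i − S_T`; on two sites they reduce *exactly* to the pairwise formulas,
which the tests assert. Two independent checks guard the implementation: a
brute-force re-derivation from raw set operations, and the R implementation
`vegan::nestedbetasor`, both agreeing to 1e-12 on random instances.

Cohorts of unequal size are used as-is, with `n_sites` reported, because
multi-site dissimilarity generally grows with site number. An optional
resampling mode (draw `m` sites, repeat `R` times, report mean ± SD) is
available for explicit size equalization but is off by default.
Incidence is `count > 0` after any upstream rarefaction; no
minimum-abundance floor is applied.

## Null model and stochasticity ratio

The null model reassembles one cohort at a time on its regional pool (all
features with at least one count in the cohort), preserving:

1. each sample's total reads, exactly;
2. per-sample richness — either exactly (`fixed`) or in expectation
   proportional to observed richness (`proportional`, the default): the
   total occurrence count `ΣS_i` is re-allocated to samples multinomially
   with weights `S_i`, clipped to `[1, pool size]`;
3. feature identity drawn without replacement with probability
   proportional to regional occurrence frequency (`proportional`) or
   uniformly (`equiprobable`).

Weighted sampling without replacement uses the Gumbel-top-k construction
(perturb log-weights with Gumbel noise, keep the largest k), which is
distributionally identical to successive renormalizing draws but
vectorizes; the calibration tests compare it against an independent
sequential sampler and against exact enumeration on a 5-feature pool.
Every selected feature receives one read; the remainder is allocated
multinomially with weights equal to the regional mean relative abundances
renormalized over the selected features. The randomization micro-algorithm
is not uniquely determined by the verbal constraints it implements; this
variant is the package's documented choice.

Expected similarity `E_ij` is the mean Bray–Curtis similarity of the pair
over `n_randomizations` independent draws (default 1,000; reports based on
fewer than 100 warn). One circulating figure caption gives 999 instead of
1,000 randomizations; the package default is 1,000 with an override.

Selection strength is two-branched so that both homogenizing (`C > E`) and
diverging (`C < E`) selection register as determinism while `SS` stays in
[0, 1]; `C = E` gives `SS = 0`. Cohort summaries report mean and
*population* SD of `ST = 1 − SS` over pairs, in percent.

A subtlety worth knowing: a deterministic filter shared by **all** samples
of a cohort changes the cohort's pool but not the within-cohort
observed-vs-null contrast; what the statistic detects is heterogeneous
determinism *within* the analyzed metacommunity (e.g., sub-groups under
different filters pooled into one unit) or selection strong enough to make
samples more mutually similar than their occurrence frequencies imply. The
monotonicity experiments below use within-cohort analysis of filtered
cohorts, which decreases cleanly with filter strength; pooling disjointly
filtered sub-groups into one metacommunity also lowers the ratio relative
to neutral, but extreme filtering (w ≳ 4) can raise it again because the
null expectation itself collapses once the pooled occurrence structure
fragments.

## Signature screen

The screen is a deliberately simplified effect-size pipeline: rarefy →
relative abundance → scale to 10⁶ per sample → Kruskal–Wallis per feature
(α = 0.05, tie-corrected, chi-square approximation; all-identical values
degenerate to p = 1) → bootstrap LDA effect size for survivors → report
features with log₁₀ effect > 3. There is no subclass (Wilcoxon) stage
because the emulated design has none.

The LDA stage fits, per enriched cohort, a one-vs-rest linear discriminant
over all candidate features on 30 class-balanced subsamples (2/3 per
class). The within-class scatter is ridge-regularized by `1e-6 ×
trace/d × I` since candidate sets are routinely rank-deficient. A feature's
effect per round is `½(|Δm_f| + |w_f Δm_f|)`: half the raw between-class
mean difference plus half the feature's own term of the projected
class-mean gap `w·Δm`. Attributing the axis gap via the feature's own term
(rather than `|w_f| · |w·Δm|`) keeps each feature's effect bounded by its
raw difference; the alternative attribution hands near-constant rare
features (whose scatter is ridge-dominated and whose discriminant weight is
therefore large) the entire projected gap and produces spurious
signatures. Effects below 1 on the 10⁶ scale are floored to score 0.
Numeric parity with the published LEfSe tool is not claimed; calibration
and planted-recovery behavior are the contract.

For more than two cohorts the default contrast is one-vs-rest with the
enriched class = highest mean. The `strict` strategy additionally requires
the enriched cohort to differ (pairwise Kruskal–Wallis, p < α) from every
other cohort individually. This matters on compositional data: a strong
enrichment in one cohort depresses every other feature's relative abundance
there, so the most abundant features can appear "enriched" in the untouched
cohorts (a compositional shadow). Shadows cannot separate the two untouched
cohorts from each other, so the strict gate removes them; the planted-
recovery experiments use it, and with the default one-vs-rest strategy one
should expect occasional shadow signatures on strongly perturbed
compositions.

## Synthetic cohort generator

The generator emulates denoised, species-annotated count tables from a
three-cohort saliva study: cohorts of 27/21/27 samples, read depths
uniform in 40,000–60,000, a regional pool of 600 taxa with log-normal
relative abundances (μ = 0, σ = 2 on the log scale — a steep, realistic
rank–abundance curve), and a 600 × 300 taxa-to-pathway trait matrix.
All randomness flows through per-purpose seeded streams, so regenerating
with one seed is bit-identical and the filter strength `w` is the only
moving part in monotonicity experiments (the taxon-by-cohort effects
`e_tc` are drawn once per dataset seed).

* **neutral** assembly: each sample is one multinomial draw of its depth
  from the pool — pure stochastic assembly.
* **filtered** assembly: cohort weights `pool_t · exp(w · e_tc)`,
  renormalized. At `w = 0` this reproduces the neutral tables exactly.
* **turnover** structure: samples are assigned round-robin to 3 disjoint
  blocks of the pool, so replacement dominates within each cohort.
* **nestedness** structure: each sample draws from a random-size top slice
  of the abundance-ranked pool (slices shrink with cohort index), so poorer
  samples are approximate subsets of richer ones.
* **core targets** `(n_core, prevalence)`: designated taxa from the upper
  abundance half are forced to the target prevalence by moving a few reads
  from the sample's most abundant taxon, conserving depth.
* **planted signatures** `(cohort, n, fold)`: taxa with pool abundance in
  3.5×10⁻⁴–8×10⁻⁴ get their weight multiplied by `fold` in one cohort. The
  window is a design choice: abundant enough that an 8-fold enrichment
  clears the 10³ effect cutoff at realistic depths, small enough that the
  compositional closure shift on the rest of the community (≈ 2% here)
  stays well below the cutoff.

Trait matrices assign each pathway exactly `redundancy` carrier taxa by
slicing a cycled random permutation (so coverage is complete whenever
`n_pathways × redundancy ≥ n_pool`), with copy numbers uniform on {1, 2, 3}.
High redundancy (30) makes pathway incidence nearly saturated and pathway
profiles far more stable than taxon profiles — the qualitative
taxonomy-versus-function contrast the analysis is designed to expose.

What the generator does *not* emulate: biological overdispersion beyond
multinomial sampling (real microbiomes vary far more sample-to-sample),
phylogenetic structure, sequencing noise and chimeras, and compositional
correlations beyond closure. Passing tests therefore demonstrate that the
statistics behave correctly under their own assumptions — not that real
salivary data will show the same effect sizes. In particular the
Kruskal–Wallis null calibration and the shadow-free planted recovery depend
on the multinomial noise floor; overdispersed data would admit more
variance-driven signatures.

## Problem sizes in tests and the acceptance script

Experiments use the default study-scale conditions where cheap (neutral
stochasticity, structure modes, redundancy, planted signatures) and
scaled-down cohorts elsewhere as the package's own choice of experimental
economy: the filter-strength sweep runs 3 × 10 samples at depth
3,000–5,000 with 100 randomizations per run over 20 paired seeds; the
null-model calibration uses a 20 × 100 cohort with 1,000 draws; the
expected-similarity convergence check uses a 3-sample toy. Every such size
is stated at the point of use.

## Known limitations

* The stochasticity ratio inherits the null model's blind spot for
  cohort-uniform filters (see above); it quantifies departure from the
  cohort's own occurrence structure, not absolute determinism.
* The LDA effect size is a behavioral re-implementation, not a drop-in
  replacement for the published LEfSe numbers.
* Multi-site partitions are incidence-only; abundance-based partitioning
  (balanced variation vs abundance gradients) is out of scope.
* No multiple-testing correction is applied in the signature screen (raw
  α per feature, matching the emulated procedure); treat the output as a
  screen, not confirmatory inference.
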