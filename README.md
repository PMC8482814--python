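# comecol

Ecological analysis of microbiome cohorts: who is consistently there (the
core microbiome), how communities differ (beta-diversity partitioned into
turnover and nestedness), what assembles them (null-model stochasticity
ratios), which features mark each cohort (LDA effect-size screening), and
how taxonomy maps onto function (trait-matrix projection). A synthetic
cohort generator with controllable ecology makes every stage testable
end to end without any sequencing data.

The package operates on sample-by-feature count tables (denoised amplicon
features annotated to species, or inferred metabolic pathways) plus a
sample-to-cohort metadata table — the typical downstream artifacts of an
amplicon workflow. The motivating application is salivary microbiomes
across oral-health states (healthy, pre-cancer lesion, oral cancer), but
nothing in the code is specific to that system.

## The statistics at the core

**Beta-diversity partition.** Total Sørensen dissimilarity splits additively
into species *turnover* (Simpson-based replacement) and *nestedness*
(ordered loss, poorer sites as subsets of richer ones). Pairwise, with `a`
shared features and `b`, `c` unique ones:

```
β_sor = (b + c) / (2a + b + c)
β_sim = min(b, c) / (a + min(b, c))
β_nes = β_sor − β_sim
```

The multi-site forms summarize a whole cohort at once (not an average of
pairs): with `S_i` the richness of site *i*, `S_T` the pooled richness, and
`b_ij` the count of features in site *i* missing from *j*,

```
β_SIM = Σmin / [(ΣS_i − S_T) + Σmin]
β_SOR = (Σmin + Σmax) / [2(ΣS_i − S_T) + Σmin + Σmax]
β_NES = β_SOR − β_SIM
```

where `Σmin`/`Σmax` run over `min(b_ij, b_ji)` / `max(b_ij, b_ji)` for all
site pairs. The implementation is verified against a brute-force
set-operation oracle and against `vegan::nestedbetasor`.

**Stochasticity ratio.** For each pair of samples in a cohort, the observed
Bray–Curtis similarity `C` is compared with the mean similarity `E` of the
pair under a null model (default 1,000 randomizations) that reassembles the
cohort from its regional pool, preserving per-sample totals and drawing
richness and feature identity proportionally to observed richness and
occurrence frequency. The selection strength

```
SS = (C − E) / C          if C ≥ E
SS = (D − E_D) / D        if C < E,  D = 1 − C, E_D = 1 − E
```

lies in [0, 1]; the stochasticity ratio `ST = 1 − SS` estimates the
fraction of community structuring attributable to stochastic processes.

**Core microbiome.** Features with prevalence ≥ 75% (threshold and
strictness configurable) within a cohort, with the full Venn decomposition
across cohorts and core fractions relative to cohort gamma richness.

**Signature screen.** Rarefy → relative abundance × 10⁶ → per-feature
Kruskal–Wallis across cohorts (α = 0.05) → bootstrap ridge-LDA effect size
for the survivors; features with log₁₀ effect > 3 are reported as cohort
signatures. A strict all-against-all mode suppresses compositional-shadow
signals.

## Worked example

```python
from comecol import (SyntheticSpec, make_dataset, core_sets, cohort_partitions,
                     stochasticity_ratio, NullModelConfig, project_traits)

spec = SyntheticSpec(seed=1, abundance_lognormal=(0.0, 3.0),
                     depth_range=(8000, 12000))
table, design, traits = make_dataset(spec)

cores = core_sets(table, design, threshold=0.75)
parts = cohort_partitions(table, design)
st = stochasticity_ratio(table, design,
                         NullModelConfig(n_randomizations=200, seed=2))
```

prints (via the obvious formatting):

```
table: 75 samples x 532 taxa
normal: 173 core taxa (36.65% of cohort richness)
OVH: 176 core taxa (37.85% of cohort richness)
OSCC: 173 core taxa (36.34% of cohort richness)
shared by all cohorts: 160
normal: beta_SOR=0.752 turnover=0.727 nestedness=0.025
OVH: beta_SOR=0.708 turnover=0.686 nestedness=0.022
OSCC: beta_SOR=0.757 turnover=0.736 nestedness=0.021
pathway beta_SOR (normal): 0.575
normal: stochasticity 80.3 +/- 2.4%
OVH: stochasticity 80.0 +/- 2.7%
OSCC: stochasticity 79.7 +/- 2.7%
```

Reading it: the three neutral cohorts (27/21/27 samples drawn from one
regional pool) differ almost entirely by species *turnover* (0.69–0.74)
with negligible nestedness (≈ 0.02) — presence/absence of the rare tail
varies sample to sample while the core persists. Projecting counts through
the trait matrix lowers the multi-site dissimilarity (0.58 vs 0.75):
function is more conserved than taxonomy because multiple taxa carry each
pathway. The stochasticity ratio of ≈ 80% says the null model reproduces
most of the observed pairwise similarity, as expected for communities
assembled by multinomial draws from a shared pool.

## Command line

Every stage is also a subcommand of the `comecol` entry point:

```sh
comecol simulate --spec spec.json --out-prefix data/run
comecol core --table data/run_table.tsv --metadata data/run_metadata.tsv --out core.tsv
comecol beta-partition --table ... --metadata ... --out beta.tsv
comecol stochasticity --table ... --metadata ... --n-rand 1000 --seed 0 --out st.tsv
comecol signatures --table ... --metadata ... --rarefy-depth 43313 --out sig.tsv
comecol project --table ... --traits data/run_traits.tsv --out pathways.tsv
comecol all --spec spec.json --seed 7 --out-dir results/
```

`all` runs simulate → core → beta-partition → project → stochasticity →
signatures and writes a manifest (version, seed, config hash, per-stage
parameters) from which the run is reproducible.

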