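# Methods

## Dose–response model

Viability is modelled on the Test/Control × 100 (%) scale with the
four-parameter logistic

    TC(c) = bottom + (top − bottom) / (1 + (c / EC50)^hill)

fit by unweighted least squares in T/C% space. The assay design is
singlicate (one well per concentration), so there is no replicate
variance to weight by. Initialisation uses top = max(TC),
bottom = min(TC), hill = 1 and EC50 at the concentration nearest the
curve midpoint; the optimiser is bounded (bottom ≥ 0, top ≤ 200,
hill ∈ [0.1, 10], EC50 ≤ 10 × the highest tested concentration) so
pathological data cannot push parameters into meaningless regions.
Series with no response spread are returned as converged flat fits
(hill pinned at 1) rather than errors; optimiser failure returns the
initial parameters flagged non-converged.

Two IC50 notions are kept apart deliberately:

* **Rel IC50** — the fitted curve's midpoint, i.e. the EC50 parameter.
  The alternative convention (concentration at 50% of *top*) exists;
  the midpoint was chosen and is recorded here as a package convention.
* **Abs IC50** — the concentration where the fitted curve crosses
  TC = 50, from the closed-form inversion
  `EC50·((top−50)/(50−bottom))^(1/hill)`. When the curve is already
  below 50% at the lowest tested dose, or never reaches 50% within the
  range, the corresponding grid boundary is substituted and the record
  flagged `at_lowest`/`at_highest`. Censored values then enter every
  downstream statistic at their clamped value — the same convention the
  source profiles use — rather than being dropped.

Response classes split at 1 and 10 µM (highly sensitive / intermediate
/ resistant, with ≥ on the resistant side). The sensitive/resistant
dichotomy used by the screens cuts at the panel's 30th Abs-IC50
percentile, computed with linear interpolation between order statistics
(numpy's default); a value exactly at the cutoff is resistant,
consistent with the ≥10 µM class convention.

## Statistical kernels

Standard tests are delegated to scipy/statsmodels behind a thin result
type whose `method` tag records the exact variant run:

* Wilcoxon rank-sum: exact enumeration when both groups have ≤ 8
  observations and no ties; otherwise the normal approximation with tie
  and continuity corrections. Fully tied inputs return p = 1.
* Fisher exact (two-sided, sum of tables no more likely than observed);
  a zero margin returns p = 1 by convention.
* Spearman with average ranks and the two-sided t-approximation.
* Ordinary two-sample t: Welch (unequal variances are the norm across
  tumour types).
* Proportion homogeneity: chi-square with k − 1 df, no continuity
  correction (the k = 2 case equals the squared two-proportion z).
* BH step-up adjustment, capped at 1. Note BH is *not* idempotent:
  re-adjusting adjusted values inflates them again; the guaranteed
  properties are adjusted ≥ raw and preservation of the raw ordering.
* Hypergeometric upper-tail over-representation for gene sets.

The **moderated t** is implemented in-package (no installed Python
library provides it). Per feature the pooled two-group residual
variance s²_g (d_g = n − 2 df) is shrunk toward a prior s₀² with d₀
prior df, both estimated by method of moments on log s²_g using
digamma/trigamma identities, with the trigamma inverse solved by Newton
iteration; the moderated statistic is
t_g = (mean₁ − mean₀) / (s̃_g √(1/n₀ + 1/n₁)) with
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), referred to a t-distribution on
d₀ + d_g df (capped at the total residual df; normal when d₀ is
infinite, in which case the prior is the arithmetic mean variance).
The test suite verifies agreement with R limma's `lmFit`/`eBayes` to
~1e-8 on both estimated hyperparameters and per-feature statistics.
The d₀ = 0 limit is the *pooled-variance* ordinary t, not the Welch t —
the two coincide in statistic (not df) for balanced groups.

## Association screens

Genomic arm: a (gene, line) is "altered" iff mutated, amplified
(PICNIC copy number ≥ 8) or homozygously deleted (= 0); genes altered
in fewer than two lines are untestable and skipped. Altered vs
unaltered Abs IC50 is compared by Wilcoxon with BH across genes, the
direction taken from the median difference.

Expression arm: probes whose values are below 5 (log2) in every sample
are removed first; each surviving feature is tested three ways (Welch t
between dichotomy groups, moderated t on the same split, Spearman vs
Abs IC50), BH-adjusted within each test, and called significant only on
the triple intersection at adjusted p < 0.05 — a deliberately
conservative rule. The log2 fold difference (sensitive-group mean minus
resistant-group mean, so positive = sensitivity-associated) is computed
on the same dichotomy the moderated test uses. Probe-level hits
collapse to one probe per gene by the supplied annotation quality score
(ties to the lexicographically smallest probe id; fall-back to mean
expression order if scores are absent — the original probe scoring
needs sequence-level annotations that are out of scope). The fold
filter is strict (|fd| > 0.5). The enrichment universe is the set of
genes that survived the probe floor and probe selection, i.e. the genes
actually tested.

Cell-line clustering uses 1 − Pearson correlation between expression
profiles with Ward linkage, cut at k clusters; correlation distance
compares profile *shapes*, so clusters reflect co-expression patterns
rather than absolute level. Per-cluster response rates are compared
with the proportion test. These parameter choices (distance, linkage)
follow common expression-heatmap practice; the upstream procedure named
only a library routine.

## Predictive score and decisional tree

Score = unweighted arithmetic mean of the 11 p53-pathway genes' log2
expression, computed on gene-level values after probe selection
(portable across probe layouts). Class boundaries are strict: high iff
score > 7.5, so exactly 7.5 is low. The 7.5 cutoff is bound to the
gcrma-style log2 scale and is meaningless on other normalisations —
the configuration documents it as scale-bound. The decisional tree
predicts sensitive iff wild-type *TP53* AND high score; its hard
guarantee — no mutant line is ever predicted sensitive, for any input —
is asserted in code and property-tested. Performance metrics take
*sensitive* as the positive class (sensitivity = tp/(tp+fn),
PPV = tp/(tp+fp), etc.); the orientation is a documented package
convention. External validation applies the frozen cutoff and tree to
a held-out cohort after removing any lines used in derivation, and
dichotomizes the external IC50s at the external cohort's *own* 30th
percentile, not the derivation cohort's.

## Synthetic panel generator

The generator emulates the statistical structure of a large MDM2-
inhibitor screen so the pipeline is testable end to end without data
downloads. A single latent binary *pathway activity* per line drives
both drug response and the expression signature — this single-driver
design is what yields the negative score–IC50 correlation with a
controllable effect size.

Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_cl | 237 | panel size |
| frac_tp53_mut | 0.69 | *TP53*-mutant fraction |
| wt/mut median IC50 | 1.4 / 15.1 µM | activity-group medians (µM) |
| ic50_log_sd | 0.07 | within-group sd, log10 µM |
| frac_wt_resistant | 21/74 | wild-type lines with low activity |
| frac_mut_sensitive | 14/163 | mutant lines with high activity |
| n_background_genes | 2000 | signal-free expression genes |
| signature_effect_log2 | 1.0 | signature shift, log2 units |
| noise_sd_expression | 0.5 | per-gene, per-line log2 noise |
| tc_noise_sd | 3.0 | T/C% noise on generated curves |
| grid | 0.001–30 µM | ten half-log concentrations |

TP53 status is Bernoulli; activity is high for wild-type lines minus
the wild-type-resistant fraction and for the mutant-sensitive fraction;
log10 IC50 is normal around the activity-group median and truncated to
the grid with censoring. The medians are attached to *activity* groups
(high → 1.4 µM, low → 15.1 µM): since each TP53 group is dominated by
one activity state, the TP53-group medians land on the same values
while the discordant subgroups remain on the wrong side — the only
assignment that reproduces the group medians, the discordance
fractions, and the mutant-resistance rate simultaneously.
`ic50_log_sd = 0.07` is a calibration, not a measured value: it is the
spread at which ~91% of mutant lines land at ≥ 10 µM and the panel's
30th percentile falls near 10.7 µM. The 11 signature genes sit at
7.5 − effect/2 plus effect × activity, so high-activity lines average
above the 7.5 cutoff and low-activity lines below it; background genes
draw line-independent baselines (N(7, 2) clipped to [2, 14], letting
the probe floor do real work). Each gene expands to 1–3 probes; the
best-quality probe carries the faithful gene value and extra probes
random offsets, so probe selection is consequential but lossless.
Background mutation genes (default 300) and copy-number events are
independent of response, giving the genomic screen a null background
with *TP53* as the only planted hit. Tumour-type labels come from a
fixed composition table and are cosmetic. All sub-streams derive from
one seed; same seed, same panel.

What the generator does **not** emulate: probe chemistry and
cross-hybridisation, copy-number segmentation structure, batch effects,
tumour-type-specific expression programmes, and any coupling between
lineage and drug response. Passing tests therefore demonstrate that the
pipeline recovers the *intended statistical structure*, not that it
would behave identically on real microarray/WES panels.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default panel (237 lines,
2000 background + 11 signature genes, ~4000 probes, 301 mutation
genes); a complete acceptance run takes a few seconds on one core, and
the multi-seed recovery test runs the whole screen over 20 seeds.
Underflowing p-values are clamped to the smallest positive float.
Curve fits that fail to converge are flagged rather than raised; flat
curves short-circuit the optimiser. Ties in probe selection, ranks and
sorting all have deterministic documented tie-breaks, so every output
table is reproducible byte for byte.

## Known limitations

* The decisional tree's panel-wide sensitivity has a structural ceiling
  under the default conditions: mutant-but-sensitive lines (14/163 by
  default) can never be predicted sensitive (the tree's hard
  guarantee), so with ~71 observed-sensitive lines the tree tops out
  near 0.75 sensitivity overall even with noiseless expression. Within
  the wild-type subset its sensitivity is ≈ 1. Both numbers are
  reported by the acceptance script.
* The 7.5 score cutoff does not transfer across normalisation schemes.
* COMPARE p-values are reported raw and BH-adjusted; with few reference
  drugs the adjustment is conservative.
* Censored IC50s at the grid boundary bias rank correlations toward
  zero when censoring is heavy; no correction is applied, matching the
  profile convention.
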