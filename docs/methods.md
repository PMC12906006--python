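# Methods

## Statistical model

### Differentially proportioned (DP) cell types

Input is a samples × cell-types matrix of fractions with a two-level
condition label per sample. Per cell type, the pipeline is:

1. **Compartment merging** (optional): tumor and other epithelial labels
   are summed into one epithelial compartment before testing, because
   tumor/epithelial assignment is inconsistent across references while
   their sum is stable. No other types are merged.
2. **Low-proportion filtering**: samples with proportion `< 0.001`
   (strict) for this cell type are excluded from this cell type's test
   only. Near-zero estimates are usually estimation failures, not
   biology, and would otherwise manufacture significance. If more than
   half (strict `>`) of either condition's samples are excluded, the
   cell type is removed from identification entirely.
3. **Two-sided Wilcoxon rank-sum test** on the retained samples. The
   p-value is exact (full enumeration) when both groups have ≤ 25
   samples and the pooled values are tie-free, otherwise the normal
   approximation with continuity correction. The switch is fixed so
   printed p-values reproduce across platforms.
4. **Benjamini–Hochberg FDR** over the cell types that produced a
   p-value in this cohort (removed/untested types contribute nothing —
   a cohort is not penalized for unestimable types). Default thresholds:
   0.1 for scRNA-derived matrices (small n per condition), 0.05 for
   deconvolution estimates. FDR is the conventional choice where the
   correction procedure is otherwise unspecified.
5. **Direction** = sign(median₁ − median₂) on retained samples. An
   exact tie gives direction 0 and the type cannot be called DP: a DP
   call without a direction cannot participate in trend matching.

A cell type with fewer than two retained samples in either condition is
reported untested, not an error. An optional sensitivity mode drops cell
types whose median abundance is below 1% in either condition of the
ground-truth matrix before testing (rare types are where deconvolution
methods disagree most).

### Prognosis-related (PR) cell types

One Cox proportional-hazards model per cell type, `hazard ∼ proportion
(+ clinical covariates)`, rather than a joint model over all cell types:
proportions are compositional, so a joint model is singular, and
per-type hazard ratios are the quantity displayed and compared. The
proportion covariate is standardized (zero mean, unit variance) by
default — raw fractions give unit-dependent hazard ratios; sign and
p-value are unaffected (configurable off). Ties use Efron's method
(lifelines default). The same low-proportion filtering applies, with the
whole survival cohort as a single group. A cell type is testable only
when ≥ 15 death events remain among retained samples (`event_floor`,
configurable); below that, Cox estimates are unstable and the result is
recorded as missing with a reason. Wald p-values are BH-adjusted over
testable types; the PR set holds (cell type, sign β) pairs with
q < 0.05 (0.10/0.15 as sensitivity settings).

### Scoring

Direction agreement is required for every notion of validated /
recovered / shared: a significance match with opposite direction is a
false agreement. A flag disables this for ablation.

* **Scenario 1** (method vs scRNA reference): recall = fraction of
  scRNA-DP types called DP by the method with matching direction (both
  modes); conservative precision = fraction of method calls that are
  scRNA-significant with matching direction; permissive precision also
  accepts calls whose scRNA direction matches without significance;
  F1 = 2PR/(P+R), zero when P + R = 0. Recall is undefined (flagged)
  when the scRNA reference has no DP types.
* **Scenario 2** (cohort A vs cohort B): union = types significant in at
  least one cohort (identical in both modes); conservative shared =
  significant in both with one direction; permissive shared additionally
  accepts significance in exactly one cohort with a matching tested
  trend in the other. Types untested in the other cohort can enter the
  union but never the shared set. Jaccard = |shared|/|union|. The F1
  against scRNA uses trend-consistency precision in *both* modes (only
  the shared set changes between modes) and direction-matched
  scRNA-significant recall.
* **Scenario 3**: the same shared/union logic on PR tables with sign(β)
  as direction, pooled across entities (Σ|shared| / Σ|union|). Single
  entities yield one-or-two-element PR sets whose Jaccard is 0-or-1
  noise; pooling is what makes the estimate stable.
* **Rank aggregation**: rank 1 = best per metric, mean of tied ranks,
  undefined scores rank last (abstention must not win), averaged across
  metrics.
* Auxiliary metrics: log2 fold change of condition medians with a
  configurable pseudocount (default 1e-4), median absolute error of
  paired log2FCs, and Pearson correlations computed across cell types
  within a sample or across samples for one cell type.

Displayed scores are rounded half-up to two decimals; JSON output keeps
full precision.

### Pan-cancer consistency

The entity × subtype matrix stores −ln(HR) = −β per testable fit
(positive = favorable). Per subtype with ≥ 5 non-missing entities
(configurable), a Wilcoxon signed-rank test against zero is run
one-sided with the alternative chosen from the sign of the observed
median. That side selection is post hoc; the output flags it and a
two-sided option exists. BH-FDR across subtypes. The ±1 clipping of
heatmap values is applied only at rendering, never in the stored matrix.
Additive indicators (sum of named subtype proportions) are evaluated by
Cox regression on the continuous standardized score — the headline
p-value — with a median-split (ties to the low group) emitted for
Kaplan–Meier display.

## Synthetic study conditions

The generator reproduces the structure the benchmark assumes, not any
particular dataset:

* **Compositions**: Dirichlet draws over 15 cell types with
  concentrations 8.0 … 0.4 (mean fractions ~20% down to ~1%, total
  concentration 40 ⇒ realistic between-sample spread). Condition 2
  multiplies two planted types' concentrations: ×3 on a 5%-type (up)
  and ÷3 on a 15%-type (down). The pair is balanced (+4.0 / −4.0) so
  the concentration total is unchanged and **non-planted types have
  identical marginals in both conditions** — without this, Dirichlet
  normalization leaks the planted shift into every other type and no
  exact null exists.
* **Batch effects**: per-cohort log-normal jitter (σ = 0.1) on the
  concentrations, shared by both conditions within a cohort, so paired
  cohorts shift in the same directions by construction while differing
  in level.
* **Method error**: Gaussian noise and per-type bias on the logit scale
  (keeps estimates in (0,1) without truncation artifacts), then
  per-type zero-inflation (the observed failure class where a method
  reports zeros for a cell type in most samples), then row
  renormalization. Presets: `accurate` (σ=0.15), `noisy` (σ=0.8), and
  `zero_inflating` (σ=0.4 plus 80% zero-inflation on one planted DP
  type and one rare type).
* **scRNA annotations**: 12 samples per condition × 1000 cells sampled
  multinomially from per-sample Dirichlet compositions; tallying
  recovers the truth up to multinomial error.
* **Survival**: exponential event times with hazard
  h₀·exp(Σ βₜ·z(proportionₜ)), h₀ = 0.1, one planted type with β = 1.2
  per SD; uniform censoring with the window tuned by bisection to a
  target event count (default 65–75% events ≈ 30% censoring).
* Default cohort size: 50 samples per condition per cohort — large
  enough for stable ranks, small enough that the full benchmark runs in
  seconds.

Every generator is a pure function of (parameters, seed); identical
seeds give byte-identical tables.

**What passing on synthetic data does and does not show.** The generator
emulates compositional shifts, batch jitter, estimation noise and
zero-inflation; it does not emulate reference mismatch between scRNA
atlas and bulk cohort, platform effects (microarray vs RNA-seq),
label-harmonization errors, non-proportional hazards, or informative
censoring. Calibration and recovery results transfer to real cohorts
only to the extent those ingredients behave.

## Numerical choices and degenerate inputs

* Deconvolution rows must sum to 1 within 1e-3 (renormalized with a
  warning) — larger drift is an error unless renormalization is forced.
* Exact/asymptotic rank-sum switch at group size 25 and tie-free data.
* Empty retained sets, all-zero event columns, constant proportion
  columns and non-converged Cox fits all yield `tested = false` records
  with reasons, never exceptions mid-pipeline.
* Jaccard with an empty union, recall with an empty reference and
  precision with an empty shared set are reported as undefined
  (`None`/flag), except that an empty shared set with a non-empty
  reference reports F1 = 0 (the method found nothing reproducible).
* Cell-type matching is exact string match after whitespace trimming; a
  JSON alias map harmonizes labels across cohorts, summing aliases that
  collapse onto one name.
* Noise-grid experiments count a method's undefined score as 0 before
  averaging over seeds (no calls ⇒ no evidence of reproducibility).
* Fractions derived from annotation counts sum to 1 at double
  precision (≤ 1 ulp from exactness for realistic cell counts).

## Problem sizes used in the shipped experiments

Calibration suites use 200 exchangeable-null cohorts at n = 30 per
condition for DP false-call rates, and 100 cohorts at n = 400 (recovery)
/ n = 200 (null) with 11 cell types for the Cox analyses; the noise grid
sweeps 3 corruption scales × 3 seeds at n = 50 per condition. These sizes
give Monte-Carlo standard errors of 1–3 percentage points on the rates
they estimate.

## Known limitations

* Two-condition contrasts only; no covariate-adjusted differential
  abundance, no compositional transforms (CLR), no >2-group designs.
* Cox models are unpenalized, time-fixed, single-event; no competing
  risks and no proportional-hazards diagnostics beyond convergence.
* The one-sided consistency test's post-hoc side selection roughly
  doubles its nominal level under the null; use the two-sided option
  when that matters.
* Per-cohort clinical covariate sets must be configured by the user;
  none are assumed.
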