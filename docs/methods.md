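# Methods

`lfqstats` detects differentially abundant proteins in label-free,
chromatography-quantified bottom-up proteomics experiments.  This note
documents the statistical model behind each stage, the defaults and why
they were chosen, and the limits of what the test suite demonstrates.

## Data model

The unit of quantification is a spectral *feature* — a peptide ion (DDA),
peptide transition (SRM) or peptide/fragment ion (DIA) — belonging to
exactly one protein.  A *run* is one LC-MS acquisition of one sample.  The
canonical table holds one row per feature per run with the raw (linear)
intensity; the literal `NA` marks a missing measurement and is always
distinct from an intensity of zero.  Data layouts of this kind are
split-plot designs: biological subjects within conditions form the whole
plot, features within runs the subplot.

## Converters and cleaning

Spectral processing tools disagree on how missing measurements are
reported (some write `NA` and no zeros, others zeros and no `NA`) and on
which quality columns accompany the intensities.  A *dialect* captures
this declaratively: the set of raw values meaning "missing", whether a
zero is a missing marker, whether a missing value is abundance-related
(censored) or missing at random, and row filters (q-value cutoffs,
contaminant flags).  New tools are supported by a small YAML config rather
than code.

Cleaning runs in a fixed order: shared-peptide removal (a peptide mapped
to more than one protein is dropped entirely), sparse-feature removal
(default: a feature must be observed in at least 2 runs), optional removal
of single-feature proteins (off by default), duplicate aggregation
(default `max`, conservative against double-counting re-quantified peaks),
fraction handling, and balanced-design expansion so every feature has a
row for every run, missing or not.  For fractionated experiments each
feature is kept in the single fraction with the highest mean observed
intensity (ties go to the lexicographically first fraction) — selection
rather than aggregation, because it is deterministic and keeps feature
profiles comparable across runs; runs are then relabelled to one logical
run per (condition, biological replicate, technical replicate).  The
pipeline is idempotent and logs row counts per stage.

## Transformation and normalization

Intensities are log2-transformed (log10 available).  Normalization is a
per-run location shift computed from observed values only, applied before
any imputation.  The default equalizes per-run medians against the median
of per-run medians — that target, unlike a pooled median, is invariant to
unequal run sizes.  Alternatives: quantile normalization (maps each run's
observed quantiles to the mean quantile function; the one method that is
not a pure location shift), normalization to spiked global standards, or
none.  Median normalization presumes that most proteins do not change;
simulations in which half or more of the proteins shift in one direction
violate that premise, so the calibration studies below switch
normalization off where every protein carries a fold change.

## Censoring threshold

Low-abundance analytes fall below the limit of quantification, so their
missingness is informative.  The threshold for high-confidence log2
intensities is the estimated 0.1th percentile of the linear regime:
assuming the linear-regime distribution is symmetric, the upper spread
learns the lower one,

    threshold = q25 − (q99.9 − q75),

with percentiles (type 7, linear interpolation between order statistics)
pooled over all observed log2 intensities exceeding 0, one threshold per
experiment.  Every cell then gets exactly one status: missing cells are
*censored*, except under the Skyline dialect (its `NA` marks truncated or
overlapped peaks, missing at random) and for reference/heavy-label
features (standards are not expected to be low abundant); observed values
below the threshold are re-marked censored but keep their magnitude.  The
whole step can be switched off, in which case all missing cells are
treated as missing at random.

## Censored-value imputation

Per protein, log2 intensities follow an additive accelerated failure time
model `y = mu + Run_k + Feature_l + eps`, `eps ~ N(0, sigma^2)`, fitted by
maximizing the joint likelihood in which observed cells contribute the
Normal density and censored cells the Normal CDF at their censoring bound.
The bound is feature-specific: the smallest observed log2 intensity of the
feature, or a known limit of quantification supplied through the optional
`CensorBound` column.  Optimization is quasi-Newton (L-BFGS-B) with
analytic gradients, sum-to-zero effect coding, and the error scale floored
at 1e-6 to avoid degenerate likelihood spikes.

The reported scale is degrees-of-freedom corrected:
`sigma = sigma_ML * sqrt(n_eff / (n_eff − p))`, where `p` counts location
parameters and `n_eff` is half the observed information for `log sigma` at
the optimum.  For fully observed data `n_eff = n` and the estimate equals
the least-squares residual SD; censored cells carry less information and
contribute less than one unit each.  Without this correction the ML scale
is biased low by `p/n`, exactly as an uncorrected variance estimate.

A censored cell is replaced by the fitted linear predictor, capped by
default at its censoring bound (a censored value is known to lie below
it); the conditional-mean alternative is not used because the cap already
enforces the constraint and keeps the imputed value interpretable.  A cell
is imputable only when its feature is observed in another run *and* its
run has an observed value from another feature — in particular a protein
entirely missing in a run, or a single-feature protein's missing run, is
never imputed there.  Observed and missing-at-random cells are never
altered.  Imputation leans on features of a protein having parallel
profiles across runs; when missingness is actually unrelated to abundance
the imputation is biased and should be disabled.  The plug-in
feature-minimum bound sits slightly above the true limit of
quantification, which leaves a small upward bias in heavily censored
features; supplying a known limit through `CensorBound` removes it.

## Run-level summarization

All features of a protein in a run are summarized to one log2 abundance by
Tukey median polish on the feature-by-run matrix: medians are swept out of
rows (features) first, then columns (runs) — results can differ slightly
by sweep order for non-convergent patterns, so the order is fixed —
with the medians of the accumulated effects folded into the overall term,
until the largest effect change falls below 1e-8 or 100 sweeps.  Medians
over an even count are the midpoint of the two central order statistics;
missing cells are simply skipped (censored cells were handled upstream).
The run summary is `overall + run_effect`; a run with no usable cell gets
no summary.  The median is what buys robustness: corrupting one cell of a
3x3-or-larger matrix moves each run summary by a bounded amount, whereas
a mean-based summary has unbounded leverage.  A plain-mean summarizer
exists only for the robustness comparisons in the tests.

## Whole-plot model and inference

Fitting one rich mixed model at the feature level is fragile: with many
variance components REML estimates degenerate when components sit near
zero, corrupting the degrees of freedom.  The two-step procedure instead
models the run summaries, whose structure is simpler.  The design is
inferred from the annotation alone — no user formulas:

* **Group comparison, no technical replicates** (each condition its own
  subjects, one run per subject): fixed-effects model
  `z = mu + Condition + error` by least squares; condition means equal
  sample means, and the residual degrees of freedom are exact — `I(J−1)`
  in a balanced design with `I` conditions and `J` replicates.
* **Technical replicates, paired or time-course designs** (a biological
  replicate appearing under more than one condition marks the design as
  paired/time-course): a random intercept per subject — per
  (condition, subject) when subjects are nested, per subject when crossed
  — estimated by REML (profiled over the variance ratio on a log grid
  plus bounded refinement, with the zero boundary always evaluated
  explicitly), and Satterthwaite degrees of freedom per contrast from the
  REML expected information of the two variance components.  In a
  balanced paired two-condition design this reproduces the classical
  paired t-test (df = J−1) exactly.  A variance ratio on the zero
  boundary sets the `singular` flag and falls back to the fixed-effects
  fit with its exact residual degrees of freedom.

Comparisons are linear combinations `L = sum_i c_i mu_i` of condition
expected values, supplied as a contrast matrix (rows = named comparisons,
columns = conditions); `t = L_hat / SE(L_hat)` is referred to a Student
distribution with the model's degrees of freedom.  Benjamini–Hochberg
adjustment is applied within each comparison across proteins, excluding
proteins whose fit produced an issue (missing condition, everything
missing, non-convergence) from the family size.  No empirical-Bayes
variance moderation is applied — each protein is analyzed on its own.

## Synthetic experiments

The generator mirrors the additive structure the models assume: log2
intensity = protein base + condition effect + subject effect + run effect
+ feature effect + Normal noise, exponentiated to the raw scale.  Defaults
emulate a small spike-in benchmark: base 20 ± 2 (log2) across proteins,
feature effects SD 1 (ionization efficiencies span orders of magnitude),
run effects SD 0.2 (pre-normalization drift), residual SD 0.2, three
subjects per condition.  Missingness has two mechanisms with truth labels
kept per cell: censoring removes cells whose true log2 value falls below
a cutoff; missing-at-random drops surviving cells independently at a
fixed rate.  Everything is deterministic given the seed, and
tool-flavored variants (zeros vs `NA`) exercise the converter dialects.

What the generator does *not* emulate: correlated feature noise,
intensity-dependent variance, interference/mis-identification, retention
time drift, or real peptide sampling.  Passing tests therefore show the
statistical machinery is correct under its own assumptions, not that
those assumptions hold in any particular real data set.

## Calibration studies (run by the test suite and acceptance script)

Problem sizes were chosen as the smallest at which the binomial tolerances
are meaningful: 1000 null proteins (group comparison, J=3, three features)
for type I error; a 500-protein 50/50 null/changed mixture (log2FC = 1,
residual SD 0.2) for empirical FDR and sensitivity under BH at 5%; 500
changed proteins for fold-change bias; 200 replicates of an 8-run,
5-feature protein with ~20% censoring at a known limit of quantification
for AFT parameter recovery.  The mixture and recovery studies disable
median normalization and run-effect noise because every simulated protein
carries the same directional change — the scenario median normalization
is designed to reject.

## Known limitations

* Label-based reference normalization (heavy/light ratios for SRM) is not
  implemented.
* Imputation is single imputation; its uncertainty is not propagated into
  downstream standard errors.
* The censoring threshold is global per experiment, not per run or per
  protein.
* Unbalanced designs with whole missing runs rely on the Satterthwaite
  approximation; no Kenward–Roger correction is provided.
* Protein inference/grouping is out of scope; the input must already map
  features to proteins.
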