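# Methods

## Scope and data model

`mrscreen` operates entirely on GWAS *summary statistics*: one record per
variant with identifier, chromosome, position, effect/other allele, effect
allele frequency, marginal effect, standard error, p-value and sample size
(tab-delimited, columns `SNP CHR POS EA OA EAF BETA SE P N`). An LD
reference panel (haplotype matrix plus variant map) is used only for
clumping. No individual-level data is touched anywhere; every resampling
procedure is therefore parametric at the summary level.

## Synthetic-data generator

The generator emulates the data regime of an immune-trait → bone-mineral-
density screen: a small exposure GWAS (default n = 3,757) against much
larger outcome GWAS (default n = 66,628; the BMD outcomes emulated range
from ~8,000 to ~66,000). Its purpose is ground truth: every dataset carries
the planted per-variant effects so recovery can be measured exactly.

For variant *j* with effect-allele frequency fⱼ ~ U(maf_range):

* true exposure effect γⱼ ~ N(0, gamma_sd²);
* true outcome effect Γⱼ = β·γⱼ + sign(γⱼ)·αⱼ, where αⱼ = 0 for valid
  instruments and αⱼ ~ N(pleio_mean + κ·|γⱼ|, pleio_sd²) for the invalid
  fraction;
* observed effects add noise with the analytic SE of a standardized-trait
  regression, SE = 1/√(2·n·fⱼ(1−fⱼ)), and two-sided normal p-values.

**Orientation of pleiotropy.** Allele labels are arbitrary, so a "mean
pleiotropic effect" is only well defined relative to a fixed orientation; we
plant α on the exposure-increasing allele, the frame in which MR-Egger
regresses after orienting exposure effects positive. κ = 0 satisfies InSIDE
(pleiotropy independent of instrument strength); κ ≠ 0 correlates the two
and is the documented failure mode of MR-Egger. `truth.alpha` stores the
exposure-increasing-orientation magnitudes.

**Default gamma_sd = 0.15** puts per-instrument variance explained in the
fraction-of-a-percent range typical of flow-cytometry trait instruments
(median PVE well below 1%), while keeping instruments selectable at
p < 1e-5 from a 3,757-sample GWAS.

**LD panel.** Haplotypes are generated per block as a binary
copy-with-probability-ρ Markov chain with a common block-level allele
frequency, so the allele correlation at lag k is exactly ρᵏ and blocks are
independent. A latent-Gaussian threshold construction was rejected because
thresholding attenuates the binary correlation below ρ, breaking the
designed relationship between the `rho` parameter and sample r². ρ must be
in [0, 1): the copy chain cannot represent negative allele correlation,
which has no role in clumping tests. Positions are spaced `pos_step` bp
apart (default 100 kb) on one chromosome, matching the id/position scheme of
the summary-statistics generator so panels and tables align.

**Mediation scenarios** add a mediator with its own instruments δₖ
(disjoint variants): mediator effects are a·γⱼ at exposure SNPs and δₖ at
its own; outcome effects are c·γⱼ + b·(mediator effect), so the planted
total effect is c + a·b and the proportion mediated a·b/(c + a·b).

What the generator does *not* emulate: realistic human LD maps, covariate
adjustment, imputation error, sample overlap between exposure and outcome
GWAS, or LD between the variants carrying the marginal effects (effects are
drawn independently at the summary level; the panel exists for clumping
behavior only). Passing tests therefore demonstrate the correctness of the
estimators and the pipeline mechanics, not robustness to those real-data
complications.

## Instrument selection

* **Significance**: strict `P < p_threshold` (default 1e-5 for exposures;
  5e-8 for outcome-side instruments in reverse MR).
* **Clumping**: greedy, p-value-ranked — repeatedly take the smallest-p
  remaining variant as index and drop same-chromosome variants within the
  window (default 500 kb) whose sample r² with it exceeds the threshold
  (default 0.1 forward, 0.01 reverse). Ties on p break by position then id,
  making the output invariant to input row order. A variant absent from the
  panel is an error naming the variant.
* **Harmonization**: outcome records are matched to exposure alleles
  directly, swapped (sign and frequency flipped), or on the complementary
  strand. Palindromic variants (A/T, C/G) are aligned by allele frequency —
  kept as-is when exposure and outcome frequencies sit on the same side of
  0.5, sign-flipped when on opposite sides — and dropped whenever either
  frequency falls in the ambiguity band [0.42, 0.58]. Incompatible allele
  pairs and variants missing from the outcome are dropped and logged, never
  fatal.
* **Strength**: per-variant PVE uses the standard summary-statistic
  approximation PVEⱼ = 2f(1−f)β² / (2f(1−f)β² + 2f(1−f)·se²·n) and
  Fⱼ = (n−2)·PVEⱼ/(1−PVEⱼ); variants with Fⱼ < 10 are removed (strictly
  below: F = 10 is retained). The set-level F is ((n−k−1)/k)·R²/(1−R²) with
  R² the summed PVE over the k retained instruments; n ≤ k+1 is an error.

## Estimators

All ratio-based methods use first-order delta-method weights
(se(r̂ⱼ) = σ_Yj/|γ̂ⱼ|, exposure-side noise ignored), so fixed-effect IVW is
identical to weighted least squares of outcome on exposure effects through
the origin with weights 1/σ_Yj². A second-order Wald-ratio SE is available
behind a flag. Consequences of the first-order choice (the NOME
approximation): with very strong causal effects and a small exposure GWAS,
exposure-side noise dominates the ratio variance and fixed-effect intervals
undercover; the random-effect over-dispersion absorbs most but not all of
it. Calibration and recovery experiments therefore use a precise-exposure
regime (exposure GWAS n ≈ 1e5) where the approximation holds; under the
null the IVW z-statistic is exact regardless, so type-I-error experiments
use the small default exposure GWAS.

* **IVW**: fixed, random (SE × max(1, √(Q/(J−1))) — multiplicative
  over-dispersion floored at 1), or auto (random iff Q's p < 0.05). One
  instrument degrades to the Wald ratio.
* **Weighted median**: order ratios, compute half-offset cumulative
  normalized weights sⱼ = (Σ_{k≤j} w_k − w_j/2)/Σw, interpolate linearly at
  s = 0.5. SE from a parametric bootstrap (default 1,000 replicates)
  redrawing both exposure and outcome effects from their sampling normals.
* **MR-Egger**: weighted regression with intercept after orienting exposure
  effects positive; inference via t with J−2 df; the residual variance is
  not floored, so an exact fit gives zero SEs (p-values then degenerate to
  the tiny-float limit).
* **Cochran's Q** about the fixed-effect estimate, df = J−1, upper-tail
  chi-square p.
* **MR-PRESSO**: observed weighted RSS of each instrument against its
  leave-one-out IVW prediction, compared to a null distribution from
  `n_sim` (default 1,000) redraws of all effects from their sampling
  normals; empirical p-values use the (1+#exceed)/(1+n_sim) convention.
  Outlier test: per-variant squared residual vs its simulated distribution,
  Bonferroni-corrected (reported p = raw × J, flagged below 0.05). Because
  the smallest attainable raw p is 1/(n_sim+1), outlier detection at level
  α requires n_sim > J/α — with J = 30 and α = 0.05, at least 600
  simulations. Distortion test: shift of the IVW estimate after removing
  flagged outliers, against removal of equally many random instruments.
* **Cook's distance** is computed on the whitened (multiply by 1/σ_Yj)
  through-origin IVW regression; instruments with D > 4/J are excluded. A
  numerically exact fit (residual variance at float-epsilon scale) excludes
  nothing. Note Cook's distance is leverage-weighted: an outlying outcome
  effect on a near-null instrument has little influence on the fit and is
  legitimately not flagged — tests plant outliers on strong instruments.
* **Re-analysis after removal** re-runs every estimator on the reduced set
  (error if fewer than 2 instruments survive). The sensitivity report
  removes the union of MR-PRESSO outliers and Cook's exclusions; no
  precedence between the two diagnostics is encoded — all are reported.
* **Reverse MR** swaps the roles and selects instruments from the original
  outcome at the stricter genome-wide settings (p < 5e-8, r² < 0.01).

## Multiplicity

BH step-up correction (via statsmodels) applied independently within each
(trait_type, panel) subgroup — 4 measurement types (MFI, AC, RC, MP) × 7
flow-cytometry panels = 28 groups when all keys are present; empty groups
are simply absent. Only the primary IVW p-values are corrected;
sensitivity-method p-values are reported raw. The grouping key is a
parameter, so correcting per outcome (adding the outcome id to the key) is
a one-line change; the 28-subgroup default treats the outcomes jointly.

## Multivariable MR and mediation

`mvmr_fit` solves the weighted normal equations without intercept; SEs carry
the same multiplicative over-dispersion floored at 1 as random-effect IVW
(df = J − k), so a single-exposure fit reproduces the fixed/random IVW pair
exactly. Rank deficiency of the weighted design is detected by pivoted QR
and reported as a collinearity error naming the offending columns.

Mediation follows the network-MR convention: the **total** effect is
univariable IVW of the outcome on the exposure over the exposure's own
instruments; the **direct** effect is the exposure coefficient of the MVMR
including the mediator; **indirect = total − direct** (difference method,
the default — it makes total = direct + indirect an identity). The
product-of-paths method (â from mediator-on-exposure IVW times the MVMR
mediator coefficient) is available as `method="product"` for cross-checks.

**Instrument policy.** The default (`"exposure"`) uses exposure-associated
SNPs only, reading the mediator's effects at those variants — the
convention stated for the emulated study. Under a pure causal chain this
design is degenerate: the mediator column equals a·γ at every instrument,
exactly collinear with the exposure column, so the mediator path is
identified only through measurement noise and the estimated proportion
mediated attenuates toward zero. `instrument_policy="union"` adds the
mediator's own instruments (selected from the mediator summary statistics
with the same thresholds), which identifies the mediator coefficient; all
recovery experiments use it. With real traits whose instrument effects are
not perfectly proportional, the exposure-only policy can be informative,
which is why it remains the documented default rather than an error.

Confidence intervals are percentile intervals from a parametric bootstrap
(default 1,000 replications): per-variant exposure, mediator and outcome
effects are redrawn from N(β̂, se²) and the full decomposition recomputed.
This is the only resampling available from summary data; BCa or
case-resampling would require individual-level access. A statistic
undefined in more than 10% of replicates is an error, except the proportion
mediated, which is reported as NaN when the total effect is numerically
zero (|total| ≤ 1e-12) rather than as an unstable ratio.

## Pipeline and determinism

`run_screen` executes simulate-or-ingest → select → estimate → sensitivity →
group-wise FDR → mediation and writes tab-delimited tables plus a manifest
(version, seed, effective configuration, per-stage row counts, SHA-256 of
input files). Every stochastic component takes an explicit seed derived
from the run seed, and re-running an identical configuration reproduces
byte-identical outputs. Per-pair failures (e.g. no instruments survive
selection) are logged to `errors.tsv` and do not abort the remaining pairs;
the run fails only if every pair fails. Input validation classifies
malformed headers, non-ACGT alleles, SE ≤ 0, p outside (0, 1] and duplicate
ids as fatal; boundary allele frequencies are warnings.

## Problem sizes used in the checks

Simulation-based checks run at desk scale, chosen to keep Monte-Carlo error
well below the margins being asserted: 5,000 replicates for type-I error
(binomial SE ≈ 0.003 at α = 0.05), 500 for bias orderings and Egger power,
200 for outlier recovery, and 100 for CI-coverage and mediation-recovery
rates, with 30–60 instruments per replicate. The weighted-median bootstrap
uses its 1,000-replicate default wherever an SE or CI is actually consumed
and a single replicate where only the point estimate enters a bias average.

## Known limitations

* No proxy-SNP lookup for instruments missing from the outcome, no Steiger
  directionality filtering, no MR-RAPS/mode-based estimators, no
  colocalization — by design out of scope.
* First-order weights (NOME) as discussed above.
* The Egger residual variance is unfloored; implementations differ here and
  slope SEs on heterogeneous data may be smaller than over-dispersed
  variants of the estimator.
* Reverse-direction MR inherits the contamination problem of outcome
  instruments that act through the exposure; with strong forward effects
  and few outcome-specific instruments the reverse estimate is biased away
  from zero (visible in the simulator when the outcome trait has no
  instruments of its own).
* The FDR subgroup labels are validated against the fixed 4 × 7 vocabulary;
  screens of other domains should pass `validate_labels=False` or their own
  grouping key.
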