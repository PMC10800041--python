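# Methods

## Summary-level model and scope

All computation is on GWAS summary statistics. For instrument j,
observed exposure and outcome effects are modelled as independent
normals around their true values with known standard errors, and the
true outcome effect decomposes as Γ_j = θ·γ_j + α_j: θ is the causal
effect of the exposure on the outcome, α_j a direct (horizontal
pleiotropy) effect that bypasses the exposure. Individual-level data,
binary-trait liability modelling, and multivariable MR are out of
scope. The exposure is treated on a continuous/standardized scale even
when it is a disease trait: the instrument-strength formula
R² = 2β²·eaf·(1−eaf) assumes that scale, and every estimator in the
package depends on the summary statistics only through ratios and
weights, which are scale-free in the sense that rescaling the outcome
rescales estimates proportionally. The generator carries an
`effect_scale` label, nothing more.

## Instrument selection

Selection is the conventional four-step sequence with these defaults:

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 5e-8 | genome-wide significance for exposure association |
| `clump_r2` | 0.001 | maximum pairwise r² after clumping |
| `clump_window_bp` | 10 Mb | clumping window |
| `proxy_r2` | 0.8 | minimum LD for an outcome-side proxy |
| `proxy_window_bp` | 1 Mb | proxy search window (not fixed by convention; exposed as config) |
| `f_min` | 10 | per-variant F retention cutoff |

Clumping is greedy by p-value with a lexicographic variant-ID
tie-break, which makes the output invariant to input row order. LD is
consumed as an unsigned pairwise r² table; because r² carries no sign,
a proxy's outcome effect cannot be re-oriented through LD — proxies are
harmonized against the original exposure alleles and dropped on a
mismatch. The exposure-side statistics of a proxied instrument remain
those of the original variant.

Harmonization aligns each outcome record to the exposure's effect
allele: identical coding is kept, swapped coding negates the outcome
beta, strand-complement coding (possibly plus swap) is resolved first,
and palindromic (A/T, G/C) variants are dropped unconditionally — with
alleles alone the strand of a palindrome cannot be resolved, and no
frequency-based rescue is attempted. Variants with missing eaf are
excluded before the F filter (the R² formula needs eaf). The F
statistic governing retention is per-variant (k = 1); the joint F over
the retained set (k = n_SNP) is reported for context only, since a
retention rule "F > 10" only type-checks per variant.

## Estimators

Wald ratios use the first-order delta-method standard error
se_out/|β_exp|, i.e. exposure-side sampling error is ignored in the
weights (the NOME approximation). Consequences and mitigations:

* **IVW**: fixed-effects weighted mean; the reported (random-effects)
  standard error is the fixed-effects one times max(1, √(Q/(n−1))).
  The floor at 1 means homogeneous data reduce exactly to fixed
  effects. P-values are two-sided normal.
* **MR-Egger**: weighted least squares of β_out on β_exp with an
  intercept, weights 1/se_out², solved by the normal equations.
  Instruments are first oriented so every β_exp ≥ 0 — the Egger model
  is not invariant to allele re-orientation and this is the established
  convention. Coefficient standard errors are multiplied by
  max(1, residual scale) and tested against t(n−2).
* **Weighted median**: ratios ordered ascending; with normalized
  weights w′ the cumulative midpoint is s_j = Σ_{i≤j} w′_i − w′_j/2 and
  the estimate interpolates ratio against s at 0.5 (clamped to the end
  ratios outside [s_1, s_n]). Standard error by parametric bootstrap:
  β_exp and β_out are re-drawn from normals at their observed values
  and standard errors, ratios and weights recomputed, and the spread of
  the point estimate over `n_boot` draws (default 1,000) taken.
* **Modes**: normal-kernel density over the ratios with equal (simple)
  or IVW (weighted) weights; bandwidth is `bandwidth_factor` × the
  modified Silverman value 0.9·min(sd, mad)·n^(−1/5); the estimate is
  the density argmax on a 512-point grid spanning [min − 3h, max + 3h].
  Zero spread degenerates to the heaviest ratio value. Bootstrap
  standard errors as for the median.

Minimum instrument counts: 1 (Wald), 2 (IVW), 3 (Egger, median, modes),
4 (the outlier test). Shortfalls raise typed signals that the study
runner records as data.

## Sensitivity battery and verdict

* **Cochran's Q** with p from χ²(n−1).
* **Residual-sum outlier test** (MR-PRESSO style): observed
  RSS = Σ_j (β_out,j − θ̂_(−j)·β_exp,j)² with θ̂_(−j) the leave-one-out
  fixed-effects IVW estimate; the null distribution comes from
  parametric re-draws of both sides (`n_sim`, default 1,000 — a
  convention, not a derived quantity). The global p uses the
  (1+count)/(1+n_sim) estimator so it is never exactly 0. Per-variant
  outlier p-values compare each observed squared residual with its own
  simulated distribution, Bonferroni-adjusted by n_SNP; note the
  attainable minimum is n_SNP/(1+n_sim), so `n_sim` must comfortably
  exceed n_SNP/α for detection to be possible at level α. Simulation
  streams are keyed to (seed, variant ID), making all outputs invariant
  to row order. When the global test is significant but no adjusted
  outlier p passes, outliers are declared unidentifiable and no
  corrected estimate is produced. The distortion p-value is a
  two-estimate bootstrap comparison: random instrument subsets of the
  corrected size are drawn from the full table and the displacement of
  the full-set estimate from the corrected one is ranked against them.
* **Steiger**: R² summed as 2β²·eaf·(1−eaf) on each side using the
  exposure eaf for both (internal consistency is what the comparison
  needs); direction is exposure→outcome when exposure R² is larger; p
  from the independent-samples Fisher-z comparison of √R² given the two
  sample sizes.
* **Leave-one-out**: IVW per omitted variant; flagged when any omission
  flips the estimate's sign or moves p across α.
* **Confounder screen**: a local variant→secondary-trait table stands
  in for an online phenotype-lookup service; matching is
  case-insensitive substring against a configurable confounder-trait
  list (default: body mass index, obesity, smoking, drinking,
  neuropsychiatric disease, hypertension, hyperlipemia). It runs only
  for nominally significant results, and IVW is re-estimated on the
  filtered set.

The verdict, in priority order: directional pleiotropy (Egger intercept
p < α) fails; a confounder screen that moves the re-estimated p above α
when the original was below fails; a wrong Steiger direction fails;
everything else survives. Heterogeneity alone never fails a result —
the random-effects IVW standard error already absorbs it — and the
leave-one-out flag is reported but not a verdict criterion, since
influence without sign/significance reversal is informational.

## Study grid and multiplicity

The default grid enumerates 34 atlas regions × {SA, TH} × {w, nw} plus
one global cell per measure = 138 cells; 4R + 2 for R regions. The
2-global-cell decomposition is the only one consistent with that total;
the weighting label of the global cells is metadata. Bonferroni uses
the number of cells actually run (α/138 = 3.62e-4, displayed at one
significant figure as 0.0004); "meaningful" means p below that
threshold, "nominal" means p < 0.05, so every meaningful cell is
nominal. Instruments are extracted and clumped once from the shared
exposure GWAS; matching, harmonization and the strength filter are
per cell. Per-cell seeds derive from the run seed and the cell's index
in the deterministic grid order, so a full study reproduces
bit-identically under one seed.

## Synthetic data generator

The generator emulates the two-sample layout at the motivating study's
scale — defaults are an exposure GWAS of N = 38,589, an outcome GWAS of
N = 51,665, 50 instruments on a background of 200 null SNPs — with:

* per-variant standard errors 1/√(2N·eaf·(1−eaf)), eaf uniform on
  (0.05, 0.95);
* instrument effects γ_j positive (the effect allele is coded as the
  exposure-increasing allele — the convention under which a nonzero
  mean direct effect is directional pleiotropy), drawn on the z scale
  from a normal centred 4 units above the genome-wide threshold
  z ≈ 5.45, truncated 1 unit above it, so instruments can pass 5e-8 at
  the configured N. A config whose instrument count would require total
  variance explained ≥ 1 (roughly n·z²/N) is rejected as unsupportable;
* direct effects α_j ~ N(μ_α, σ_α) on a configurable fraction of
  instruments; `inside_violation` mixes the standardized instrument
  strength into α with the given correlation, violating the InSiDE
  assumption on demand;
* block LD: variants laid out in blocks (one instrument per block head,
  blocks 20 Mb apart across chromosomes, so default instruments are
  mutually independent), with r² = ρ^(2|i−j|) within a block;
* allele realism: a configurable fraction of palindromic (A/T, G/C)
  codings, and outcome rows re-expressed with swapped allele order
  (beta negated) and/or on the opposite strand, which harmonization
  must undo exactly;
* optional confounder-linked instruments emitted as a secondary-trait
  annotation table for the screen.

All randomness flows from one `numpy` generator seeded by the config;
grid simulation spawns one child stream per cell. What the generator
does **not** emulate: case/control liability-scale effects, realistic
MHC-scale LD complexity, sample overlap between the two GWAS, allele
frequency differences between panels, and population stratification.
Passing tests therefore demonstrate correctness of the estimators and
plumbing under the stated generative model, not robustness to those
real-data pathologies.

## Problem sizes and numerical choices

The validation suite uses 1,000 replicates for the null rejection rate,
200 for estimate/coverage and Egger-intercept recovery, 100 for Steiger
direction, and a full 138-cell study at 30 instruments + 60 null SNPs
with 100 bootstrap and 150 outlier-simulation draws — sizes chosen so
the whole battery recomputes in about a minute on one core while
keeping Monte-Carlo error well inside the tested bands. A residual
~2% downward bias in the IVW estimate at the default instrument
strengths is the expected NOME/winner's-curse attenuation at finite
instrument F, visible in the calibration outputs and within their
Monte-Carlo bands.

Ties everywhere break by p-value then lexicographic variant ID;
p-values are floored at the smallest positive double rather than 0;
bootstrap draws of β_exp that land exactly on 0 are nudged to the
smallest positive double before forming ratios; BH adjustment is the
standard step-up with monotone enforcement; the nearest-gene distance
compares the variant position directly against BED boundary
coordinates (gap distance, 0 inside the gene), a one-base convention
choice that cannot change a nearest-gene assignment by more than a tie.

## Known limitations

* Wald-ratio weights ignore exposure-side error (NOME); no modified
  second-order weights are offered.
* Unsigned LD makes outcome-side proxies unusable when the proxy's
  allele coding cannot be harmonized against the original variant.
* The distortion test is the subset-resampling comparison described
  above, not a full outlier-redistribution scheme.
* The enrichment module validates ranking logic on synthetic
  annotations; real GO/KEGG term lists are database-version dependent
  and out of scope.
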