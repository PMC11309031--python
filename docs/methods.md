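# Methods

## Model and assumptions

The package implements summary-level (two-sample) Mendelian randomization.
For each instrument j we observe the per-allele association with the
exposure, βX_j with standard error σX_j, and with the outcome, βY_j with
σY_j, estimated in non-overlapping samples. Under the instrumental-variable
assumptions (relevance, independence from confounders, no effect on the
outcome except through the exposure), each Wald ratio βY_j/βX_j estimates
the causal effect θ, and the estimators differ in how they aggregate the
ratios when some instruments violate the third assumption (horizontal
pleiotropy).

Estimator conventions, chosen where the literature admits variants:

- **IVW, multiplicative random effects.** θ̂ = Σ w_j βX_j βY_j / Σ w_j βX_j²
  with w_j = 1/σY_j² (regression through the origin). The fixed-effect SE
  (Σ w_j βX_j²)^(−1/2) is multiplied by √max(1, φ), φ = Q/(J−1) the
  residual overdispersion; the floor at 1 means heterogeneity can widen but
  never narrow the interval. p-values are normal. With J = 1 this reduces
  exactly to the Wald ratio with its first-order SE σY/|βX|.
- **MR Egger.** Pairs are first oriented so βX_j > 0 (the fit is not
  invariant to allele coding, so a fixed convention is required), then βY
  is regressed on βX with an intercept, weights 1/σY². SEs carry the same
  max(1, ·) residual-scale floor; p-values use t with J−2 df. The intercept
  estimates average directional pleiotropy and feeds the pleiotropy test.
- **Weighted median.** Ratios sorted, weights 1/se_ratio² normalized;
  the estimate interpolates linearly at cumulative weight ½ (half-weight
  midpoint convention, so equal weights reproduce the ordinary interpolated
  median).
- **Mode-based (simple/weighted).** Gaussian-kernel density over the
  ratios, bandwidth h = φ_bw · 0.9 · min(SD, 1.4826·MAD) · J^(−1/5) with
  φ_bw = 1 by default; if one of SD/MAD degenerates to zero the other is
  used, and when all ratios coincide the common ratio is returned. The
  argmax is located on a 2001-point grid spanning [min−3h, max+3h].
- **Median/mode uncertainty** comes from a parametric bootstrap
  (B = 1000 by default, seeded): βX_j* ~ N(βX_j, σX_j²),
  βY_j* ~ N(βY_j, σY_j²), estimator recomputed per draw with refreshed
  first-order weights, SE = SD of the draws, normal CI and p. No closed
  form exists for the mode; using the same machinery for the median keeps
  the two comparable.

Sensitivity battery: Cochran's Q about the fixed-effect IVW estimate with
first-order ratio weights βX²/σY² (df J−1) and Rücker's Q′ about the Egger
fit (df J−2), both with χ² tail p-values; the Egger-intercept t-test; and
MR-PRESSO. The PRESSO observed statistic is the leave-one-out residual sum
of squares Σ_j w_j (βY_j − θ̂_{−j} βX_j)²; its null distribution is
simulated by redrawing βY*_j ~ N(θ̂_{−j} βX_j, σY_j²) and recomputing the
statistic, including the leave-one-out fits, per draw. All Monte-Carlo
p-values use the add-one convention, so they are bounded below by
1/(nb_sim+1); per-SNP outlier p-values are additionally Bonferroni-scaled
by J, which means outliers are only detectable when nb_sim is large enough
that J/(nb_sim+1) clears the significance threshold (with the default
nb_sim = 1000 and J ≤ 50 that holds). The distortion test compares the
relative shift of the outlier-corrected IVW estimate with the shifts
produced by removing random subsets of the same size.

Two-step mediation multiplies the exposure→mediator and mediator→outcome
IVW estimates (β1, β2) for the indirect effect and divides by the total
effect β3 for the proportion mediated. Uncertainty is a parametric
bootstrap with independent normal draws of the three effects — summary-
level data admit no individual-level resampling, and independence is an
approximation justified by the non-overlapping source GWAS. The pathway
p-value tests the indirect effect (z = point estimate / bootstrap SE); the
proportion's own bootstrap distribution is heavy-tailed whenever β3 is
imprecise, so it supplies intervals but not the test. If more than 1% of
β3 draws land within 1e-8 of zero the proportion interval is flagged
unstable and a warning is raised.

## Instrument selection and harmonization

Selection keeps SNPs with p strictly below the threshold (default 5×10⁻⁸;
per-exposure relaxation to 5×10⁻⁷/5×10⁻⁶ is a config field, mirroring
practice when few variants qualify), then greedily clumps: keep the most
significant remaining SNP (ties broken by position, then identifier) and
discard neighbours on the same chromosome within the window (default
10,000 kb) whose r² with it is ≥ 0.001. LD is consumed as a precomputed
pairwise table; pairs absent from the table are treated as unlinked, so
clumping without an LD table prunes nothing unless r² = 0 is requested.
Instrument strength uses R²_j = 2βX_j²·EAF_j(1−EAF_j) and
F = (N−K−1)/K · R²/(1−R²); the weak-instrument filter applies the per-SNP
form (K = 1), matching the per-SNP phrasing of the conventional F < 10
exclusion, while the joint-K F is also reported.

Harmonization aligns outcome records to the exposure's effect allele,
comparing allele pairs up to reverse complement before declaring a
mismatch. Palindromic (A/T, C/G) variants carry no strand information in
their letters; they are resolved through minor/major-allele concordance
when both studies' EAFs lie outside the ambiguity band [0.30, 0.70]
(configurable) and dropped otherwise — the band default is this package's
choice, not asserted as universal. Instruments absent from the outcome are
dropped, never proxied. Every exposure SNP lands either in the retained
pairs or in the exclusion log, and harmonization is idempotent on its own
output.

## Synthetic data generator

The generator emulates the three summary tables such an analysis consumes.
Per instrument j: EAF ~ Uniform(0.05, 0.95); true effects are drawn on the
standardized-genotype scale (per-allele effect ∝ 1/√(2pq), matching the
observed tendency of rarer alleles to carry larger per-allele effects) with
magnitudes Uniform(0.6, 1.4) around a common scale, then normalized so the
J instruments explain exactly r2_total of exposure variance. The spread
matters: near-constant effects leave MR Egger without slope identification
(I²_GX → small), while the chosen spread keeps the weakest instrument's
true F above 10 at the default scale. Effect alleles are reported as the
exposure-increasing allele, as in curated instrument lists. SEs follow the
standardized-trait formula se = (2n·pq)^(−1/2) per study; observed effects
are normal around γ_j (exposure), κγ_j (mediator) and
(θ_direct + κ·θ_med)γ_j + α_j (outcome), with independent noise across
the three studies (no sample overlap). p-values are exactly 2Φ(−|β/se|).
Pleiotropy regimes for α_j: none, balanced N(0,τ²), directional N(μ,τ²),
or correlated with γ_j at ρ (an InSIDE violation). A configurable fraction
of SNPs receives palindromic alleles (default 0, so bookkeeping identities
are exact; tests opt in). An optional block mode places consecutive SNPs
10 kb apart and emits a matching LD table to exercise clumping.

The paper-scale preset fixes the study conditions of the headline analysis:
J = 26 instruments, total effect θ = 0.79 decomposed as
θ_direct = 0.4755 plus κ = 0.85 times θ_med = 0.37 (true proportion
mediated ≈ 0.398), r2_total = 0.01, exposure/mediator GWAS n = 90,000 and
outcome n = 30,000, giving mean per-SNP F ≈ 35 with every true F ≥ 10 and
roughly half to two-thirds of instruments passing 5×10⁻⁸.

What the generator does **not** emulate: LD between instruments (summary
rows are independent; the block mode correlates only the emitted LD table,
not the statistics), realistic allele-frequency spectra, binary-outcome
liability scales, sample overlap, and population stratification. Passing
tests therefore validate the estimators and the pipeline plumbing under
the stated sampling model, not robustness to those real-data features.

Because the mediator table of one study contains only the exposure's
instruments (with effects κγ_j), the mediator→outcome leg of mediation is
exercised with a *second* generated study placing the mediator in the
exposure role — precisely how a real two-step analysis uses the mediator's
own GWAS hits. Reusing the exposure's instruments for that leg would
estimate θ_total/κ instead of θ_med.

## Simulation scales used in the checks

Recovery and calibration checks run at two deliberate scales:

- **Strong-instrument scale** (exposure/mediator n = 4,000,000, mean true
  per-SNP F ≈ 1500): used for parameter-recovery and type-I-error checks.
  IVW on noisy exposure effects carries relative attenuation ≈ 1/(F̄+1)
  and Egger suffers regression dilution 1 − I²_GX; at F̄ ≈ 35 these biases
  (~3%) exceed the Monte-Carlo resolution of a 500-replicate mean, so
  unbiasedness is asserted where it actually holds. The outcome GWAS stays
  at n = 30,000 so sampling noise remains realistic.
- **Paper scale** (F̄ ≈ 35): used for power, coverage, robustness and
  pipeline checks, where finite-instrument-strength bias is part of the
  phenomenon being tolerated, as it is in the real analysis.

Replicate counts follow the size of the effect being measured: 500 for
means and type-I rates, 200 for coverage and robustness contrasts, with
MR-PRESSO at nb_sim = 300 in repeated-replicate checks and 1000 elsewhere.

## Pipeline behaviour

The orchestrator runs selection → clumping → F-filter → harmonization →
estimator suite → sensitivity battery per exposure, contains per-exposure
failures in a failure log without aborting the run, and BH-adjusts the IVW
p-values across exposures by default (the adjusted family is
configurable). Mediation screening follows the two-step order: a mediator
enters only if its own instruments give a significant (p < 0.05) IVW
effect on the outcome and no Egger-intercept evidence of pleiotropy
(p < 0.05 — the generalization of excluding a pleiotropic mediator);
exposures enter only if FDR-significant on the outcome; each surviving
pathway additionally requires a significant exposure→mediator effect.
All randomness derives from the single config seed via per-component
seed derivation (CRC-tagged SeedSequence), and report metadata contains no
timestamps, so identical inputs, config and seed reproduce every output
byte for byte.

## Known limitations

- No multivariable MR, Steiger directionality filtering, proxy-SNP lookup,
  or non-linear (J/U-shaped) dose–response modelling.
- LD is consumed, never computed; clumping fidelity is bounded by the
  supplied table.
- The weak-instrument F filter uses summary-level R² and assumes EAF and N
  are available and accurate.
- Egger estimates remain sensitive to low instrument-strength heterogeneity
  (I²_GX); the package reports but does not correct for it (no SIMEX).
- Bootstrap independence of β1/β2/β3 ignores any residual sample overlap
  between source GWAS.
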