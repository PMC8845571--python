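# Methods

This note documents the models, estimators and numerical choices behind
`gradientnet`, and what the synthetic study does and does not establish.

## The pH pseudo-series

The survey design is cross-sectional: samples differ in pH, not in time.
The analysis treats the acidic samples (pH < 5.1, where exchangeable Al³⁺
rises sharply) as a *pseudo-series* indexed by pH in equal ΔpH = 0.01 steps.
`build_ph_series` rounds each sample's pH half-up to the nearest step,
averages the proportion profiles of samples sharing a step, and fills
interior gaps by linear interpolation between the flanking observed steps.
Every filled step is flagged, and provenance (step → contributing samples)
is kept, so downstream stages can treat observed and interpolated steps
differently:

- **Spectral diagnostics exclude interpolated steps.**  Linear interpolation
  manufactures autocorrelation, which would redden every spectrum.
- **Interaction inference includes them by default.**  A survey of ~130
  acidic samples occupies only a fraction of a ~150–200-step grid; demanding
  both endpoints of a transition be observed leaves ~45 usable transitions
  for a 12-taxon regression, far too few.  Interpolated transitions are
  smoothed versions of the underlying change and empirically help rather
  than hurt recovery; `exclude_interpolated=True` restores the strict
  behaviour.
- `max_gap` bounds how long a stretch may be fabricated (default 10 steps
  for generic use; the pipeline passes 50 because a nested region/field
  design clusters samples, leaving wider between-region gaps).

Whether to build the series from counts or proportions is not dictated by
the data; proportions are used because sequencing depth varies per sample
and the Ricker regression operates on relative abundances.

## Noise color and neutrality

Per taxon, `periodogram_slope` estimates the spectral exponent by OLS of
log₁₀ power on log₁₀ frequency over the positive frequencies of the
mean-detrended periodogram.  `classify_noise` maps slope s (when
significantly negative at p < 0.05) to left-closed bins centred on the
canonical exponents: white s ≥ −0.5, pink [−1.5, −0.5), brown [−2.5, −1.5),
black < −2.5.  The bin edges are a package choice (the colors' canonical
exponents are 0/−1/−2/−3) and are exported as constants.

`neutrality_test` screens for temporal structure before inferring
interactions.  The statistic is the mean cross-validated R² (4 contiguous
blocks) of a linear one-step predictor of each taxon's increment from the
full community state.  The null cyclically shifts every taxon's series by an
independent random offset: each taxon's marginal autocorrelation (and its
own self-predictability) is preserved, while cross-taxon alignment is
destroyed, so the test is sensitive specifically to between-taxon structure.
p = (1 + #{null ≥ observed}) / (1 + n_perm); the verdict is *structured* iff
p ≤ 0.5.  The lax threshold deliberately lets anything except clearly
structure-free series through to inference.  Under an exchangeable null the
p-value is uniform by construction (verified by a KS calibration test), so
structure-free series are called neutral about half the time at this
threshold — the screen is a filter for obvious non-structure, not a
hypothesis test at conventional levels.

## Ricker / LIMITS interaction inference

Model: x_i(t+1) = x_i(t)·exp(r_i + Σ_j A_ij x_j(t) + ε_i(t)), so the
log-ratio y_i(t) = ln x_i(t+1) − ln x_i(t) is linear in the state.
`RickerInteractionModel.fit` estimates row i of A by forward stepwise ridge
with bagging:

1. 31 random half-splits of the transition axis (train/validation);
2. per bag, start from the self term (A_ii is always modelled but never
   becomes an edge — it is density dependence, not interaction), then add
   the predictor that most reduces validation MSE while the relative
   reduction is ≥ `error_threshold`;
3. keep A_ij only if j was selected in ≥ 50% of bags; the estimate is the
   median over the bags that selected it.

Ridge is applied on standardized predictors (penalty `ridge_lambda`·n on the
standardized scale, default 0.01, intercept unpenalized) and coefficients
are mapped back, so the penalty strength does not depend on the abundance
units.  A pseudocount (half the smallest nonzero value) is added only when
zeros are present.  `error_threshold` defaults to 0.05: the best of ~n_taxa
chance candidates reduces held-out MSE by roughly 2·k/n_val ≈ 3–5% on
series of one–two hundred transitions, so a smaller threshold admits about
one spurious predictor per target and fills the network with false edges;
0.05 keeps the false-edge count near zero at the cost of missing the weakest
true links.  All of these are constructor parameters.

Identifiability caveat: a noiseless system relaxing to equilibrium stops
being informative once fast modes decay (all deviations become collinear);
sustained excitation — process noise or oscillatory/chaotic dynamics — is
what makes A recoverable.  Tests therefore benchmark noiseless recovery in
the sustained (chaotic-regime) Ricker parameterisation.

Link-structure significance rethrows the nonzero off-diagonal entries to
uniformly random off-diagonal positions (preserving their number and
values), recomputing the non-orphan taxon count (or edge count), with
p = (1 + #{random ≥ observed}) / (1 + n_rand), n_rand = 100.

## Roles, niche breadth, letters

Roles come from the in-/out-degrees of the directed network: influential
(out only), sensitive (in only), bidirectional (both), orphan (neither).

Levins' niche breadth B_j = 1/Σ_i P_ij², with P_ij the proportion of OTU j's
abundance found in community (sample) i of a metacommunity.  The
metacommunity is a pH bin — pH < 5.1, [5.1, 7), ≥ 7 by default (bin edges
configurable) — and Bcom is the mean B over the role's members present in
the bin; absent members are excluded from that bin's mean rather than scored.
B is computed within each bin separately (a `--global` alternative would
compute over all samples then average; per-bin is the default because the
breadths are compared *between* pH conditions).

`range_groups` runs one-way ANOVA then a multiple-range letter display.
Duncan's test compares the range of k adjacent ordered means against
q_{(1−α)^{k−1}}(k, df)·√(MSE/n_h) (studentized-range quantiles at the
stepwise protection levels, harmonic mean group size), with non-significant
ranges protecting their sub-ranges; Tukey's HSD is the conservative
alternative and doubles as an independent cross-check in the tests.

## Gene–taxon associations and Mantel tests

`spearman_fdr_network` computes Spearman r (average ranks for ties) for
every gene × taxon pair over shared samples, two-sided p-values from the t
approximation, Benjamini–Hochberg correction across all tested pairs as one
family, and keeps edges with r > 0.6 and q < 0.01 (an `absolute` flag admits
strong negative correlations).  Constant vectors are skipped with a warning.

`mantel` correlates the strictly-lower triangles of two distance matrices
(Pearson) and permutes the row/column labels of the second jointly,
one-sided (greater), add-one convention; `n_perm="exact"` enumerates all
permutations for small matrices.  `partial_mantel` residualises both
triangles on the third matrix by OLS and permutes the second matrix's
labels; residualising a matrix on itself is detected and returns r = 0
rather than numerical noise.

`fit_exponential_decay` fits Al³⁺ = a·e^(−b·pH) by nonlinear least squares
initialised from the log-linear fit, with R² on the original scale and a
log-linear fallback on non-convergence.

## The synthetic study

`SimulationConfig` defaults define the study conditions:

- **Design**: 13 regions × 3 fields × 11 subsamples = 429 samples; region
  mean pH on an equally spaced grid over 3.6–8.7 (the north–south transect);
  field offsets N(0, 0.18), subsample jitter N(0, 0.12); pH clipped to the
  range and read to 0.01.  About 130 samples fall below pH 5.1.
- **Chemistry**: Al³⁺ = 4000·e^(−1.5·pH)·Lognormal(0, 0.6) (units of mg/kg;
  the rate and noise give a visually and statistically strong but scattered
  exponential, R² ≈ 0.6); 14 covariates (MAT, MAP, OM, …) are linear-in-pH
  trends plus noise.
- **Tolerant community**: 12 of 120 taxa, assigned genera from the
  Al-resistance probe source pool (disjoint from the other genera, so
  gene-based identification is exact by construction — the point of that
  stage is plumbing, not difficulty).  A sparse signed interaction matrix
  (density 0.08 of off-diagonal slots ≈ 10–11 edges, magnitudes
  uniform [0.24, 0.48], random sign, self-limitation −0.25) is drawn with an
  equilibrium targeted directly (x* ~ U(0.7, 1.3), r = −A x*) and accepted
  only if the linearised update is stable.  The trajectory along the acidic
  grid uses process noise σ = 0.15.
- **Mapping to data**: the tolerant block maps *linearly* to relative
  abundances, p_i = c·x_i with one global c putting ~70% of acidic
  community mass in the block; the neutral lognormal baseline fills the
  remainder.  The linear map keeps the planted Ricker relation valid on the
  observed relative-abundance scale; renormalising the block per sample
  would inject a compositional common mode that the inference model does not
  describe.  Counts are multinomial at a per-sample depth in
  [20000, 30000]; gene signals are sums of linked-taxon proportions plus
  |N(0, 0.002)| noise, with antioxidant probes linked to taxa that have
  out-edges.
- **Seeding**: one global seed expands to per-stage child streams by fixed
  offsets, so stages are independently reproducible.

The dynamics parameters (weak self-limitation, σ = 0.15, magnitudes ≈
0.24–0.48) were chosen so that a ~150-step series carries enough excitation
for the interaction structure to be statistically identifiable at
20,000-read depth: per-edge signal grows with A²·var(x_j), and var(x_j)
grows as self-regulation weakens and process noise rises above the
sequencing noise floor.  A flatter, lower-noise regime is equally realistic
ecologically but leaves the planted structure unidentifiable at this series
length — recovery tests would then measure the generator, not the estimator.

**What the generator does not emulate**: real rank-abundance tails (only a
two-parameter lognormal baseline), spatial autocorrelation within fields,
pH measurement error, OTU-level phylogenetic structure, gene probes with
cross-hybridisation, or tolerant taxa whose genera overlap non-tolerant
ones.  Passing the recovery tests therefore shows the pipeline is correct
and well-calibrated under its own model assumptions — not that the same
accuracy would be achieved on field data, where genus-sharing between
tolerant and non-tolerant OTUs and unmodelled environmental forcing will
blur both the identification and the inference stages.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline at the
default 429-sample, 120-taxon configuration (seconds on one core), the
neutrality calibration at 200 runs × 99 permutations on 6 × 48 series, the
FDR calibration at 20 seeds × 2500 pairs, and the Mantel tests at
999/499 permutations on ~130 acidic samples.  Every stochastic component
takes an explicit seed and is exactly reproducible; all tabular outputs are
plain TSV/JSON.
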