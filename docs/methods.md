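# Methods

## Labeling quantities

A mass-isotopomer distribution (MID) is the vector of relative abundances
M₀…Mₙ of an ion's isotope peaks, normalized over the isotopomer window the
upstream extraction software reports — the package neither extends nor
truncates envelopes, since the definition of the monoisotopic share is tied
to the observed cluster. Total labeling is E = 1 − M₀/ΣMⱼ; E and the
monoisotopic share are exact complements, and E is invariant under global
intensity scaling. Negative intensities are rejected rather than clamped:
they indicate an upstream extraction fault that silent repair would hide.

No natural-abundance baseline is subtracted before computing E. The
kinetic model's fitted baseline E(0) absorbs whatever constant offset the
unlabeled envelope carries, which is also why a nonzero true baseline
(default 0.02 in the generators) is the realistic simulation condition —
it keeps the E(0) ≥ 0 constraint inactive, as it is in real fits.

For discrete tracers (e.g. d3-acetate appearing at M+3), the molar
fraction of the labeled species is estimated as the normalized abundance at
M+shift minus the same coordinate of an unlabeled reference spectrum,
clamped at zero. This is the simplest excess-abundance estimator; it is
exact for a two-component mixture of the reference envelope and a pure
M+shift species, and biased low if the labeled species' own envelope leaks
into neighboring isotopomers.

## One-compartment fitting

E(t) = E(0) + (E(ss) − E(0))(1 − e^(−kt)) is fitted by variable
projection. Writing a = E0, b = Ess − E0 and x(t) = 1 − e^(−kt), the model
is a + b·x, linear in (a, b) under the constraints a ≥ 0, b ≥ 0, a + b ≤ 1
(equivalently 0 ≤ E0 ≤ Ess ≤ 1). For fixed k this convex QP over a
triangle is solved exactly by candidate enumeration (interior stationary
point plus the three clipped edge minimizers). k is profiled on a 200-point
log grid over [1e-4, 10] d⁻¹ and refined by golden-section search to
relative tolerance 1e-8. The procedure is deterministic — no starting
values, no seeds — and global to within grid resolution; a unit test checks
agreement with an exhaustive 10⁵-point grid, and noise-free data are
recovered to |Δk|/k < 1e-6.

Joint ("collective") fits share one k across all peptides of a parent with
per-peptide (E0, Ess), reflecting that the plateau depends on the peptide's
exchangeable-hydrogen content while turnover is a property of the protein
(or acetyl-site). The profile RSS is then a sum of independent per-peptide
QPs, so joint fitting costs the same per candidate k as single fitting.

Rate estimates at the search boundary are flagged non-converged, as are
series with no labeling amplitude (all plateaus equal to baselines); both
are excluded from downstream inference. The standard error of k comes from
the curvature of the profiled RSS at the optimum (central differences,
relative step 1e-4): Var(k) ≈ 2σ̂²/(∂²RSS/∂k²), σ̂² = RSS/df. Confidence
intervals use the t(df) quantile; simulated coverage of the 95% interval is
~95% at σ_E = 0.005 (checked in the test suite). Time is in days and k in
d⁻¹ throughout; t½ = ln2/k.

## Two-group inference

The between-group test for a turnover change is a nested-model F-test. Full
model: per-peptide (E0, Ess) shared across groups plus one rate constant
per group; reduced model: the same with a single common rate. Sharing the
baselines/plateaus across groups reflects matched body-water enrichment in
the two arms — the plateau is peptide chemistry, not treatment — and makes
the test a pure one-degree-of-freedom contrast on k:

    F = (RSS_reduced − RSS_full) / (RSS_full / (n − p_full)),  p_full = 2P + 2

referred to F(1, n − p_full). The full model is optimized by coordinate
descent started at the reduced optimum, so RSS_full ≤ RSS_reduced holds by
construction. Because the shared linear parameters couple the two rates,
the RSS valley runs diagonally in (k_PF, k_EF); descent therefore operates
in mean-ratio coordinates k_PF = s/r, k_EF = s·r, which align with the
valley and converge in a few sweeps (verified against a dense 2-D grid).
Empirical type-I error at α = 0.05 is ≈ 0.05 over 2000 null replicates
(slightly anticonservative, ~0.055, from the nonlinearity of the profiled
rate at n = 18 observations).

Fold changes are reported as log2(k_EF/k_PF). Multiplicity is controlled
with Benjamini–Hochberg step-up adjustment (via statsmodels), applied as
three separate families — native-protein turnover, acetyl-site turnover,
differential abundance — because they answer separate questions; adjusted
p < 0.05 is the default significance call. Differential abundance on log2
intensity tables uses Welch's two-sample t-test by default (a pooled
variance flag is provided); features with fewer than two finite values in
a group are reported untested rather than silently dropped.

## Histone acetylation stoichiometry

Forms of a derivatized histone peptide are grouped by acetyl count (the
only thing MS1 distinguishes). Within the monoacetylated class, positional
isomers are resolved from fragment light/heavy pairs: for H3 18–26
(KQLATKAAR) the b2 ion contains only K18, so share(K18ac) =
b2_light/(b2_light + b2_heavy); for H4 4–17 (GKGGKGLGKGGAKR) the per-ion
light fractions f(y5), f(y7), f(y12) telescope into K16 = f(y5), K12 =
f(y7) − f(y5), K8 = f(y12) − f(y7), K5 = 1 − f(y12). Noise can invert the
ladder; negative shares are clamped to zero, the vector renormalized, and
the event flagged per record. Fragment intensities are summed across scans
of the same precursor form before the ratio is taken, which weights scans
by intensity. Per-site stoichiometry is then

    stoich(site) = Σ_f MS1(f) · occ_f(site) / Σ_f MS1(f)

over all quantified forms including the all-heavy (endogenously
unmodified) one, whose presence is required — without it the denominator is
incomplete and the computation refuses to proceed. Stoichiometries are
invariant to global MS1 scaling. H4 2ac/3ac species would need an
MS1-MS2-MS3 scheme for positional attribution; they enter the denominator
and are reported as a combined class (the four middle diacetyl species
K5K12/K5K16/K8K12/K8K16 summed), not per site.

## Synthetic data

The generator emulates the two-group terminal-sampling design: 9 animals
per group, each euthanized at one point of the {0, 1, 3, 7, 14, 21}-day
grid (round-robin allocation), peptide labeling drawn from the
one-compartment model with per-peptide plateaus uniform on [0.05, 0.15],
true baseline 0.02, and independent Gaussian noise on E truncated to
[0, 1] (σ_E = 0.005 by default, the scale at which fitted-rate CVs are a
few percent). The compartment-effect template plants rate decreases in
mitochondrial parents and increases in cytosolic parents. Body water
follows a single-exponential rise from a bolus-set initial enrichment
(2%) to a 3.5% plateau at 0.5 d⁻¹. Histone fixtures are generated by the
same telescoping fragment model the analyzer inverts, with multiplicative
log-normal intensity noise; log2 abundance tables are Gaussian with
planted mean shifts. Every generator ships its ground truth, and all
stochastic draws flow from one seed.

What the generator does *not* emulate: chromatographic interference,
identification errors, missing-at-random dropout, correlated residuals
within an animal, or isotopomer-level spectral noise (an optional raw-MID
mode convolves binomial labeling for testing the isotopomer layer, but
E-level noise is the default because E is the quantity the model fits).
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to every artifact of real
LC-MS data.

## Power analysis

`simulate_power` estimates the probability that the nested F-test rejects
at α for a given fold change, by simulating the full design per replicate
and fitting both models with a vectorized implementation of the same
profiling algorithm (pinned to the scalar API by a consistency test).
Replicates whose rate estimates hit the search boundary are excluded and
reported via `n_sim_effective`. Because the measurement-noise SD of real
designs comes from prior data that a new design rarely has,
`calibrate_noise` inverts the power curve: bisection on σ_E with common
random numbers (the same plateau and noise draws reused at every σ), which
makes the curve a clean monotone step function and the result reproducible.

The power scenario's plateau defaults to a *fixed* typical value (0.10)
rather than a per-replicate draw. This is deliberate: the signal amplitude
(Ess − E0) enters the F-test noncentrality squared, so a scenario that
mixes amplitudes from a wide range is a mixture of easy and hard
replicates, and the calibrated power relationship across fold changes
flattens — a mixed design point calibrated to 82.4% power at a 1.3-fold
change tops out near 95% at 1.5-fold, whereas the homogeneous design point
gives ≈ 99.4% (both facts reproducible from the noncentral-F distribution
alone). A power analysis describes one typical peptide; population
heterogeneity belongs in the data generator.

Default design: n = 9/group, six time points over 21 days, k = 0.15 d⁻¹,
α = 0.05, 1 peptide (acetyl-site) or 3 (native protein). With these
settings, calibrating to 82.4% power at a 1.3-fold change yields ≈ 99.4%
at 1.5-fold (one peptide), and calibrating to 99.2% yields ≥ 99.9% (three
peptides); `scripts/acceptance.py` recomputes these each run.

## Numerical and design choices

- Rate search bounds [1e-4, 10] d⁻¹ cover half-lives from ~4 minutes to
  ~19 years; anything at the boundary is treated as non-identifiable.
- The golden-section stage always returns the best point *seen*, so grid →
  refinement never increases RSS, and the full model is initialized at the
  reduced optimum, so nesting (RSS_full ≤ RSS_reduced) is structural.
- Monte-Carlo sizes: 2000 replicates for calibration and power (binomial
  SE ≤ 1.1 points), 1000 for CI coverage, 200 fixtures for stoichiometry
  noise studies — sized so the full test suite runs in a couple of minutes
  while keeping MC error well inside the tested tolerances.
- Fragment channel matching tolerance defaults to 0.02 Da — tighter than a
  typical MS2 tolerance because the light/heavy spacing (3.0188 Da per
  acetyl) invites crosstalk at loose settings; both masses and the
  tolerance are configurable constants.
- TSV is canonical on disk; JSON configs reject unknown keys (silent
  misconfiguration is the main reproducibility hazard); the pipeline
  manifest records inputs, outputs, content hashes, seed and parameters.

## Known limitations

- The one-compartment model ignores precursor (free amino-acid pool)
  kinetics; for very fast-turnover proteins the rise of body-water and
  precursor enrichment biases k downward. Multi-compartment precursor
  models are out of scope.
- Plateaus are fitted per peptide, not predicted from sequence-specific
  exchangeable-hydrogen counts; the package therefore cannot check a
  fitted plateau against theory.
- The F-test's slight anticonservatism at n = 18 (~0.055 empirical at
  nominal 0.05) is inherent to nonlinear least squares at small df; users
  needing exact calibration should permute group labels.
- Acetyl-site turnover treats the acetylated peptide's labeling as the
  site's turnover signal; acetyl-group exchange on a stable backbone and
  backbone synthesis are not separated.
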