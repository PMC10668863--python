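# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Spectral core

All computations live on a 300–700 nm grid at 1 nm; integrals are
trapezoidal. Spectra are non-negative, unit-tagged, and strictly increasing
in wavelength; duplicate wavelengths in input files (instrument re-scans)
are averaged rather than rejected, and resampling outside a spectrum's
support pads with zero and warns, because measured sky and LED exports
routinely cover different ranges.

Energy↔photon conversion uses N(λ) = E(λ)·λ/(hc) with CODATA constants.
Photometric intensity uses the CIE 1924 photopic V(λ) (tabulated at 5 nm,
interpolated) and 683 lm/W; candela values label stimulus settings only and
make no claim about bird-perceived brightness. `total_photon_output` sums
per-bin counts on the 1-nm grid — the counts-per-bin reading of
spectroradiometer photon exports; if a deposited file instead stores
densities per nm the sum coincides on a 1-nm grid, which is why the 1-nm
working grid is also the safest summation convention.

## Visual system

Pigment absorbance uses the Govardovskii et al. (2000) A1 nomogram (alpha
plus beta band), normalized to peak 1; its source is pinned here because
only the pigment peak wavelengths, not the template, are usually reported
with retinal data. Oil droplets are either tabulated transmittance or a
Gompertz long-pass `exp(−exp(−slope·(λ−cut)))` with slope 0.08 nm⁻¹ —
a smooth cutoff of realistic steepness; the shortest-wavelength cone is
droplet-transparent by default, as is typical for violet/UV cones.

Ocular media: scans are averaged, max-normalized, and λ_T0.5 is the first
upward 0.5-crossing from short wavelengths, linearly interpolated between
grid points (a curve already above 0.5 at the short end has no measurable
cutoff and is an error). A four-parameter logistic
`d + (a−d)/(1+exp(−(λ−m)/s))` is least-squares fitted and replaces the raw
curve *below* λ_T0.5, so short-wavelength instrument noise cannot leak into
quantum catches; if the fit fails on degenerate input the raw curve is kept
with a warning. On synthetic logistic scans with noise SD ≤ 0.02 the cutoff
is recovered within 1 nm.

Exact Canada-goose cone parameters (λmax, droplet cutoffs, densities) are
not bundled: they are configuration inputs (YAML), and the synthetic
tetrachromat (peaks ≈405/460/515/570 nm, densities 1–2.2, ω = 0.1, ocular
cutoff ≈369 nm) is a clearly-labelled placeholder for tests and examples,
not a transcription of measured goose values.

## RNL contrast

The log-linear receptor code (Δf as log catch ratio after von Kries
adaptation to the background) is the bright-light/photopic convention of
the Vorobyev–Osorio framework; the background radiance itself is the
adapting field, with no separate illuminant multiplication, because the
stimuli are emissive LEDs viewed against sky radiance. ω defaults to 0.1 on
the most abundant cone and is configurable. The general-n ΔS formula is
implemented once and checked in tests against independently coded di-,
tri- and tetrachromat closed forms (equality to 1e−10). Zero quantum
catches raise an error naming the cone: silently clamping would corrupt the
JND scale.

## LED scan

Peak shifting is a rigid translation of the template (no wavelength
warping); tails truncated at the grid edge are re-normalized to the target
peak afterward. "Normalize to 4000 photons" means peak value, not total.
Candidate peaks are local maxima of the ΔS curve, greedily thinned to a
60 nm minimum separation (so one short- and one long-wavelength candidate
emerge), ties breaking toward shorter wavelengths; a flat curve falls back
to the global argmax with a warning. Grid-edge maxima can be excluded
(`include_edges=False`) since a maximum at the scan boundary is a
truncation artifact rather than a relative peak — the analysis scripts do
so. Radiometric matching minimizes the relative difference in peak photon
output over all setting pairs; commercial availability of an emitter at the
chosen wavelength is a lab decision outside the algorithm.

The synthetic LED template is an asymmetric Gaussian (FWHM 30 nm, the
long-wavelength flank 10% broader) with a 1e−3 stray-light pedestal.
The pedestal reflects real spectroradiometer exports, which never fall to
exactly zero; without it, simulated LEDs far from every cone peak produce
astronomically large JNDs driven entirely by the ratio of near-zero tail
catches.

## Mixed models

Both families use a single random intercept per bird — the study design
(8 trials per bird) cannot support random slopes.

*Gaussian:* REML, profiled over the variance ratio φ = σ²_b/σ²_e and
optimized in log φ over a 1-D bounded search (Woodbury identities per
group, so fits are closed-form fast and the repeatability bootstrap of
1000 refits is cheap). Per-term tests are Type-III-style F statistics on
sum-coded designs with Satterthwaite denominator degrees of freedom,
computed by the eigendecomposition method: the term's contrast covariance
is diagonalized, each 1-df component gets ν = 2f²/(gᵀAg) with g the
numerical gradient of the contrast variance in (σ²_b, σ²_e) and A the
inverse numerical Hessian of the REML criterion. Kenward–Roger is not
implemented; for random-intercept models Satterthwaite is near-identical,
and the implementation reproduces lmerTest's F, denominator df and p to
three or more significant digits in the test suite. When the individual
variance is estimated at the boundary the fallback denominator df is
n − p, and the fit carries a `singular` flag (reported, never discarded —
the scientific focus is the fixed effects).

*Binomial:* Laplace-approximated maximum likelihood. The joint mode of
(β, b) is found by penalized IRLS (Newton with a Schur-complement solve
and step-halving); the Laplace log-likelihood is optimized over log σ_b
(1-D bounded). Quasi-separated cells (an all-0 or all-1 treatment cell)
stall on a likelihood plateau and return large-but-finite estimates with
large SEs, mirroring glmer; *complete* separation — every observation
perfectly predicted — raises an error. Per-term tests are
likelihood-ratio χ² against the refit without the term's columns.
The implementation matches glmer's log-likelihood and variance component
to ~1e−3 in the test suite.

Estimated marginal means average predictions on the link scale over a
balanced grid of the model's factors with covariates at their observed
means, back-transforming with a delta-method SE for the binomial family.
The reference grid for the 8-level trial-order factor is the balanced grid.

Marginal/conditional R² follow the variance-decomposition convention:
marginal = Var(Xβ)/(Var(Xβ)+V_ind+V_res), conditional adds V_ind; for the
logistic family the latent residual variance is fixed at π²/3.
Repeatability is 100·V_ind/(V_ind+V_res) with a parametric-bootstrap
percentile CI (default 1000 refits of data simulated from the fitted
model, seeded; the reported interval is widened to contain the point
estimate so the invariant ci_low ≤ value ≤ ci_high always holds).
Classification: ≤20% low, ≤40% moderate, otherwise high.

*Stepwise ladder:* step 1 tests color×frequency on top of the base model
(color, frequency, categorical trial order, PCA1); step 2 adds the two
order interactions; step 3 the two ambient-light interactions; each step
drops non-significant candidates (α = 0.05) and carries survivors forward;
step 4 refits base + survivors as the reported model. Every intermediate
test is kept in the report. Trial order is categorical throughout because
the expected exposure effects (avoidance→attraction reversals, U-shapes)
are not monotone slopes.

The ambient-light PCA uses the correlation matrix — eigenvalues then sum
to the number of variables and the eigenvalue-greater-than-1 retention
rule is meaningful; PCA1 is oriented so both loadings are positive (higher
score = brighter arena). Arena side is excluded from the response models
because the counterbalanced design makes light-on side structurally
associated with the other factors; the side-bias diagnostic (intercept-only
logistic GLMM on the no-light control trials) is provided instead.

## Synthetic data: what it emulates, and what passing means

The trial generator reproduces the design exactly: 19 birds (the number
completing all treatments), 8 trials each — all four color×frequency cells
in trials 1–4 with randomized sides, repeated in trials 5–8 with sides
flipped. Ambient lux pairs are bivariate lognormal; the `lux_correlation`
parameter (default 0.83) is the *raw-scale* Pearson target, converted
internally to the corresponding log-scale correlation. Avoidance is
Bernoulli with per-cell log-odds following the observed pattern (red:
strong initial avoidance decaying to attraction; blue: a U-shape settling
at weak avoidance), plus a pulsing-by-ambient interaction (pulsing more
avoided in bright conditions, default coefficient 0.6 per SD of ambient
score) and a small individual intercept SD (0.2, echoing the near-zero
between-individual variation in binary choices). Latencies are gamma
(base mean 35 s; red and pulsing faster, multiplicatively), capped at
600 s — capped trials become mistrials and are dropped, as are a further
2% at random. Movement counts are Poisson over the visible duration with
a small individual log-rate SD (0.08, keeping movement repeatability in
the "low" band the study reports). The side-bias control is 23 birds × 3
trials with P(right) = 0.41.

For power simulations the generator exposes `color_order_reversal`: a
color effect of the stated log-odds magnitude whose sign flips between the
first and second half of the trial sequence — the shape of the observed
avoidance-to-attraction reversal. A reversal of 1.5 at 40 birds gives the
7-df interaction test near-certain power, which is what the retention
calibration exercises.

What the synthetic data do *not* contain: real sky and LED spectral shapes
(so the candidate peak wavelengths of the synthetic scan — ≈410 and
≈590 nm — are properties of the placeholder visual system and skies, not
predictions for the goose), serial dependence between a bird's successive
choices beyond the random intercept, latency–choice correlation, or any
mechanistic habituation dynamics (exposure effects enter only through the
per-cell log-odds table). Green tests therefore establish correctness and
calibration of the *procedures* — not that real geese behave like the
generator.

## Problem sizes and runtime

The test suite uses the study-sized dataset (19×8) for pipeline tests,
40 birds × 100 replicates for ladder power/null calibration, 200
replicates for side-bias CI coverage, and 30 replicates for variance-ratio
recovery; the acceptance script runs the full 201-LED scan and one
study-sized analysis with a 1000-refit latency bootstrap. Everything
completes in a few minutes on one CPU.

## Known limitations

- Only the chromatic (single-cone opponent) channel is modelled; the
  achromatic double-cone channel, visual acuity and detection distance are
  out of scope.
- Random-intercept-only mixed models; random slopes and crossed or nested
  random structures are not supported.
- The binomial repeatability rests on the latent-scale π²/3 convention and
  is hard to resolve from 8 binary trials per bird; treat small estimated
  values as "not distinguishable from zero" rather than precise ratios.
- Satterthwaite (not Kenward–Roger) denominator df; for richer covariance
  structures the two can diverge, though not materially for this design.
- Type-III-style term tests assume sum-to-zero coding; interpreting main
  effects in the presence of retained interactions carries the usual
  caveats.
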