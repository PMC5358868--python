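# Methods

## Measurement model

A droplet digital PCR well partitions a 20 µL reaction into R ≈ 20,000
droplets of volume v (default 0.85 nL, the QX200 convention). Target
copies distribute at random, so the per-droplet copy count is Poisson
with mean λ and the probability a droplet is positive is 1 − e^(−λ).
From P observed positive droplets the maximum-likelihood estimate is
λ̂ = −ln(1 − P/R), implemented with `log1p` for accuracy at trace
occupancies. Concentration in copies/µL is λ̂/v times any configured
dilution factor. The estimate requires P < R; a saturated well raises a
dedicated error (the remedy is dilution, not arithmetic). Wells with
fewer than 10,000 accepted droplets are flagged in logs but not
rejected — there is no universally agreed QC cutoff, and discarding
wells silently would bias trace-level studies.

The droplet volume matters only for the absolute copies/µL scale. Every
mass-fraction computation uses copy *ratios* between two targets of the
same well set and is volume-invariant, which is why absolute
concentrations are never part of the validation targets.

**Uncertainty.** The CI on λ uses the delta method: Var(p̂) = p(1−p)/R
and dλ/dp = 1/(1−p) give SE(λ̂) = √(p̂/((1−p̂)R)). At P = 0 the lower
bound is exactly 0 and the upper bound is the exact one-sided binomial
bound, the largest p with (1−p)^R ≥ 1 − level. At p̂ = ½ with
R = 20,000, SE(λ̂) = √(1/20000) ≈ 0.00707; a parametric bootstrap in
the test suite confirms this and the Monte-Carlo coverage of the 95%
interval at λ = 0.5 sits within [0.93, 0.97]. The delta interval is
adequate in the occupancy range of practical assays; it degrades near
saturation, where the point estimate itself should not be trusted.

**Pooling.** Replicate wells may be merged by summing positives and
totals before inversion (the merged-well estimate). For small λ this
equals the totals-weighted average of per-well estimates to within 1%;
merged wells carry a sentinel replicate index of −1.

## Multiplication-factor calibration

Copies per unit mass differ by species (cell density, genome size,
extraction behaviour), so the copy ratio Qc/Qs of adulterant to base
species is not the mass ratio. With C the copies-per-unit-mass constant
of each species under a fixed extraction protocol, M = Q/C and

    Mc/Ms = (Cs/Cc)·(Qc/Qs) = k·(Qc/Qs).

k is calibrated from an equal-mass 50/50 w/w reference: Mc/Ms = 1
forces k = Qs/Qc per replicate. The pooled k is the arithmetic mean of
the per-replicate ratios — not the ratio of means — with the sample
(n−1) RSD as its spread; the mean-of-ratios convention reproduces the
3.1% RSD of the bundled six-parallel reference, the ratio-of-means does
not define a replicate spread at all. k is reported to one decimal
(0.8) but full precision propagates internally. For chicken in sheep,
the bundled known-mixture series (10–80% w/w) implies k between 0.74
and 0.83, consistent with a single constant across mixture ratios; the
1% row of that series is internally inconsistent in the source records
and is excluded from validation.

The fraction is 100·kQc/Qs / (1 + kQc/Qs), strictly increasing in both
the copy ratio and k. Bias is reported as 100·(measured − true)/true.

## qPCR comparator

Standard curves are fitted by OLS of mean Ct per dilution level on
log10 declared copies (fitting raw replicates is an option); a fit
needs ≥ 3 distinct levels and a negative slope, otherwise it is
rejected as invalid. Efficiency is 100·(10^(−1/slope) − 1), monotone in
the slope toward 100% at −1/log10 2 ≈ −3.3219. Log base 10 is used
throughout. Unknown Ct values invert to copies via
10^((Ct − intercept)/slope), with extrapolation beyond the fitted range
permitted but flaggable. The qPCR fraction is the copy share
100·Cc/(Cc+Cs), scale-invariant in the pair.

The equal-mass standard is declared at a virtual common concentration
(10^5) for both species. In expectation this convention cancels k
exactly: interpolated copies are actual copies rescaled by the
species-specific 50/50 reference concentration. The large negative
biases seen in wet-lab qPCR data therefore reflect
amplification-efficiency and matrix discrepancies between standards and
unknowns, which the simulator exposes as optional per-species Ct
offsets on unknowns (default 0).

## Validation rules

* RSD: sample (n−1) SD over mean, in percent. Chosen because it
  reproduces the bundled reference summaries (3.1% calibration RSD,
  3.18% operator-B repeatability); the population SD does not.
* Linearity: OLS of mean measured fraction on true fraction across
  ≥ 3 levels; r² reported to 4 decimals.
* LOQ: levels are scanned from the largest fraction downward; the LOQ
  is the smallest level of the unbroken run passing RSD ≤ 25% and
  |bias| ≤ 25% (FAO-style limits; the bias gate can be disabled for an
  RSD-only rule). Requiring contiguity means an isolated passing level
  below a failure cannot define the LOQ.
* LOD: smallest level (again contiguous from the top) at which every
  replicate well shows ≥ 3 positive droplets. The qualitative notion of
  "stably seen positives" is operationalised as a configurable
  min-positives threshold; 3 is a common guard against isolated
  false-positive droplets.

Report display rounds fractions, RSD and bias to 2 decimals, k to 1,
r² to 4; computation is never rounded.

## Synthetic-data generator

The generator emulates the statistical structure of the instrument, not
its physics. For a scenario with adulterant mass fraction f:

* expected concentrations are conc_c ∝ f·Cc·retention_c and
  conc_s ∝ (1−f)·k·Cc·retention_s, with Cc defaulting to 1000
  copies/µL per unit mass fraction so that simulated wells land on a
  realistic scale (hundreds of copies/µL at tens of percent, ~10 at 1%,
  ~1 at 0.1%);
* occupancy is sampled as Binomial(R, 1 − e^(−λ)) — equivalent in
  distribution to explicit molecule placement and much faster;
* per-well pipetting noise is multiplicative Gaussian with CV 2%
  (replicate-level variability beyond partition sampling is not
  documented for such assays; 2% is a typical liquid-handling CV),
  applied independently per well since each target runs in its own
  well; false-positive/negative rates act per droplet;
* differential degradation under harsh processing (heat above 100 °C,
  pressure treatments) is abstracted as per-species retention factors
  in (0, 1]; equal retentions cancel in every ratio, unequal retentions
  shift the measured mass ratio by exactly retention_c/retention_s —
  at f = 50% and retention_c = 0.7 the recovered fraction is
  100·0.7/1.7 ≈ 41.2%, and simulation matches this closed form. No
  kinetic temperature/time model is attempted;
* matched qPCR tables use configurable per-species standard curves
  (defaults: the bundled reference coefficients), six 4-fold dilutions
  of the virtual-10^5 equal-mass standard in triplicate, and additive
  Gaussian Ct noise (SD 0.15 cycles, a typical instrument-level
  spread).

All randomness flows from one integer seed; seeded runs are
bit-reproducible. What the generator does **not** model — droplet-size
dispersion, "rain" (intermediate fluorescence clusters), gating errors,
inter-well contamination, extraction chemistry — means that passing
tests demonstrate correctness of the statistical pipeline under its
stated assumptions, not robustness to every instrument artefact.

## Problem sizes and stochastic checks

Simulation-based checks run at the study's own scale: 20,000 droplets
per well, 3 quantification replicates per level, 6 calibration
parallels, 1000 wells for estimator-bias checks, 2000 for CI coverage,
200 runs for the LOD detection rate. The end-to-end recovery metric
(mean |bias| of recovered 5–80% fractions) is intrinsically noisy for a
single 3-replicate study — partition sampling alone gives it a spread
comparable to its ~0.9% expectation — so it is measured as an average
over 30 independent simulated studies at unchanged conditions. The full
test suite completes in a few seconds on one CPU.

## Known limitations

* Two-species binary mixtures only; simultaneous deconvolution of ≥ 3
  species is out of scope.
* k is protocol-specific: it must be recalibrated for a different
  extraction procedure or heavily processed matrices (differential DNA
  degradation changes Cs/Cc — the retention-factor simulations show the
  direction and size of the resulting bias).
* Absolute copies/µL depend on the configured droplet volume and
  dilution factors; only ratios are validated.
* The delta-method CI is per-well; it does not include between-
  replicate extraction variability, which the replicate RSD captures
  instead.
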