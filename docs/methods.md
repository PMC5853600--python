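# Methods

## Response models

Light-response data are modelled as saturating functions of actinic
intensity *I* (µmol photons m⁻² s⁻¹):

* **PSII operating efficiency.**  The efficiency form
  φ_II = φ_m (I_k/I)(1 − e^(−I/I_k)) and the electron-transport form
  φ_II = ETR_max/(a_II·I)(1 − e^(−I/I_k)) are algebraically identical when
  ETR_max = a_II·φ_m·I_k; the package implements both and property-tests
  the identity to 1e-12 relative error.  The electron-transport form is
  undefined at I = 0 (the 1/I prefactor), so the module exposes the
  efficiency form for that limit, where the removable singularity
  evaluates to φ_m.  In practice the measurement grid starts at
  22 µmol photons m⁻² s⁻¹ so the limit only matters for plotting.
* **Total electron flow.**  TEF = TEF_max(1 − e^(−I/I_k)), the same
  saturation directly in rate units (ETR ≈ TEF assumed).
* **NPQ.**  A Hill dose-response.  The symmetric form
  NPQ_max·Iⁿ/(I₅₀ⁿ + Iⁿ), which satisfies NPQ(I₅₀) = NPQ_max/2 for every
  Hill coefficient n, is the default.  A dimensionally asymmetric variant
  with an un-exponentiated I in the denominator is available behind the
  explicit flag `literal_printed_form=True` so the two conventions can be
  compared; it is never selected silently.

The absorption constant a_II = absorbance × PSII fraction = 0.84 × 0.5 =
0.42 is an assumption, not a measurement, and is overridable everywhere it
appears (`a_ii=` keyword / `AbsorptionConstant`).

## Likelihood, priors, sampling

Observations within a treatment are independent normal around the
deterministic curve with one noise SD σ per treatment, estimated jointly as
a nuisance parameter.  Replicates are pooled as independent observations
rather than averaged, which matches that likelihood.  All parameters —
including σ and the NPQ Hill coefficient n — are sampled on the log scale,
enforcing positivity, with flat improper priors there; the log posterior
therefore equals the log likelihood, and the posterior mode coincides with
the maximum-likelihood estimate (checked against an independent optimizer
and a lattice search).

The sampler is random-walk Metropolis with diagonal Gaussian proposals.
During burn-in the step size adapts every 100 iterations toward ~30%
acceptance and is then frozen, so retained draws come from a fixed kernel.
Failed model evaluations return −∞ log-density (proposal rejected) rather
than raising mid-chain.  A chain that never accepts after burn-in is a hard
error; an acceptance rate outside [0.05, 0.7] emits a tuning warning.
Initial values are heuristic (saturation level from the largest observed
response, half-saturation from the median intensity, σ from the residual SD
of that start); convergence checks make the choice non-critical.
Everything is a pure function of (data, config): the same seed reproduces a
chain bit for bit.

Default draw counts are desk-scale — 50,000 samples after 2,000 burn-in —
with the protocol-scale 1,000,000/20,000 available through `FitConfig`.
Adequacy at desk scale is guarded by effective-sample-size and
rank-normalised split-R̂ diagnostics (via arviz; threshold 1.05), computed
across ≥2 chains started from dispersed points — a quantitative stand-in
for visual trace inspection.

## Posterior summaries

* **Credible bands**: 10,000 with-replacement draws from the joint
  posterior, curve evaluated per draw, per-intensity equal-tailed 2.5/97.5
  percentiles; φ_II chains are reported in ETR units, where the conversion
  ETR = φ_II·I·a_II cancels to ETR_max(1 − e^(−I/I_k)).  Quantiles use
  linear interpolation between order statistics, so outputs are bit-stable
  for a fixed seed.
* **Difference tests**: Δ = θ_A − θ_B from 100,000 independently paired
  with-replacement draws (the two treatments are fitted independently, so
  index-aligned pairing would be arbitrary).  Reported: P(Δ ≤ 0), the
  equal-tailed 95% interval, and a significance flag.  The one-sided rule
  "P(Δ ≤ 0) < 0.025 is significant" is symmetrised with P > 0.975 for
  differences in the opposite direction.  Equal-tailed (not
  highest-density) intervals are used throughout.

## Synthetic study design

The generator emulates the study layout: 2 genotypes (WT and a
pyrenoid-less mutant) × light acclimation (LL 10 / SL 50, with HL 100
supported by the types) × CO₂ (air / 5%), 6 biological replicates for
colony-fluorescence φ_II and 3 for spectroscopic TEF and NPQ, measured at
the eight actinic steps 22, 46, 106, 170, 251, 356, 509, 679
µmol photons m⁻² s⁻¹, with independent homoscedastic normal noise around
the true curve.  φ_II draws are reject-redrawn into [0, 1] (a proportion);
a scenario whose mean lies outside [0, 1] by more than 5σ is rejected as
inconsistent.  TEF and NPQ noise is left unclipped to match the plain
normal likelihood, so slightly negative NPQ draws can occur at the lowest
intensity.

True parameter values are synthetic defaults, not measurements: WT SL/air
ETR_max = 30, I_k = 150, with the genotype ETR_max contrasts set to 12
(SL/air), 4 (LL/air) and exactly 0 under 5% CO₂ — a built-in null.  The
φ_II noise SD of 0.02 was calibrated once so simulated standard errors
resemble colony-fluorescence error-bar scale.  What the generator does not
emulate: replicate-level variance heterogeneity across intensities,
between-replicate random effects, instrument drift, or any raw-fluorescence
signal processing — so passing tests demonstrate correctness of the
statistical machinery under its own assumptions, not robustness to real
data's departures from them.

## Replicated studies (`lightresponse.experiments`)

* **Null calibration**: paired identical-truth datasets, independent fits,
  difference test; across 20 experiments the mean P(Δ ≤ 0) should sit at
  0.5 ± 0.1.  Run by `scripts/acceptance.py`.
* **Parameter recovery**: 50 datasets per arm at 20,000 draws each;
  posterior-mean bias of ETR_max below 5% of truth and 95%-interval
  coverage within [0.90, 0.99].  Two representative arms (WT SL/air,
  mutant LL/air) are exercised; the study sizes were chosen to keep the
  whole suite comfortably runnable on a single CPU.
* **Contrast structure**: 20 end-to-end runs of simulate → fit → compare;
  the SL/air genotype comparison should be flagged significant, and each
  CO₂-saturated comparison non-significant, in ≥90% of runs.

## Numerical choices and limitations

* `expm1` is used for 1 − e^(−x) to avoid cancellation at small x.
* Per-experiment seeds are spawned from one base seed as integers < 2³¹.
* Report CSVs are read back with round-trip float parsing so a report
  equals its own re-read.
* Treatments are fitted fully independently — no hierarchical pooling, no
  multiple-comparison correction across the comparison list, no
  photoinhibition decline term in the saturation models, and no model
  selection; these are out of scope by design.
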