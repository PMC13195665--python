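# Methods

## The measurement being modeled

Theta-emitter native mass spectrometry initiates a bimolecular reaction
by mixing the contents of two capillary channels at the electrospray
Taylor cone, seconds before the droplets are ionized and the intact
complexes weighed. Each spectrum is therefore a snapshot of a reaction
at some unknown age ("droplet lifetime" or mixing time). Two devices
make the data interpretable:

* **An internal timer.** A nanobody–epitope pair with independently
  measured rate constants is present in the same droplets (either the
  epitope is genetically fused to the analyte protein — *fusion* mode —
  or added as a separate protein — *nonfusion* mode). Because the
  timer's occupancy follows a known binding curve, the observed timer
  bound fraction of a spectrum can be inverted into that spectrum's
  mixing time.
* **A mixing factor α per burst.** Spectra arrive in *bursts* (trains
  acquired during one ESI-voltage on/off cycle). The two channels do not
  necessarily contribute equally to the mixed droplet; α is the protein
  channel's volume fraction, so post-mixing initial concentrations are
  P₀ = α·P_total and L₀ = (1−α)·L_total. Ideal 1:1 mixing is α = 0.5.
  α varies between bursts (emitter asymmetry, uneven flow) and is
  estimated per burst.

## Kinetic model

1:1 reversible association,

    d[PL]/dt = k_on [P][L] − k_off [PL],   K_D = k_off / k_on,

with mass balance [P] = P₀ − [PL], [L] = L₀ − [PL]. Starting from zero
complex this Riccati equation has the closed form

    C(t) = r₁ r₂ (1 − E) / (r₂ − r₁ E),   E = e^(−k_on (r₂ − r₁) t),

where r₁ ≤ r₂ are the roots of C² − (P₀+L₀+K_D)C + P₀L₀ (computed in
the cancellation-free product form r₁ = P₀L₀/r₂). The closed form is
the default evaluation path inside fitting; an adaptive ODE route
(LSODA, state normalized to bound fraction, rtol 1e-10 / atol 1e-14)
is retained as an independent numerical path and for future multi-site
extensions — the two agree to better than 1e-6 relative (verified over
randomized systems). k_off = 0 encodes irreversible (covalent) binding;
the degenerate equal-concentration irreversible branch switches to
C = P₀²k_on t/(1 + P₀k_on t) at |P₀−L₀| < 1e-9 relative, avoiding
catastrophic cancellation. All concentrations are molar; files carry no
units and no unit inference is attempted.

## Timer calibration

`build_curve(timer, α)` evaluates the timer's bound-fraction curve
f(t) = C(t)/P₀ under α-scaled initial concentrations.
`invert_time` maps an observed timer fraction back to a mixing time
using the exact logarithmic inverse of the closed form (the curve is
strictly increasing, so the inverse is unique); a bracketed Brent
solver is kept as a cross-checked alternative path, and the tests
verify both against bisection on a fixed-step RK4 integration. The
analytic inverse was chosen over root finding because the global fit
re-inverts every spectrum's time whenever a trial α changes the
calibration curve, making inversion the hot path.

Spectra whose timer fraction is within ε = 1% of the curve's plateau
are *equilibrated*: any sufficiently long time explains them, so they
are dropped (with a log message) rather than assigned a capped time,
which would bias fits. The drop decision is made once per fit against
the α = 0.5 reference curve so the least-squares objective keeps a
fixed dimension; during optimization, a trial α whose plateau falls
below an observed fraction clamps the inversion just under the plateau.
`sensitivity_window` reports the times at which the curve passes 5% and
95% of its plateau — outside that window small fraction errors become
large time errors.

## Global fit

The fitted observable is the analyte bound fraction (dimensionless),
not a concentration: fractions are invariant to total-signal scale and
response-factor-corrected upstream. The objective is

    min over (k_on, k_off, α₁..α_B)  Σ_spectra ( f_obs − f_model(t(α_b); k_on, k_off, α_b) )²

with t(α_b) recomputed from the spectrum's timer fraction through the
α_b-dependent calibration curve on every objective evaluation. Models:
`shared_alpha` (one α per emitter), `per_burst_alpha` (one per burst),
and the irreversible variant of either (k_off ≡ 0). Rate constants are
optimized in log₁₀ space within k_on ∈ [10², 10¹⁰] M⁻¹s⁻¹,
k_off ∈ [10⁻⁶, 10³] s⁻¹, α ∈ [0.05, 0.95], by bounded trust-region
least squares from a deterministic 3×2 grid of starts
(k_on ∈ {10⁴, 10⁵, 10⁶}, k_off ∈ {10⁻³, 10⁻¹}, α = 0.5), keeping the
lowest-RSS solution — multistart without nondeterminism. Per-fit
standard errors come from the Jacobian at the optimum (delta method for
the log-parameterized rates); headline uncertainties are the mean ±
sample SD across emitter replicates, with K_D computed per replicate as
that replicate's k_off/k_on before averaging.

Model comparison uses the classical extra-sum-of-squares F-test,
F = ((RSS_r − RSS_f)/(p_f − p_r)) / (RSS_f/(n − p_f)), with the
per-burst model adopted when p < 0.05. Burst-level quality control
flags bursts whose RMS residual exceeds 3× the pooled RMS of the
*other* bursts (leave-one-out pooling: with B equal bursts the ratio
against all-burst pooling is bounded by √B, so a threshold of 3 could
never fire in a 5-burst dataset, and a corrupted burst would inflate
its own baseline). Flags are advisory; refitting after exclusion is an
explicit user action.

## Synthetic data

`simulate_dataset` is the forward model of the measurement: per burst,
an α (fixed, listed, or drawn uniformly from a range, default
[0.4, 0.6]); per spectrum, a latent time drawn log-uniformly from
[0.1, 40] s (the observed span of droplet lifetimes; an alternative
deterministic per-scan exponential-decay schedule mimics the drift from
long, partially premixed times at ESI onset toward short times late in
a burst); timer and analyte bound fractions evaluated at that time and
perturbed by independent additive Gaussian noise (σ = 0.02 by default,
overridable per margin) truncated to [0, plateau]; abundances emitted
as fractions scaled to a nominal total intensity (in fusion mode as the
product-form 2×2 contingency of the two occupancies). Ground truth
(latent times, per-burst α, rates) is written to a sidecar table.
Everything is reproducible bit-for-bit from the seed.

What the generator does *not* emulate: counting statistics and
intensity-dependent noise, charge-state structure and deconvolution
artifacts, response-factor drift, within-burst correlation of mixing
times, and any mechanistic model of premixing. Passing recovery tests
therefore demonstrate correctness of the inference given the declared
noise model, not robustness to instrument systematics.

### Default regimes

* Reversible benchmark: analyte k_on = 1.3×10⁵ M⁻¹s⁻¹,
  k_off = 1.3×10⁻² s⁻¹ (K_D = 100 nM), channel totals 0.8 µM protein /
  2 µM nanobody; timer 1 µM epitope / 2 µM nanobody with
  k_on = 3.6×10⁵, k_off = 9.4×10⁻⁶ (a near-irreversible tag–nanobody
  pair); 5 bursts × 15 spectra.
* Irreversible benchmark: k_on = 8×10⁵ M⁻¹s⁻¹, channel totals 4 µM /
  4 µM, chosen so the covalent step's post-mixing half-time (~0.6 s)
  sits inside the timer-resolvable window.

## Validation studies and their problem sizes

`thetakinetics.validation` computes every quantity the package claims:
six published (k_on, k_off, K_D) triples reproduced by Eq.-level
consistency; ODE-vs-closed-form agreement over 200 random systems;
calibration round-trip exactness at α ∈ {0.3, 0.5, 0.7}; reversible
recovery over 50 seeded emitters; irreversible recovery over 20; F-test
null calibration over 200 datasets. The F-test null study generates
data under the test's own assumptions — shared α, exact times,
untruncated iid Gaussian noise on the fitted observable (latent times
restricted to [1, 15] s so fractions stay several σ away from 0 and the
plateau) — because a type-I-error calibration is a statement about the
test, and is only defined where the null model actually holds.

## Known limitations

* **k_off and α are weakly identified at saturating compositions.**
  With ligand far above K_D the analyte curve over the timer-resolvable
  window is nearly indistinguishable from an irreversible fit with a
  slightly different α (α reshapes both the apparent plateau and the
  time axis). A Cramér–Rao analysis at the reversible benchmark regime
  gives 1σ ≈ 15% on k_off and up to ≈ 0.16 on individual burst α at
  σ = 0.02 even with exact times; measured Monte-Carlo scatter matches.
  Single-emitter k_off values at such regimes should be read with their
  reported uncertainties, and replicate averaging is essential. k_on is
  robust (1σ of a few percent).
* **Timer noise is an errors-in-variables problem.** Observed timer
  fractions are inverted directly into times, so timer noise becomes
  (heteroscedastic) regressor noise. Near the timer plateau the
  amplification is unbounded — the equilibrated-spectrum drop rule
  caps, but does not remove, the effect. One consequence: under the
  full two-margin noise model the nested F-test over-rejects a true
  shared-α null (measured ~0.4 at nominal 0.05), because the per-burst
  model partially absorbs burst-specific time-noise patterns. The
  F-test verdict on real data should be read as a model-selection
  heuristic, exactly calibrated only when its assumptions hold.
* **Fraction truncation bias.** Clipping noisy fractions to
  [0, plateau] is physical but makes noise one-sided within ~2σ of the
  edges, biasing late-time fractions slightly downward.
* Response-factor correction assumes a single multiplicative factor for
  the bound species per margin; per-charge-state factors are not
  identifiable from a bulk mixing titration.
* Multi-site/cooperative binding, two-step covalent mechanisms and
  droplet reaction-acceleration are out of scope; the covalent fit
  estimates only the rate-limiting irreversible step because bound
  states of equal mass are indistinguishable in the spectrum.
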