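# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `spikefield`. Everything stated here is
computed by the package's tests or scripts; nothing is quoted from external
results.

## Point-process model

Each unit's spike train is binned at Δ = 1 ms and modeled as a Bernoulli
process with per-bin probability λ_tΔ, where ln λ_t = μ + A·X_t. The bin
width is small enough that double spikes per bin are negligible for cortical
rates (the generator warns if λ_tΔ exceeds 1 in more than 0.1% of bins).
The fitted objective is the per-sample-normalized penalized log-likelihood

    (1/T) Σ_t [ Y_t ln(λ_tΔ) − λ_tΔ ] − α ‖A‖²,

normalizing by T so that α has the same meaning regardless of session
length, and leaving μ unpenalized. The per-bin Poisson-style likelihood is
consistent for Bernoulli data with the same mean, so fits on simulated
Bernoulli spikes are unbiased. All covariates are z-scored before fitting
(the penalty then treats features symmetrically); the z statistics always
come from training data and travel with the model.

## Feature construction

**LFP.** Eight bands: δ 0.3–2, θ 2–7, α 7–15, β 15–30, γ₁ 30–60, γ₂ 60–100,
MUA₁ 100–200, MUA₂ 200–400 Hz. Each is extracted by a causal (forward-only)
Butterworth band-pass built from a 4th-order low-pass prototype
(`scipy.signal.butter(4, [lo, hi])`, eight poles, second-order sections).
The analytic signal is computed by the FFT Hilbert transform over the whole
recording block, all features are delayed by 1 ms, and narrow bands (≤30 Hz)
contribute amplitude, Re/Im, and the cos/sin of instantaneous phase — the
linear-predictor form of cosine phase tuning with preferred phase
θ₀ = atan2(w_sin, w_cos) and depth √(w_cos² + w_sin²). The first and last
2 s of each block are excluded from model fitting; they are dominated by
filter and Hilbert-transform edge transients.

Causality audit. The real path (band-pass) is exactly causal; the Hilbert
transform is not. `causality_audit` measures the percentage of the
composite imaginary-path impulse response's absolute area at negative lags,
with the impulse centred in a 2^17-sample window (tail mass < 1e-8). At
1 kS/s with the 1 ms delay the measured fractions are β 0.13%, α 0.19%,
θ 0.87%, δ 2.60%. The leakage scales with the band's period because the
Hilbert kernel decays only as 1/t, so the slow bands' quadrature component
unavoidably reaches seconds across the spike time; the 1 ms delay is
negligible relief at those timescales (50 ms of delay removes only ~0.6
percentage points for δ). Interpretation: phase/amplitude features of bands
at and above β are effectively spike-contamination-safe; δ- and θ-band
quadrature features retain a percent-level non-causal component that users
should weigh when predicting spikes from same-electrode LFP. Zero-phase
(forward-backward) filtering, provided for comparison, is ~50% non-causal.

**Kinematics.** Wrist x/y/z and grasp aperture at 240 frames/s are smoothed
and differentiated with a Savitzky–Golay kernel (5th-order polynomial,
halfwidth 25 samples), which attenuates content above ~20 Hz while passing
movement-band frequencies nearly ideally (≤2% derivative error at 1 Hz);
velocities are then subsampled to 40 S/s. A pathlet at model time t is the
velocity trajectory at 17 lags (−100…+300 ms every 25 ms), L2-normalized
separately for the wrist-3D group (51 values) and the aperture group (17),
plus mean speed (mean Euclidean wrist speed and mean |aperture velocity|
over the window) and zero-lag position: 74 columns. Trajectories with raw
norm below 1e-6 mm/s (numerical noise of the smoother) map to zero vectors:
no motion → no signal. Rows between 25 ms grid points hold the most recent
grid value rather than interpolating. Pathlets intentionally include future
kinematics; lag signs are encoded in the column labels, and only the
history features are causal by construction. An un-normalized
position-trajectory variant (68 columns) is provided for comparison.

**Spiking history.** Ten raised-cosine bumps, evenly spaced in
log(lag + 1 ms) with peaks from 2 to 80 ms (peak-normalized to 1; the
downstream z-scoring makes the scale immaterial), are convolved with the
unit's own past spikes over lags 1…100 ms. The current bin is strictly
excluded, verified by an add-a-spike invariance test.

## Fitting and evaluation

The objective is smooth and convex; with α > 0 (or full-rank design) the
minimizer is unique. The reference fitter is full-Hessian Newton with
Armijo backtracking in float64, converging on both relative objective
change (<1e-9) and gradient norm. Cross-validated model selection uses a
faster path solver that fits the entire 11-value α grid simultaneously with
preconditioned Newton sweeps: a single weighted-Gram Hessian approximation
(Cholesky-factored once per α, refreshed when progress stalls) gives each
sweep the cost of two thin matrix products. Convergence is declared on the
gradient (relative tolerance 1e-3 for inner selection fits, 1e-4 for the
refits that produce reported scores; 1e-8/1e-9 in float64), so the reached
optimum does not depend on the preconditioner. Design matrices inside the
CV machinery are float32 — the gradient noise floor of single-precision
accumulation (~1e-7 relative) is far below any PP-relevant effect — and a
λ ≤ 10⁴ spikes/s cap inside exp() keeps line searches finite (cap activity
at a solution is reported and treated as a failed fit).

Predictive power is 2·AUC−1 with AUC the area under the ROC convex hull,
computed exactly: ROC points over all score thresholds, upper convex hull
anchored at (0,0) and (1,1), trapezoidal integration. The hull construction
guarantees PP ∈ [0, 1]. On small held-out samples the hull estimator is
positively biased under the null (the hull of a noisy ROC lies above the
diagonal), which is precisely why chance levels are estimated by
permutation rather than assumed to be zero.

Two-tier cross-validation: 10 outer folds (contiguous time blocks by
default, to avoid optimistic leakage through autocorrelation; random-bin
folds available), each reserving 10% as test data. Within each training
set, a random half/half split fits the full α grid on each half and scores
it on the other (both directions averaged, ties going to the smaller α);
the best-generalizing α is refit on the whole training set and scored on
the held-out fold. Per-fold PPs and a pooled PP (one ROC over the
concatenated held-out scores; every bin is test data exactly once) are
reported. Inner-selection scoring keeps all spike bins but at most 20,000
sampled non-spike bins per validation half — the α comparison happens on a
common subsample, and outer/pooled PPs are always exact.

Chance level: covariates are shuffled in 100 ms contiguous chunks relative
to spiking (preserving autocorrelation, destroying alignment; a trailing
partial chunk participates), then one rotating 90/10 split is fit per
permutation at a fixed α (the median selected on the real data) and scored
on its test fold; the 95th percentile over ≥20 permutations is the
threshold. A full nested CV per permutation would multiply cost by ~50 for
no change in the null's meaning.

Redundancy is operationalized as ΔPP of nested models: per-unit
ΔPP = PP(extended) − PP(base), two-sided Wilcoxon signed-rank on the unit
population (zeros discarded; an all-zero difference vector reports p = 1),
Bonferroni-corrected across the comparisons or sessions tested.

`evaluate_population` evaluates several units and feature-set ladders in
one pass, sharing the fold layout, training-fold z statistics and the
gathered shared design across units; it is tested to agree with the
per-unit reference path.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes, from
fully specified ground truth; defaults describe a 600 s session (1 kS/s
LFP, 240 frames/s kinematics, 1 ms spikes).

* **Kinematics**: minimum-jerk point-to-point wrist reaches (0.5–0.9 s) to
  uniform targets in a 300 mm cube, starting at exponential intervals
  (default 0.4 reaches/s); the aperture opens from 20 mm to 60–90 mm over
  the first 70% of each reach and closes by 250 ms after it.
* **LFP**: per band, a unit-RMS band-pass-filtered Gaussian carrier times a
  rectified 0.5 Hz low-pass noise envelope, scaled to a per-band RMS
  (defaults 40 µV for δ down to 2 µV for MUA₂), plus 1/f-power background.
  Movement coupling with fraction c enters twice, both zero-phase on the
  generator side: the δ component is a √(1−c)/√c mixture with the δ-band
  (zero-phase) filtered wrist speed, and the MUA-band envelopes are
  (1−c)/c mixtures with the low-passed speed. Zero-phase injection is
  deliberate: the slow motor potential, multi-unit modulation and the
  kinematics are cotemporal effects of a common motor drive, and the
  *analysis* path stays strictly causal regardless. (With causal injection
  the generator's and analyzer's ~1 s δ-band group delays would compound
  and the LFP would spuriously decouple from movement.)
* **Spikes**: Bernoulli per bin from ln λ = μ + weights on the *same*
  z-scored LFP/pathlet columns the pipeline extracts, plus a raw-scale
  history filter whose contribution accumulates recursively from the
  emitted spikes (strongly negative at short lags for refractoriness,
  mildly positive near 5–15 ms for bursting).

Two canonical ground-truth families are provided. `recovery_truth` is a
single unit with δ-phase tuning (θ₀ = 2π/3, depth 0.3), a δ analytic-signal
weight, a negative β-amplitude weight, a high-band amplitude weight,
speed/velocity/position tuning and the refractory filter — used for
parameter-recovery validation. `population_truths` draws a speed-tuned
population (wrist-speed weight U(0.35, 0.7) per SD, a sprinkling of random
pathlet and position weights, jittered refractory/bursting history,
baseline rates 10–25 Hz) driven by kinematics and history but *not*
directly by the LFP; with coupling c = 1 the δ-LFP and MUA envelopes are
functions of wrist speed, so LFP features predict spiking exactly insofar
as movement does — redundancy holds by construction, which is what makes
the population a valid positive control for redundancy detection.

What the generator does **not** emulate: spike waveforms and sorting
artifacts, LFP spike contamination, electrode cross-talk, multi-electrode
spatial structure, non-movement covariates (attention, reward), torques or
muscle activity, and non-stationarities across blocks. Passing tests
therefore demonstrate that the *pipeline* recovers known structure and
detects known redundancy — not that real motor-cortex LFP is redundant; on
real data the conclusions also depend on the fidelity of these unmodeled
features.

## Study sizes used by the test suite

Chosen as the package's standing configuration for its validation studies:
parameter recovery uses one 600 s session (~596,000 usable bins, 116
features, α = 1e-6), asserting every weight within 3 estimated standard
errors of truth and θ₀ within 0.2 rad. The redundancy study uses two
sessions of 10 units at 300 s, coupling 1, with 20 block-shuffle
permutations per unit; it asserts that ≥90% of units have LFP-only PP above
chance, that the median ΔPP(kin→kin+lfp) is not significant, and that the
median ΔPP(kin→kin+hist) is significantly positive (Wilcoxon, Bonferroni
over the two sessions). The shuffled-LFP control asserts |ΔPP| < 0.03 when
100 ms block-shuffled LFP columns are appended to the kinematics model.

## Known limitations

* The δ/θ non-causal quadrature leakage described above is intrinsic to
  Hilbert-based phase features of slow bands with causal band-passes; no
  delay of practical size removes it.
* The Bernoulli thinning cap (λΔ ≤ 1) slightly deforms the intensity for
  pathological ground truths with extreme rates; the generator warns.
* Contiguous outer folds trade a little statistical efficiency for
  robustness to autocorrelation leakage; random-bin folds are available but
  optimistic for slow signals.
* The inner α selection scores on subsampled negatives (exact above); with
  pathologically few spikes per fold (<10) PP is unstable and a warning is
  raised.
* `chance_population` shares one shuffle sequence across units of a
  session, so per-unit thresholds are correlated across units; thresholds
  remain marginally valid per unit.
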