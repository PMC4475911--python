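# spikefield

How much of a motor-cortex neuron's millisecond-scale spiking variability is
explained by the local field potential (LFP), by the animal's reach-and-grasp
kinematics, and by the neuron's own recent spiking history — and how much of
that information is *redundant* between those signals?

`spikefield` is a Python package for answering this question with
point-process generalized linear models (GLMs). It is aimed at systems
neuroscientists who record spikes, LFP and motion capture simultaneously and
want a tested, reusable implementation of the full analysis chain:
spike-safe causal LFP feature extraction, kinematic trajectory features,
spike-history filters, penalized conditional-intensity fitting, ROC-based
scoring under nested cross-validation, permutation chance levels, and
nested-model redundancy comparisons. Because raw multielectrode datasets of
this kind are rarely shareable, the package also contains a first-class
synthetic-session generator with known ground truth, so every stage of the
pipeline is verifiable end to end.

## The model

Spiking is modeled as a binary point process in Δ = 1 ms bins. The
probability of a spike in bin *t* is λ_tΔ, with the conditional intensity
λ_t (spikes/s) log-linear in the covariates:

```
ln λ_t = μ + A · X_t
```

`X_t` may contain, in any combination:

* **LFP features** — each of eight bands (δ 0.3–2, θ 2–7, α 7–15, β 15–30,
  γ₁ 30–60, γ₂ 60–100, MUA₁ 100–200, MUA₂ 200–400 Hz) is extracted with a
  causal 4th-order Butterworth band-pass, turned into an analytic signal
  z(t) by the Hilbert transform, and delayed by 1 ms. Narrow bands (≤30 Hz)
  contribute |z|, Re z, Im z, cos Arg z, sin Arg z (the cos/sin pair realizes
  cosine tuning `a₄ cos(θ₀ − Arg z)` to a preferred phase θ₀); broad bands
  contribute |z|, Re z, Im z. Causal filtering confines any spike-waveform
  contamination to times *after* the spike.
* **Kinematic pathlets** — Savitzky–Golay smoothed/differentiated wrist
  (x, y, z) and grasp-aperture velocities, sampled every 25 ms from 100 ms
  before to 300 ms after the current bin, L2-normalized per channel group,
  plus mean speed and zero-lag position (74 columns).
* **Spiking history** — the unit's own spike train convolved with ten
  raised-cosine basis functions log-spaced over the preceding 100 ms
  (refractoriness, bursting, rhythmicity); strictly causal.

Fitting maximizes the per-sample L2-penalized log-likelihood
`(1/T) Σ_t [Y_t ln(λ_tΔ) − λ_tΔ] − α‖A‖²` (μ unpenalized, all features
z-scored). Predictive power is reported as **PP = 2·AUC − 1**, the
normalized area under the ROC *convex hull* for held-out 1 ms spike/no-spike
prediction: 0 is chance, 1 is perfect. The penalty α is selected per outer
fold by an inner random two-group split over the grid {0} ∪ 10^linspace(−9, 2, 10),
inside 10-fold outer cross-validation; chance levels come from re-fitting
after shuffling covariates in 100 ms blocks.

## Worked example

Generate a 120 s synthetic session with two speed-tuned units whose δ-band
LFP is fully driven by wrist speed (`coupling=1`), then score the four
feature-set ladders:

```python
import numpy as np
import spikefield as sf
from spikefield.evaluation import evaluate_population, chance_population

truths = sf.population_truths(seed=11, n_units=2, coupling=1.0)
session = sf.generate_session(truths, duration_s=120.0)
sb = sf.build_blocks(session)
cfg = sf.CVConfig(seed=0)
results = evaluate_population(sb.kin, sb.lfp, sb.hist, sb.Y, cfg,
                              ladders=("lfp", "kin", "kin+lfp", "kin+hist"))
thr, _ = chance_population([sb.lfp], sb.Y, cfg, 20,
    alphas=[max(np.median(r.selected_alphas), 1e-6) for r in results["lfp"]])
```

Output (pooled PP per unit and feature set):

```
unit      lfp    kin  kin+lfp  kin+hist  chance95
unit00  0.134  0.264    0.270     0.362     0.113
unit01  0.172  0.251    0.253     0.396     0.096
```

Read: LFP features alone predict spiking well above the block-shuffle
chance level (0.13–0.17 vs ≈0.1), but adding them to the kinematics model
barely moves PP (0.264→0.270) — the LFP's predictive information is
redundant with movement, exactly as constructed (`coupling=1` makes the
δ-LFP a function of wrist speed). Spiking history, in contrast, adds
~0.1–0.15 of genuinely new predictive power (0.264→0.362).

A command-line interface wraps the same pipeline:

```bash
spikefield simulate --units 4 --duration 120 --coupling 1.0 --out ses/
spikefield run manifest.json       # pp_by_unit.csv, comparisons.json, ...
spikefield audit                   # causal-filtering audit per band
```

`spikefield audit` prints the fraction of each band's composite impulse
response (band-pass → Hilbert → 1 ms delay, imaginary path) that lies at
negative lags:

```
band         range_hz  noncausal_%
delta      0.3-2.0          2.6034
theta      2.0-7.0          0.8675
alpha      7.0-15.0         0.1920
beta      15.0-30.0         0.1281
...
```

The leakage grows sharply toward slow bands — see `docs/methods.md` for why
and what it means for spike-contamination safety.

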