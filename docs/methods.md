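# Methods

This note documents the models, defaults and numerical choices behind
`ratiodecode`, in enough detail to judge what the package's results do and
do not demonstrate.

## The encoding

A message is one of ten codes: five E11-14:OAc / Z9-14:OAc volume ratios
(1:0, 2:1, 1:1, 1:2, 0:1) at a 1 uL (codes R1–R5) or 2 uL (R6–R10) total.
Component volumes are the ratio fraction of the total, truncated toward
zero at two decimals (so 2/3 of 1 uL is 0.66 uL), which keeps the code
table in round figures. `(ratio, volume level) <-> code` is a bijection.

## Sensor-array simulator

### Response model

The differential channel of a dual SAWR sensor responds to a blend with a
superposition of per-component first-order rises:

    f(t) = Σ_c  s_c · v_c · (1 − exp(−(t − t_inj)/(g·τ_c))),    t ≥ t_inj,

where `s_c` is the steady-state sensitivity to component `c` (Hz/uL),
`v_c` the injected volume, `τ_c` a per-component rise time, and
`g = 1 + κ·(v_total − 1)` a dose-dependent slowdown (a larger dose
evaporates for longer). Steady state is linear in volumes — consistent
with partition-coefficient sorption at low concentration — and is reached
roughly 600 s after injection at the default rise times. The sense channel
adds a common-mode drift; the uncoated reference carries the drift plus a
fraction `ref_coupling` of the response; differential = sense − reference.

Two modelling points deserve emphasis, because they are what makes
transient decoding possible at all in the simulation:

* **Per-component kinetics + dose slowdown.** If every blend rose with one
  shared τ, the transient shape would carry no category information and
  derivative/rise-time features would be pure noise. Giving each acetate
  its own τ per polymer (faster for E11-14:OAc) and slowing larger doses
  makes the early trace composition- and volume-dependent.
* **Injection-timing jitter.** Each injection's effective start time is
  drawn once per sample (SD 14 s, shared by the three sensors, clipped at
  ±3 SD). Early in the rise the trace is steep, so timing jitter corrupts
  instantaneous shift readings in proportion to the local slope — it is
  the dominant early error source for steady-state features — while the
  local *slope and log-decrement* are barely affected (they shift by
  e^(±jitter/τ) ≈ ±8%). At the plateau the jitter effect vanishes. This
  single mechanism reproduces the observed crossover: transient features
  decode best right after injection, steady-state features win later.

### Noise terms

Per profile and channel: multiplicative Gaussian noise (`noise_rel`,
i.i.d. per timestamp, proportional to the clean response), an additive
i.i.d. floor (`floor_sd_hz`, dominant pre-injection), and one Gaussian
baseline offset per profile (`baseline_sd_hz`, the residual of imperfect
common-mode rejection — this is why pre-injection deviation statistics
look "random and widely distributed"). All terms are driven by one seed
per design; repeats of a category differ only in their noise realisation.

### Default parameters

| sensor | s_a, s_b (Hz/uL) | τ_a, τ_b (s) | noise_rel | baseline (Hz) | floor (Hz) |
|--------|------------------|--------------|-----------|---------------|------------|
| PE     | 700, 170         | 95, 170      | 0.030     | 7             | 2.0        |
| PSB    | 430, 520         | 130, 215     | 0.015     | 5             | 1.5        |
| PEVA   | 180, 720         | 170, 260     | 0.015     | 5             | 1.5        |

Dose slowdown κ = 0.3 for all sensors; drift 0.04–0.05 Hz/s; reference
coupling 0.12–0.15; injection at 100 s; 1 s sampling; 1050 s recordings;
6 repeats per low-volume code and 3 per high-volume code (45 samples per
sensor, 135 profiles). Absolute shift scales are an order-of-magnitude
choice (hundreds of Hz per uL); only ratios of scales matter downstream.
The three sensitivity vectors point in distinct directions (PE prefers
E11-14:OAc, PEVA the opposite, PSB balanced): that contrast is the
selectivity that makes ratios decodable. PE carries the largest relative
noise, reflecting its poorer steady-state repeatability.

These defaults were calibrated once against the target statistics for the
emulated system — per-category steady-state relative deviation below 10%
and mean inter-sensor correlations in the high 0.9s (0.96–0.99 at the
defaults) — and then frozen.

### What the simulator does *not* model

No SAW acoustics, oscillator electronics, polymer-film viscoelasticity,
evaporator kinetics or plume fluid dynamics; transport is folded into the
effective rise times. Noise is Gaussian and stationary — no spikes, no 1/f
wander, no sensor poisoning or long-term drift of sensitivity. Passing
tests therefore show that the *decoding pipeline* behaves correctly on
data with the documented statistical structure, not that any particular
hardware meets these numbers.

## Feature extraction

All ten features are computed at a single time station from the
differential traces (configurable to the sense channel). Numerical
guards, chosen so the feature matrix is always finite and rectangular:

* divisions and logs clip their argument at `eps = 1e-6 · max|f|` of the
  profile (a relative floor; absolute override available);
* `Zscore` returns 0 where the across-sample SD is 0; `AS` returns 0 for
  all-zero rows;
* derivatives use a moving average over `smoothing_window = 21` samples
  followed by a central difference (one-sided at the recording edges);
  the window is a package choice — 1 s raw differences are noise-dominated;
* τ₁ is fitted as −1/slope of ln(f̂_inf − f) by local least squares over
  the smoothing window, τ₂ as f̂_inf over the local least-squares slope;
  both windows are truncated at the injection instant so baseline samples
  never enter a post-injection fit, and both estimates are capped at
  2000 s (≈ 2 recordings) — without the cap, a noise-flattened derivative
  clipped at `eps` produces ~10^6-scale outliers that wreck any classifier
  sensitive to feature scale;
* the stationary value f̂_inf is estimated per profile, by default from
  the mean of the final smoothing window (offline mode); the online mode
  uses the running maximum of the smoothed trace, for streaming use.

## Decoders

**LDA.** Pooled within-class covariance ridged by `1e-6 · trace/dim` for
invertibility when (combined, expanded) feature dimension approaches the
sample count; up to c−1 generalised eigendirections; nearest class mean in
discriminant space; ties go to the lowest code index, as everywhere.

**PNN.** The scalar kernel bandwidth is generalised to one bandwidth per
feature, estimated as the median per-coordinate gap of within-class
nearest-neighbour pairs (neighbours by full Euclidean distance): features
with wildly different scales then need no prior normalisation. Three modes
are offered — pooled per-feature (default), per-class per-feature, and a
single scalar. The pooled default is deliberate: with 2–5 repeats per
class, per-class medians occasionally collapse to a near-zero coordinate
gap, giving the true class a needle-thin kernel that loses to a broader
neighbouring class; pooling across classes removes those intermittent
errors. Zero/undefined medians fall back to the global per-feature median,
then the feature SD, then 1.0. Densities are evaluated in log space with
log-sum-exp, so underflow is effectively impossible; a nearest-template
fallback guards the remaining pathological case. As the bandwidth scale
tends to 0 the classifier approaches 1-nearest-neighbour; as it grows, the
class probabilities flatten.

**MLPNN.** 10 sigmoid hidden units, 2 linear outputs regressing the
component concentrations, decoded to the nearest of the ten target pairs.
Full-batch gradient descent with momentum (lr 0.01, momentum 0.9, epoch
cap 2000, early-stopping patience 200 on the best MSE), deterministic for
a given seed and invariant to training-row order. Inputs are standardised
inside the model (the affine map is part of the fitted state) — Hz-scale
inputs would otherwise saturate the sigmoid layer at initialisation.
Regressing 2 concentrations instead of 10 one-hot outputs keeps the
network small; hidden size, epochs and rates are configurable.

## Evaluation protocols

Leave-one-out is exhaustive and deterministic (every sample is the test
case exactly once) rather than a randomly repeated draw — identical in
expectation, reproducible in fact. Station sweeps default to a 50 s grid.
Sequential forward selection greedily adds the pool feature that most
improves the LOO rate (pool order breaks ties) and stops at the first
non-improving round; the selection is re-run independently at every
station. Neighbour expansion appends, for every sample, the feature vector
extracted one acquisition interval earlier (offset configurable), doubling
45 rows to 90. In expanded LOO the held-out row's temporal twin is also
removed from the training fold by default: the twin is a near-duplicate of
the test point, and training on it trivially inflates rates. The unguarded
mode is available for comparison.

The streaming decoder retrains a PNN on the raw shifts of the reference
profiles at every time step (1 s by default; leave-one-out over profiles
unless an explicit test split is given) and emits code 0 for a profile
until its baseline-corrected shift exceeds 5× the pre-injection noise SD
(estimated from the first 50 s). Decoded codes early in the transient jump
between response-adjacent categories before locking in; the recognition
ratio reaches 100% while the mean sensor response is still far from its
peak.

## Problem sizes

The default study is deliberately desk-scale: 45 samples × 3 sensors ×
1051 time points. The test suite evaluates station sweeps on a 50 s grid,
MLPNN leave-one-out runs at a 400-epoch cap, and the streaming decoder at
a 5 s step; `scripts/acceptance.py` uses the same sizes. All were chosen
as the smallest sizes at which the qualitative patterns are stable across
seeds.

## Known limitations

* Recognition rates on synthetic data are not comparable number-for-number
  with any physical system; only the qualitative structure (ordering of
  feature families over time, benefit of expansion, decode-before-peak) is
  meaningful.
* The jitter/baseline/kinetics parameters are a calibrated, not measured,
  noise budget; real SAWR arrays add drift and memory effects the
  simulator omits.
* τ₂ is a small-t approximation by construction and is reported as a
  feature, not as an unbiased τ estimate.
* The MLPNN is a fixed-architecture baseline; no regularisation or
  architecture search is attempted.
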