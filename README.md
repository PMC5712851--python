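# ratiodecode

Simulation and decoding of **ratiometric chemical blend codes** sensed by a
polymer-coated SAW-resonator (SAWR) array — an end-to-end model of a
biomimetic infochemical communication link.

Moths such as *Spodoptera littoralis* communicate by the **ratio** of
pheromone blend components, not by unique molecules. An artificial analogue
encodes a message as one of ten codes `R1..R10`: five volume ratios of
E11-14:OAc to Z9-14:OAc (1:0, 2:1, 1:1, 1:2, 0:1) at two total-volume
levels (1 uL and 2 uL). A chemoreceiver of three SAWR sensors coated with
polyethylene (PE), polystyrene-co-butadiene (PSB) and
polyethylene-co-vinyl-acetate (PEVA) reads the blend as three correlated
frequency-shift time series; the decoding problem is to recover the code
from those traces, as early as possible.

This package is aimed at researchers in machine olfaction and chemosensory
signal processing who want a fully reproducible, desk-scale testbed for
blend-ratio decoders: every stage from raw sensor physics to streaming
classification is simulated, feature-extracted, and scored.

## Model and methods

**Sensor response.** Each sensor's differential frequency shift follows a
first-order sorption rise after injection at time t_inj:

    f(t) = f_inf · (1 − exp(−(t − t_inj)/τ)),
    f_inf = s_a·v_a + s_b·v_b,

with per-component sensitivities s_a, s_b (Hz/uL), injected volumes v_a,
v_b (uL) and rise time τ (s). Each component carries its own τ and larger
doses rise more slowly, so the transient shape — not just the plateau —
encodes the blend. Noise comprises multiplicative (relative) noise, an
additive floor, a per-profile baseline offset, and per-injection timing
jitter shared by the array.

**Features.** At a time station t, ten features are derived from f_ij(t)
(sample i, sensor j): the raw shift `Orig`, standardised `Zscore`,
row-normalised `AS`, RMS-normalised `AR`, volume-scaled `XC`, `LnF`
= ln|f|, the smoothed derivative `Deriv`, two rise-time estimators

    τ₁ = −1 / (d ln[f_inf − f(t)]/dt),     τ₂ = f_inf / (df/dt),

and pairwise sensor ratios `RatioF`. For a first-order rise τ₁ recovers τ
exactly; τ₂ equals τ·e^(t/τ) and is a small-t approximation.

**Decoders.** Three classifiers, all implemented here:

* **LDA** — Fisher discriminant directions maximising between/within
  scatter, nearest class mean in discriminant space;
* **PNN** — Parzen-window kernel density classifier,
  f_a(X) = (2π)^(−p/2)/∏σ_k · (1/n_a) Σ_i exp(−½ Σ_k ((X_k−Y_aik)/σ_k)²),
  with bandwidths set by the median within-class nearest-neighbour gap;
* **MLPNN** — one sigmoid hidden layer regressing the two component
  concentrations, decoded to the Euclidean-nearest of the ten target pairs
  [1.00, 0], [0.66, 0.33], …, [0, 2.00].

**Evaluation.** Exhaustive leave-one-out recognition per time station,
greedy sequential forward feature selection, nearest-neighbour dataset
expansion (45 → 90 rows, with a leakage guard that holds out a row's
temporal twin), and a per-second streaming decoder that emits code 0 until
the signal clears a noise threshold.

## Worked example

```python
import ratiodecode as rd

dataset = rd.simulate_design(rd.default_design(seed=1))      # 45 samples x 3 sensors
report = rd.calibration_report(dataset)
lo, hi = report.correlation_range()
print(f"sensor-pair correlations: {lo:.3f} .. {hi:.3f}")
print(f"steady-state relative deviation (worst): {report.max_steady_state_deviation():.1%}")

fm = rd.extract(dataset, rd.FeatureSpec(name="Orig"), 650.0)
rate = rd.leave_one_out(lambda: rd.PNNClassifier(), fm)
print(f"LOO recognition, Orig @ 650 s, PNN: {rate:.1%}")

traj = rd.decode_stream(dataset, time_step=5.0)
print(f"real-time decode complete at {traj.time_to_full_recognition():.0f} s "
      f"(response peaks at {rd.mean_response_peak_time(dataset):.0f} s)")
```

prints

```
sensor-pair correlations: 0.963 .. 0.993
steady-state relative deviation (worst): 8.1%
LOO recognition, Orig @ 650 s, PNN: 100.0%
real-time decode complete at 250 s (response peaks at 1037 s)
```

The correlations confirm the three polymers respond similarly (selectivity
comes from small sensitivity contrasts); repeat-to-repeat scatter at the
plateau stays under 10%. A Parzen classifier on the raw shifts decodes
every sample at the 650 s station, and the streaming decoder identifies
all ten codes roughly 150 s after injection — long before the sensor
response itself peaks, which is the point of transient-aware decoding.

A command-line interface mirrors the library:

```sh
ratiodecode simulate --seed 1 --out data.csv
ratiodecode extract --in data.csv --feature Orig --time 650 --out orig.csv
ratiodecode evaluate --in data.csv --method pnn --features Orig --stations 150:950:50 --out rates.csv
ratiodecode decode-rt --in data.csv --out decoded.csv
ratiodecode run --seed 1 --out results/
```

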