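# tempocode

Analysis tools for **temporal encoding by spike doublets** in sensory
neurons — the question of whether short patterns of two spikes act as
distinct codewords that carry stimulus information beyond what a linear,
independent-spikes code can explain.

The package targets the kind of data collected from wind-sensitive
interneurons driven by 10–200 Hz band-passed Gaussian white-noise air
currents, but every stage runs on synthetic surrogates generated by the
package itself, so the full analysis is reproducible without recordings.

## What it computes

Given a long non-repeated recording and/or frozen-noise repeats
(spike times in ms, stimulus velocity in mm/s at 10 kHz), the pipeline
estimates:

* **Interval statistics** (`spike_stats`) — ISI histograms, the Normal-CDF
  fit to the relative refractory recovery (mean ≈ 2.5 ms, SD ≈ 0.2 ms in
  these cells), and a Bonferroni-corrected test of consecutive-ISI
  independence.
* **Pattern precision** (`events`) — repeatable doublet events in
  frozen-noise rasters; onset jitter and within-doublet correlation as
  functions of ISI, fitted with `jitter(ISI) = x1·e^(−ISI/x2) + x3` and a
  double exponential `R(ISI) = x1·e^(−ISI/x2) + x3·e^(−ISI/x4)`; plus the
  two single-spike jitter estimators (raster method and iterative
  dejittering).
* **Timing models** (`timing_models`) — three generative models of doublet
  variability (independent spikes, refractory-corrected, data-matched with
  imposed correlation `t2 = ISI + R·t1 + ε`, `ε ~ N(0, σ₀²(1−R²))`), their
  conditional (noise) entropies `H_C = ½log₂(2πe·σ²_total)` and
  histogram-weighted entropy and information rates.
* **Information rates** (`info_rates`) — the direct method (context-tree
  weighting for the total entropy rate, across-trial word entropy for the
  noise entropy) and the linear-reconstruction bound
  `I = −∫ log₂(1−γ(f)) df` from multitaper coherence.
* **Pattern-conditioned stimulus models** (`stimulus_models`) — Gaussian
  models (mean + covariance of the 50 ms of stimulus before the
  pattern-defining spike at 1 kHz): singlet-triggered (STSM),
  doublet-triggered per 1 ms ISI bin (DTSM), and the synthetic doublet
  model (sDTSM) built from two time-offset copies of the STSM — the
  decodable prediction of linear superposition — all projected into a
  reduced space spanned by the band-limited stimulus covariance.
* **Likelihood tests** (`likelihood`) — cross-validated log-likelihood
  ratios DTSM-vs-STSM and DTSM-vs-sDTSM with small-sample optimism
  correction, the exponential decay of the LLR with ISI, the best-offset
  scan that exposes the compressive nonlinearity (very short doublets match
  *superimposed*, not offset, singlet kernels), and the csDTSM.
* **iSTAC** (`istac`) — the orthonormal subspace that preserves the most
  Kullback–Leibler divergence between synthetic and data-based models, the
  cumulative KL curve, and the mcsDTSM (synthetic model corrected to match
  the data model inside a low-dimensional subspace).

`tempocode.synthetic` generates the inputs: band-passed Gaussian noise
stimuli (RMS 72–76 mm/s) and spike trains from a stochastic
linear–nonlinear encoder with a Normal-CDF refractory recovery and an
optional burst mechanism. With `burst_gain = 0` the encoder is an exact
superposition null (negative control); with `burst_gain > 0` sharp
stimulus slopes elicit 2–8 ms doublets whose conditioned stimuli are
sharper and larger than linear predictions (positive control).

## Worked example

```python
import tempocode as tc
from tempocode import spike_stats, info_rates, timing_models

stim = tc.generate_stimulus(duration_ms=300_000, seed=1)     # 5 min of 10-200 Hz noise
spec = tc.EncoderSpec(burst_gain=30.0, latency_jitter_ms=0.3)
train = tc.encode(stim, spec, seed=2)

hist = spike_stats.isi_histogram(train, bin_width_ms=0.1, max_isi_ms=70.0)
rec = spike_stats.fit_recovery_function(hist)

frozen = tc.generate_stimulus(10_000, seed=3)
raster = tc.frozen_noise_session(frozen, spec, n_repeats=40, seed=4)
direct = info_rates.direct_information(train, raster)
linear = info_rates.coherence_information(stim, train)
```

which prints (formatted):

```
7571 spikes at 25.2 Hz
fraction of ISIs below 70 ms: 0.82
refractory recovery: Normal CDF(mu=2.54 ms, sigma=0.38 ms)
direct MI: 31.6 bits/s, linear MI: 7.3 bits/s (ratio 4.3)
conditional entropy at 4 ms ISI: independent 2.93 bits, data-matched 2.50 bits
```

The recovered refractory mean (2.54 ms) sits at the generator's 2.5 ms
setting; the direct information rate is several times the linear bound —
the information gap that motivates the pattern analysis; and the
data-matched timing model has ~0.4 bits less noise entropy per doublet
than the independent-spikes model, i.e. correlated doublet timing frees
coding capacity.

The full pipeline (simulation → interval statistics → event precision →
timing models → information → stimulus models → likelihood tests → iSTAC)
runs end to end with

```bash
tempocode pipeline --seed 1 --out results/
```

writing `report.json` and a short text summary.

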