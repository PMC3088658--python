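# Methods

This note records the models, estimators, numerical choices and known
limitations behind `tempocode`. Units are fixed throughout: milliseconds
for time, mm/s for air-particle velocity, bits for information (natural
logs appear only inside likelihoods, which are reported in nats).

## Synthetic data

**Stimulus.** Band-passed Gaussian white noise: white Gaussian samples are
masked in the frequency domain with a raised-cosine transition of at most
5 Hz at the band edges (default 10–200 Hz, 10 kHz sampling) and rescaled
to the target RMS (default 74 mm/s, the middle of the 72–76 mm/s range
used experimentally). The generator is deterministic given its seed; its
marginal is Gaussian (|excess kurtosis| < 0.1 for ≥10 s), out-of-band
power is <1% and the pass-band is flat within a factor of 3.

**Encoder.** A linear–nonlinear cascade driving an inhomogeneous renewal
process. The stimulus is filtered by a biphasic 50 ms kernel
(parameterized at 1 kHz, resampled to the stimulus rate, unit-normalized);
the intensity is `λ(t) = base_rate · exp(gain · (u(t) − threshold))`,
clipped at 600 Hz, multiplied by a Normal-CDF recovery
`Φ((Δ − 2.5)/0.2)` of the time Δ since the last spike, with a hard 2 ms
floor. Defaults (`gain 0.55`, `base_rate 18 Hz`) give sustained rates of
roughly 20–30 Hz.

The *exponential* nonlinearity is a deliberate choice: for Gaussian
stimuli, conditioning an exponential-intensity process on any spike
pattern multiplies the Gaussian prior by factors `exp(k·x)`, so the
pattern-conditioned ensemble stays Gaussian with mean equal to the sum of
time-shifted single-spike means and covariance equal to the prior. The
`burst_gain = 0` encoder therefore satisfies the superposition null by
construction and serves as the pipeline's negative control. Residual
deviations (isolation/silence conditioning, refractoriness) are real but
small (≲0.1 nats at 30-minute sample sizes).

**Burst mechanism.** When the slope of the filtered stimulus crosses
`burst_threshold_sd` (default 2.4 SD), the intensity is multiplied by
`1 + burst_gain` for 8 ms. With the canonical `burst_gain = 30`, sharp
upward deflections reliably elicit 2–8 ms doublets whose conditioned
stimuli are sharper and larger than summed single-spike predictions —
the positive control. The mechanism is phenomenological; it asserts
nothing about biophysics (no conductance model, no saturation), and the
burst-triggering feature (the derivative of the filtered stimulus) is
simply a convenient direction weakly represented in the single-spike
ensemble.

**Per-spike latency noise** is additive Gaussian (`latency_jitter_ms`),
applied after the point process; spikes violating the 2 ms floor after
jittering are dropped.

**What the surrogate does not emulate.** Adaptation over trials, slow
(e.g. calcium-dependent) burst priming with its long-silence signature,
spike-waveform information, non-Gaussian stimulus statistics, and any
saturating nonlinearity. Tests that pass on the surrogate therefore
establish that the *estimators* behave as claimed under the stated
statistical structure — not that real cells have that structure.

## Interval statistics

Histograms use half-open bins `[lo, hi)`, default 0.1 ms up to 70 ms. The
refractory recovery is fit by least squares as a Normal CDF to the
histogram normalized to 1 at its modal short-ISI bin, between the minimum
observed ISI and the mode; the fit is refused if no mode exists below
10 ms. The consecutive-ISI independence test compares the joint histogram
of (ISI₁, ISI₂) pairs (1 ms bins by default) to the product of its
marginals: per-bin two-sided binomial tests (exact up to expected count
30, normal approximation beyond), Bonferroni-corrected across the tested
bins, excluding bins with expected count < 5. Significant bins carry the
sign of (observed − expected).

## Event precision

Doublet events in frozen-noise rasters: leading trials firing above 120%
of the mean rate are dropped (adaptation), a 1 ms PSTH is thresholded at
2× its mean count (the threshold factor is configurable), supra-threshold
runs are padded by
1 ms, and windows in which ≥80% of trials contain exactly two spikes are
kept. Isolated single-spike events use the same machinery with a 5 ms pad
and a 20 ms isolation requirement.

Exponential fits (jitter-vs-ISI, correlation-vs-ISI, LLR-vs-ISI decay)
use bounded trust-region least squares; model order (2/3/4 parameters) is
chosen by AIC for the jitter model, while the correlation and LLR-decay
fits keep the 4-parameter double exponential for comparability even when
the second term is inactive. Parameter CIs are asymptotic (1.96·SE from
the fit covariance); prediction bands use the delta method.

**Dejittering** aligns spike-conditioned stimulus segments to their
ensemble mean by bounded shifts (±5 ms default): FFT cross-correlation
with parabolic sub-sample refinement, mean recomputation, iterating until
the largest shift update is <0.05 ms (50 iterations maximum; convergence
flagged). Shifts are re-centered each iteration to prevent drift; the
jitter estimate is the SD of the final shifts. Clipping at the bound
slightly shrinks the estimate for generating SDs near half the bound
(≈2% at SD 2.1 ms).

## Timing models and conditional entropy

The three doublet models share the measured isolated-single-spike latency
SD σ₁ = 1.3 ms. Model 1 draws both spike times independently
(SD 1.3 ms); the earliest draw is always attributed to the first spike.
Model 2 additionally redraws second spikes landing within 3 ms of the
first at `t₁ + |N(2.5, 0.2)|`. Model 3 (data-matched) uses the fitted
jitter model for σ₀(ISI) and the fitted correlation R(ISI), imposing
`t₂ = ISI + R·t₁ + ε`, `ε ~ N(0, σ₀²(1−R²))`, which preserves the
unconditioned second-spike variance and gives `var(ISI) = 2σ₀²(1−R)`.

Conditional entropy of a pattern given its stimulus is the differential
entropy of a Gaussian whose variance is the correlation-constrained ISI
noise variance plus the squared onset jitter:
`σ²_total = σ₁²(1−R²) + jitter²`, with R the model's spike-time
correlation at that ISI (the fitted double exponential for model 3, a
seeded Monte-Carlo estimate for models 1–2, where correlation arises only
from ordering and refractory displacement) and jitter the model's onset
jitter (1.3 ms for models 1–2, the fitted exponential for model 3). Among
the defensible combinations of these variance components, this is the one
that reproduces the reference worked example for these cells
(3.09 / 2.43 bits at 4 ms ISI) within 0.2 bits for both models; the
alternative `var(ISI) + jitter²` with model-specific σ₀ matches model 1
but misses model 3 by ~0.4 bits. Entropy rates weight the per-ISI
conditional entropies by the ISI histogram (1 ms bins, so that discrete
and differential entropies share a scale) and multiply by the ISI
occurrence rate `(n_spikes − 1)/duration`; the total rate uses the
discrete histogram entropy.

## Information rates

**CTW.** Standard binary context-tree weighting: Krichevsky–Trofimov
estimators at every node, weight ½ between the node estimate and its
children's product, tree depth D (default 100 for sparse spike
sequences; analytic-source validation uses the depth matching the source
order). Nodes are stored sparsely, so cost is O(n·D) worst case but far
less on sparse spike data. The entropy rate is −log₂ of the weighted
coding probability divided by sequence length; it converges within 2% of
the true rate on Bernoulli and first-order Markov sources at 10⁶ symbols.

**Direct method.** Total entropy rate: CTW on the 1 ms-binned long
non-repeated response (bins with >1 spike are clipped to 1 and counted).
Noise entropy rate: at each time bin of the frozen raster, the
Miller–Madow-corrected entropy of 4-bin words across trials, averaged
over time. With 30–100 trials this term is biased low (order
`2^L/trials` effects); the word length default (4) keeps it below
log₂(trials). The shuffle control (trials from unrelated stimuli)
accordingly tests that the residual "information" is small relative to
the total entropy rate, not exactly zero.

**Linear bound.** Spikes are binned at the stimulus rate; coherence is
multitaper (Slepian tapers, NW = 4, 8 tapers, 2¹⁴-sample segments, 50%
overlap), and `I = −∫ log₂(1−γ²(f)) df` is integrated over the stimulus
band only, since out-of-band frequencies carry no stimulus power and
would only add estimator-noise inflation.

## Stimulus models

All pattern-conditioned models live on 50 samples at 1 kHz covering
offsets −50…−1 ms relative to the pattern-defining spike (the second
spike for doublets). Isolation requires no other spikes within 20 ms of
the pattern; doublet ISIs are grouped in 1 ms bins (`bin k = [k, k+1)`),
and bins with fewer than 80 events are dropped. Models are sample means
and covariances; validation uses 10 disjoint folds of ≈10% each
(deterministic assignment).

**Reduced space.** Eigenvectors of the unconditioned 50-sample stimulus
covariance (Toeplitz, from the stimulus autocorrelation) with eigenvalue
≥1% of the largest — ≈19–24 dimensions for a 10–200 Hz band, matching
the 2BT degrees-of-freedom count. All likelihood work happens after
projection (`μ' = Bᵀμ`, `C' = BᵀCB`).

**Synthetic doublet model (sDTSM).** Mean: `μ_s(t) + μ_s(t + ISI)`, the
singlet mean plus a copy shifted to the first spike, zero outside the
singlet support. Covariance: `k·(C_s + shift(C_s))` with the
cross-covariance between the copies deliberately omitted — that omission
*is* the linear-independence hypothesis under test. The shifted copy is
extended with the stationary prior covariance where its window provides
no data: zero padding would delete the copy's variance from the most
recent ISI milliseconds and a periodic shift would sever its
cross-correlations, and either distortion (~0.4 nats) would be charged
against the synthetic model even when the superposition null is exactly
true; with the stationary extension the construction reproduces a
stationary covariance exactly (<10⁻⁴ nats at every offset). The volume
constant k matches the reduced-space generalized variance (eigenvalue
product) of the synthetic covariance to the reference DTSM's. Negative
offsets mirror positive ones with added response latency.

## Likelihood analysis

Log-likelihoods are exact Gaussian densities via Cholesky factors. For
each ISI bin, per-fold DTSMs are fit on the training split and compared
with the STSM or the per-fold sDTSM on held-out segments; per-sample LLRs
are pooled over folds, 3-SD outliers removed (typically <2%), and
summarized by mean ± 1.96·SE. "Significant" means the 95% CI of the mean
excludes zero.

**Optimism correction.** The DTSM is fit from ~10²–10³ events in ~20
dimensions while the sDTSM derives from ~10⁴ singlets, so the raw
cross-validated LLR is biased against the DTSM by the difference in
finite-sample optimism. The correction adds back each model's exact
expected held-out deficit under Gaussianity,

    opt(d, n) = ½ [ Σᵢ ψ((n−i)/2) − d·ln((n−1)/2) + (1 + 1/n)·d(n−1)/(n−d−2) − d ],

(Wishart expectations for the sample covariance with ddof = 1; ψ is the
digamma function). The empirical train/test log-likelihood gap matches
the corresponding Gaussian prediction on the surrogate ensembles,
supporting the Gaussian form. The correction is default-on and applied
symmetrically to both models in every comparison; for the mcsDTSM, whose
parameters mix doublet-fit and singlet-derived parts, optimism is
allocated proportionally to the data-estimated parameter count. Not
modeled: the selection effect of optimizing the iSTAC basis on the same
fold (see limitations).

**Offset scan.** sDTSMs are built at offsets −3…29 ms, each
volume-matched to the DTSM of the test ISI so that likelihood differences
reflect shape, not scale; per-sample posteriors under a uniform prior are
averaged and column-normalized. The csDTSM is the sDTSM at the peak
offset for each test ISI.

**LLR decay.** The mean LLR versus ISI is fit with the same double
exponential as the correlation model; the reported "indistinguishable
beyond" ISI is where the 95% prediction band first includes zero.

## iSTAC

The comparison model is whitened against the base model
(`μ_W = C_b^{-1/2}(μ_c − μ_b)`, `C_W = C_b^{-1/2} C_c C_b^{-1/2}`,
symmetric square root), after which
`D = ½(Tr C_W + μ_Wᵀμ_W − n − ln|C_W|)/ln 2` bits. The
m-dimensional maximally informative subspace maximizes the same
expression restricted to an orthonormal basis B: projected-gradient
ascent on the Stiefel manifold (QR retraction, backtracking line search),
seeded from the eigenvectors of C_W ranked by their single-dimension KL
contribution, the mean direction, and random frames (≥5 restarts).
Cumulative KL curves take a running maximum across m so optimizer noise
cannot break monotonicity; the curve equals 1 at full dimension by
construction.

**mcsDTSM.** In whitened coordinates (where the synthetic model is
(0, I)), the data model's mean and covariance are imposed inside the
subspace; the cross blocks default to the data model's (so the subspace
marginal matches the DTSM exactly), with a `cross="synthetic"` option.
The composite is symmetrized and eigenvalue-clipped if positive
semidefiniteness is lost (flagged in the label), then mapped back.

## Study conditions and problem sizes

The canonical synthetic sessions are 30 minutes of non-repeated noise at
10 kHz (the standard session length for codeword analyses in this
preparation), giving ≈3–5·10⁴ spikes, ≈2·10⁴ isolated singlets and
250–900 isolated doublets per 1 ms ISI bin; frozen-noise sessions use
30–100 repeats of 10 s. Parameter-recovery checks use 5,000 simulated
doublets per ISI, 50,000 renewal intervals, 200 events × 85 trials for
the raster jitter estimator and 1,000 segments at SNR 3 for dejittering.
The orchestrated pipeline defaults to a 5-minute recording, which keeps a
full run in the minutes range on one CPU.

## Known limitations

* The conditional-entropy formula is one defensible combination of the
  variance components; the reference worked example constrains but does
  not uniquely determine it (see above).
* The word-based noise-entropy estimator is biased low at few trials;
  direct-method MI values are therefore comparative, not absolute.
* The optimism correction is exact only under Gaussian ensembles and does
  not cover iSTAC basis selection; at ISIs where synthetic and data models
  genuinely coincide, the mcsDTSM can score slightly worse than the
  csDTSM because its imposed subspace statistics are fold-level noise.
* On the bursty surrogate the DTSM-vs-csDTSM difference at 5–7 ms ISIs is
  not rank-3, so the 3-dimensional correction leaves a small but (at
  30-minute power) statistically resolvable residual there; full parity is
  reached where the difference is low-rank.
* The offset scan's best offset tracks the test ISI but sits 1–2 ms below
  the diagonal for burst-driven doublets, because the burst window makes
  all short doublets compressive; an encoder with a saturating
  nonlinearity would be required to separate the diagonal regime from the
  compressive one more sharply.
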