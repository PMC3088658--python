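"""Doublet timing-variability models and their information rates.

Three generative models of the trial-to-trial variability of a two-spike
response to a fixed stimulus:

* ``independent`` -- first and second spike times drawn independently
  (Gaussian, SD 1.3 ms each), the strict reading of linear-reconstruction
  assumptions;
* ``refractory`` -- as above, but second spikes landing within 3 ms of the
  first are displaced using the Normal-CDF recovery function;
* ``matched`` -- onset jitter follows the fitted jitter-vs-ISI exponential
  and the first/second spike correlation follows the fitted double
  exponential; the correlation is imposed by t2 = ISI + R*t1 + eps with
  eps ~ N(0, sigma0^2 (1 - R^2)), which preserves the unconditioned
  variance of the second spike while shrinking var(ISI) to
  2 sigma0^2 (1 - R).

The conditional (noise) entropy of a pattern given its eliciting stimulus
is the differential entropy of a Gaussian whose variance combines the
correlation-constrained ISI noise variance with the squared onset jitter;
weighting by the ISI histogram and the ISI occurrence rate converts
per-event entropies into entropy rates and a model mutual-information rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spike_stats import IsiHistogram, RecoveryFunction

# Best-fit parameters of the pooled-data exponential models (40 cells,
# 7753 doublet events): onset jitter(ISI) and spike-time correlation R(ISI).
EQ1_PARAMS = (-1.0, 4.8, 1.1)
EQ2_PARAMS = (2.3, 1.7, 0.2, 28.9)

# Isolated-single-spike latency SD from the frozen-noise raster method (ms).
SINGLE_SPIKE_JITTER_MS = 1.3

REFRACTORY_WINDOW_MS = 3.0  # upper edge of the recovery window


def jitter_vs_isi(isi_ms, params=EQ1_PARAMS):
    """Onset jitter (ms) as a simple exponential of the following ISI."""
    x1, x2, x3 = params
    return x1 * np.exp(-np.asarray(isi_ms, dtype=float) / x2) + x3


def correlation_vs_isi(isi_ms, params=EQ2_PARAMS):
    """First/second spike-time correlation as a double exponential of ISI."""
    x1, x2, x3, x4 = params
    isi = np.asarray(isi_ms, dtype=float)
    return x1 * np.exp(-isi / x2) + x3 * np.exp(-isi / x4)


@dataclass
class TimingModelSpec:
    kind: str = "matched"  # independent | refractory | matched
    onset_sigma_ms: float = SINGLE_SPIKE_JITTER_MS
    recovery: RecoveryFunction = field(
        default_factory=lambda: RecoveryFunction(2.5, 0.2)
    )
    eq1_params: tuple = EQ1_PARAMS
    eq2_params: tuple = EQ2_PARAMS

    def __post_init__(self):
        if self.kind not in ("independent", "refractory", "matched"):
            raise ValueError(f"unknown timing model kind {self.kind!r}")

    def onset_jitter(self, isi_ms):
        if self.kind == "matched":
            return jitter_vs_isi(isi_ms, self.eq1_params)
        return np.broadcast_to(self.onset_sigma_ms, np.shape(isi_ms)) if np.ndim(isi_ms) else self.onset_sigma_ms


@dataclass
class EntropyRates:
    total_bits_per_s: float
    conditional_bits_per_s: float
    isi_rate_per_s: float

    @property
    def mutual_info_bits_per_s(self) -> float:
        return self.total_bits_per_s - self.conditional_bits_per_s


def sample_doublets(spec: TimingModelSpec, mean_isi_ms: float, n_trials: int, seed=0):
    """Draw (t_first, t_second) arrays for ``n_trials`` two-spike responses.

    Times are relative to the mean first-spike time (0 ms).  The earliest
    spike of each pair is always attributed to the first-spike
    distribution.
    """
    if mean_isi_ms < 2.0:
        raise ValueError("mean ISI must be >= 2 ms (hard refractory floor)")
    rng = np.random.default_rng(seed)
    if spec.kind in ("independent", "refractory"):
        s0 = spec.onset_sigma_ms
        t1 = rng.normal(0.0, s0, n_trials)
        t2 = rng.normal(mean_isi_ms, s0, n_trials)
        first = np.minimum(t1, t2)
        second = np.maximum(t1, t2)
        if spec.kind == "refractory":
            close = second - first < REFRACTORY_WINDOW_MS
            n_close = int(close.sum())
            if n_close:
                disp = np.abs(
                    rng.normal(spec.recovery.mu_ms, spec.recovery.sigma_ms, n_close)
                )
                second = second.copy()
                second[close] = first[close] + disp
        return first, second
    # matched: correlation imposed on the first-spike time
    sigma0 = float(jitter_vs_isi(mean_isi_ms, spec.eq1_params))
    r = float(np.clip(correlation_vs_isi(mean_isi_ms, spec.eq2_params), -0.999, 0.999))
    t1 = rng.normal(0.0, sigma0, n_trials)
    noise_sd = sigma0 * np.sqrt(1.0 - r**2)
    t2 = mean_isi_ms + r * t1 + rng.normal(0.0, noise_sd, n_trials)
    return np.minimum(t1, t2), np.maximum(t1, t2)


def model_correlation_curve(
    spec: TimingModelSpec, isi_grid, n_per_isi: int = 20000, seed: int = 0
):
    """Monte-Carlo first/second spike correlation per ISI."""
    out = np.empty(len(isi_grid))
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(len(isi_grid))
    for i, isi in enumerate(isi_grid):
        t1, t2 = sample_doublets(spec, float(isi), n_per_isi, seed=ss[i])
        out[i] = np.corrcoef(t1, t2)[0, 1]
    return out


def gaussian_entropy_bits(variance) -> np.ndarray:
    """Differential entropy (bits) of a Normal with the given variance (ms^2)."""
    return 0.5 * np.log2(2.0 * np.pi * np.e * np.asarray(variance, dtype=float))


def conditional_entropy(
    spec: TimingModelSpec,
    mean_isi_ms: float,
    base_sigma_ms: float = SINGLE_SPIKE_JITTER_MS,
    n_mc: int = 50000,
    seed: int = 12345,
) -> float:
    """Conditional (noise) entropy in bits of one doublet pattern.

    The stimulus-conditioned pattern variance combines the
    correlation-constrained ISI noise variance sigma^2 (1 - R^2) -- with
    sigma the isolated-single-spike latency SD -- and the model's squared
    onset jitter at this ISI.  R is the model's spike-time correlation:
    the fitted double exponential for the matched model, a seeded
    Monte-Carlo estimate for the other two (where correlation arises only
    from spike ordering and refractory displacement).
    """
    if spec.kind == "matched":
        r = float(np.clip(correlation_vs_isi(mean_isi_ms, spec.eq2_params), -0.999, 0.999))
        jitter = float(jitter_vs_isi(mean_isi_ms, spec.eq1_params))
    else:
        t1, t2 = sample_doublets(spec, mean_isi_ms, n_mc, seed=seed)
        r = float(np.corrcoef(t1, t2)[0, 1])
        jitter = spec.onset_sigma_ms
    var_total = base_sigma_ms**2 * (1.0 - r**2) + jitter**2
    return float(gaussian_entropy_bits(var_total))


def entropy_rates(
    spec: TimingModelSpec,
    isi_hist: IsiHistogram,
    n_spikes: int,
    duration_s: float,
    **ce_kwargs,
) -> EntropyRates:
    """Entropy and mutual-information rates from an ISI histogram.

    Total rate: discrete entropy of the ISI distribution times the ISI
    occurrence rate ((n_spikes - 1) / duration).  Conditional rate: the
    histogram-weighted mean of the per-ISI conditional entropies times the
    same rate.  Bin width should be 1 ms so that the discrete total
    entropy and the differential conditional entropy share a scale.
    """
    if isi_hist.empty or isi_hist.counts.sum() == 0:
        raise ValueError("empty ISI histogram")
    p = isi_hist.probabilities
    nz = p > 0
    total_bits = float(-np.sum(p[nz] * np.log2(p[nz])))
    centers = isi_hist.centers
    hc = np.array(
        [
            conditional_entropy(spec, max(float(c), 2.0), **ce_kwargs)
            for c in centers[nz]
        ]
    )
    cond_bits = float(np.sum(p[nz] * hc))
    isi_rate = (n_spikes - 1) / duration_s
    return EntropyRates(
        total_bits_per_s=total_bits * isi_rate,
        conditional_bits_per_s=cond_bits * isi_rate,
        isi_rate_per_s=isi_rate,
    )
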