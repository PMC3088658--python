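"""Synthetic stimuli and surrogate spike trains.

Every downstream stage of the analysis (interval statistics, precision
measurement, information rates, pattern-conditioned stimulus models) is
exercised on data from this module: band-limited Gaussian white-noise air
velocity waveforms and spike trains from a stochastic encoder with a
refractory recovery period and an optional doublet-generating ("burst")
nonlinearity.

The encoder is a linear-nonlinear cascade driving an inhomogeneous renewal
process.  The firing nonlinearity is exponential: for Gaussian stimuli an
exponential-intensity point process has the property that the ensemble of
stimuli conditioned on any spike pattern is Gaussian with mean equal to the
sum of time-shifted single-spike means and covariance equal to the prior
covariance.  With ``burst_gain = 0`` the surrogate therefore satisfies, by
construction, the null hypothesis that doublet-conditioned stimuli are
linear superpositions of singlet-conditioned stimuli -- the negative
control for the likelihood analysis.  With ``burst_gain > 0`` sharp upward
deflections of the filtered stimulus transiently boost the firing intensity
for ~8 ms, producing short doublets whose conditioned stimuli are sharper
and larger than the linear superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


HARD_REFRACTORY_MS = 2.0  # hard refractory floor observed in these cells
DEFAULT_BAND = (10.0, 200.0)  # Hz, stimulus pass band
DEFAULT_RMS = 74.0  # mm/s, middle of the 72-76 mm/s range
DEFAULT_RATE_HZ = 10_000.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Stimulus:
    """Band-limited air-particle velocity waveform.

    Attributes
    ----------
    samples : ndarray
        Velocity in mm/s.
    rate_hz : float
        Sampling frequency (10 kHz by default).
    band : tuple of float
        (low, high) pass band in Hz.
    rms : float
        Target RMS amplitude in mm/s.
    """

    samples: np.ndarray
    rate_hz: float = DEFAULT_RATE_HZ
    band: tuple = DEFAULT_BAND
    rms: float = DEFAULT_RMS

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * (1000.0 / self.rate_hz)

    def value_at(self, t_ms) -> np.ndarray:
        """Linear interpolation of the waveform at arbitrary times (ms)."""
        return np.interp(np.asarray(t_ms, dtype=float), self.times_ms, self.samples)


@dataclass
class SpikeTrain:
    """Sorted spike times in ms (real-valued, not binned)."""

    times_ms: np.ndarray
    duration_ms: float

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.times_ms.size and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times_ms.size)

    def isis(self) -> np.ndarray:
        return np.diff(self.times_ms)

    @property
    def rate_hz(self) -> float:
        return 1000.0 * self.n_spikes / self.duration_ms


@dataclass
class TrialRaster:
    """Spike trains from repeated presentations of one frozen stimulus."""

    trials: list
    stimulus_id: str = ""

    def __post_init__(self):
        if self.trials:
            d0 = self.trials[0].duration_ms
            if any(abs(t.duration_ms - d0) > 1e-9 for t in self.trials):
                raise ValueError("all trials must share the same duration")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration_ms(self) -> float:
        return self.trials[0].duration_ms


@dataclass
class EncoderSpec:
    """Parameters of the surrogate encoder.

    kernel_tau_ms / kernel_ms shape the biphasic linear filter (50 ms
    support, parameterized at 1 kHz and resampled to the stimulus rate).
    ``gain`` scales the filtered stimulus (in SD units) inside the
    exponential nonlinearity, ``threshold_sd`` shifts it, and
    ``base_rate_hz`` sets the spontaneous intensity; together they
    control the mean rate (~20-40 Hz).
    ``recovery`` is the (mu, sigma) of the Normal-CDF relative refractory
    recovery; spikes are forbidden outright within the 2 ms hard floor.
    ``burst_gain = 0`` yields the purely linear surrogate (negative
    control); ``burst_gain > 0`` converts threshold-exceeding upward slopes
    of the filtered stimulus into transient intensity boosts lasting
    ``burst_window_ms``, generating 2-8 ms doublets.
    ``latency_jitter_ms`` adds i.i.d. Gaussian latency noise per spike.
    """

    gain: float = 0.55
    threshold_sd: float = 0.0
    base_rate_hz: float = 18.0
    recovery: tuple = (2.5, 0.2)
    burst_gain: float = 0.0
    burst_threshold_sd: float = 2.4
    burst_window_ms: float = 8.0
    latency_jitter_ms: float = 0.0
    kernel_ms: float = 50.0
    kernel_tau_ms: float = 5.0
    max_rate_hz: float = 600.0
    seed: int = 0

    def kernel(self, rate_hz: float) -> np.ndarray:
        """Biphasic band-limited filter, most recent sample last."""
        t = np.arange(0.0, self.kernel_ms, 1000.0 / rate_hz)  # ms since input
        tau = self.kernel_tau_ms
        k = (t / tau) * np.exp(1.0 - t / tau) - 0.55 * (t / (2 * tau)) ** 2 * np.exp(
            2.0 - t / (2 * tau)
        )
        k *= np.hanning(2 * len(t))[len(t):] ** 0.25  # taper the tail
        return k / np.sqrt(np.sum(k**2))


# ---------------------------------------------------------------------------
# stimulus generation
# ---------------------------------------------------------------------------


def generate_stimulus(
    duration_ms: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    band: tuple = DEFAULT_BAND,
    rms: float = DEFAULT_RMS,
    seed: int = 0,
) -> Stimulus:
    """Band-passed Gaussian white-noise velocity waveform.

    White Gaussian noise is masked in the frequency domain with a
    raised-cosine transition (<= 5 Hz wide) at the band edges and rescaled
    to the target RMS.  Deterministic given ``seed``.
    """
    low, high = band
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if not (0 < low < high < rate_hz / 2):
        raise ValueError(f"invalid band {band} for sampling rate {rate_hz} Hz")
    n = int(round(duration_ms * rate_hz / 1000.0))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    trans = 5.0
    mask = np.zeros_like(f)
    inside = (f >= low) & (f <= high)
    mask[inside] = 1.0
    lo_edge = (f >= low - trans) & (f < low)
    mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (low - f[lo_edge]) / trans))
    hi_edge = (f > high) & (f <= high + trans)
    mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (f[hi_edge] - high) / trans))
    x = np.fft.irfft(spec * mask, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return Stimulus(samples=x, rate_hz=rate_hz, band=(low, high), rms=rms)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sim_loop(lam_per_bin, recovery_mu, recovery_sigma, floor_bins, dt_ms, uniforms):
    """Renewal sampler: spike in bin i w.p. lam_per_bin[i] * w(t - t_last)."""
    n = lam_per_bin.shape[0]
    out = np.empty(n, dtype=np.int64)
    m = 0
    last = -1_000_000.0
    inv = 1.0 / (recovery_sigma * math.sqrt(2.0))
    for i in range(n):
        delta = (i - last) * dt_ms
        if delta < floor_bins * dt_ms:
            continue
        w = 0.5 * (1.0 + math.erf((delta - recovery_mu) * inv))
        p = lam_per_bin[i] * w
        if uniforms[i] < p:
            out[m] = i
            m += 1
            last = float(i)
    return out[:m]


def filtered_drive(stimulus: Stimulus, spec: EncoderSpec) -> np.ndarray:
    """Filtered stimulus, normalized to unit SD (the encoder's generator)."""
    k = spec.kernel(stimulus.rate_hz)
    if len(k) > len(stimulus.samples):
        raise ValueError("kernel longer than stimulus")
    u = np.convolve(stimulus.samples / stimulus.rms, k)[: len(stimulus.samples)]
    sd = np.std(u)
    return u / sd if sd > 0 else u


def encode(stimulus: Stimulus, spec: EncoderSpec, seed=None) -> SpikeTrain:
    """Encode a stimulus into a spike train.

    Intensity lambda(t) = base_rate * exp(gain * u(t)) (clipped at
    ``max_rate_hz``), times a Normal-CDF recovery of the time since the
    last spike, with a 2 ms hard refractory floor.  When ``burst_gain > 0``
    the intensity is multiplied by (1 + burst_gain) for ``burst_window_ms``
    after the filtered-stimulus slope crosses ``burst_threshold_sd``.
    """
    if seed is None:
        seed = spec.seed
    u = filtered_drive(stimulus, spec)
    dt_ms = 1000.0 / stimulus.rate_hz
    lam = spec.base_rate_hz * np.exp(spec.gain * (u - spec.threshold_sd))
    if spec.burst_gain > 0:
        du = np.gradient(u) / dt_ms  # SD units per ms
        du /= np.std(du)
        crossings = np.flatnonzero(
            (du[1:] >= spec.burst_threshold_sd) & (du[:-1] < spec.burst_threshold_sd)
        )
        boost = np.zeros(len(u))
        w = int(round(spec.burst_window_ms / dt_ms))
        for c in crossings:
            boost[c : c + w] = 1.0
        lam = lam * (1.0 + spec.burst_gain * boost)
    np.clip(lam, 0.0, spec.max_rate_hz, out=lam)
    lam_per_bin = lam * (dt_ms / 1000.0)
    rng = np.random.default_rng(seed)
    uniforms = rng.random(len(lam_per_bin))
    floor_bins = int(round(HARD_REFRACTORY_MS / dt_ms))
    idx = _sim_loop(
        lam_per_bin, spec.recovery[0], spec.recovery[1], floor_bins, dt_ms, uniforms
    )
    times = idx * dt_ms
    if spec.latency_jitter_ms > 0 and len(times):
        times = times + rng.normal(0.0, spec.latency_jitter_ms, size=len(times))
        times = np.sort(times)
        times = _enforce_floor(times, HARD_REFRACTORY_MS)
        times = times[(times >= 0) & (times < stimulus.duration_ms)]
    return SpikeTrain(times_ms=times, duration_ms=stimulus.duration_ms)


def _enforce_floor(sorted_times: np.ndarray, floor_ms: float) -> np.ndarray:
    """Drop spikes violating the hard refractory floor after jittering."""
    keep = []
    last = -np.inf
    for t in sorted_times:
        if t - last >= floor_ms:
            keep.append(t)
            last = t
    return np.asarray(keep)


def frozen_noise_session(
    stimulus: Stimulus, spec: EncoderSpec, n_repeats: int, seed: int = 0
) -> TrialRaster:
    """Repeated presentations of one frozen stimulus, independent noise per trial."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    child_seeds = seed.spawn(n_repeats)
    trials = [encode(stimulus, spec, seed=s) for s in child_seeds]
    return TrialRaster(trials=trials, stimulus_id=f"frozen-{seed}")


def generate_renewal_train(
    n_isis: int,
    recovery: tuple = (2.5, 0.2),
    base_rate_hz: float = 50.0,
    seed: int = 0,
    max_isi_ms: float = 500.0,
) -> SpikeTrain:
    """Stationary renewal train whose hazard is base_rate * NormalCDF recovery.

    Used as the null model for the joint-ISI independence test and for
    recovery-function parameter-recovery checks: the short-ISI edge of its
    interval histogram follows the Normal-CDF recovery (mean 2.5 ms,
    SD 0.2 ms by default).
    """
    rng = np.random.default_rng(seed)
    dtau = 0.01  # ms
    tau = np.arange(0.0, max_isi_ms, dtau)
    hazard = (base_rate_hz / 1000.0) * ndtr((tau - recovery[0]) / recovery[1])
    hazard[tau < HARD_REFRACTORY_MS] = 0.0
    cumhaz = np.cumsum(hazard) * dtau
    e = rng.exponential(1.0, size=n_isis)
    isis = np.interp(e, cumhaz, tau)
    times = np.cumsum(isis)
    return SpikeTrain(times_ms=times, duration_ms=float(times[-1] + 1.0))


def simulate_ground_truth_doublets(
    isi_ms: float, n_trials: int, timing_model_spec, seed: int = 0, t_ref_ms: float = 100.0
) -> TrialRaster:
    """Raster of two-spike trials drawn from one of the timing models."""
    from .timing_models import sample_doublets

    t1, t2 = sample_doublets(timing_model_spec, isi_ms, n_trials, seed)
    dur = t_ref_ms + isi_ms + 100.0
    trials = [
        SpikeTrain(times_ms=np.array([t_ref_ms + a, t_ref_ms + b]), duration_ms=dur)
        for a, b in zip(t1, t2)
    ]
    return TrialRaster(trials=trials, stimulus_id=f"model-{timing_model_spec.kind}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def save_raster_csv(raster: TrialRaster, path) -> None:
    """Write (trial_id, spike_time_ms) rows."""
    import pandas as pd

    rows = [
        (i, t) for i, tr in enumerate(raster.trials) for t in tr.times_ms
    ]
    pd.DataFrame(rows, columns=["trial_id", "spike_time_ms"]).to_csv(path, index=False)


def load_raster_csv(path, duration_ms: float) -> TrialRaster:
    import pandas as pd

    df = pd.read_csv(path)
    trials = []
    for _, grp in df.groupby("trial_id"):
        trials.append(
            SpikeTrain(np.sort(grp["spike_time_ms"].to_numpy()), duration_ms)
        )
    return TrialRaster(trials=trials)


def save_stimulus_hdf5(stimulus: Stimulus, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("velocity_mm_per_s", data=stimulus.samples)
        d.attrs["rate_hz"] = stimulus.rate_hz
        d.attrs["band_hz"] = stimulus.band
        d.attrs["rms_mm_per_s"] = stimulus.rms


def load_stimulus_hdf5(path) -> Stimulus:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["velocity_mm_per_s"]
        return Stimulus(
            samples=d[:],
            rate_hz=float(d.attrs["rate_hz"]),
            band=tuple(d.attrs["band_hz"]),
            rms=float(d.attrs["rms_mm_per_s"]),
        )
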