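"""Repeatable-event detection and spike-timing precision.

Identifies doublet (and isolated single-spike) events in frozen-noise
rasters, measures onset jitter, ISI variability and first/second spike
correlation, fits the exponential jitter-vs-ISI and double-exponential
correlation-vs-ISI models, and implements the two single-spike jitter
estimators: the raster (frozen-noise) method and the iterative dejittering
alignment for non-repeated stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import TrialRaster


# ---------------------------------------------------------------------------
# exponential-family fitting (shared by the jitter, correlation and LLR fits)
# ---------------------------------------------------------------------------


def _exp2(x, x1, x2):
    return x1 * np.exp(-x / x2)


def _exp3(x, x1, x2, x3):
    return x1 * np.exp(-x / x2) + x3


def _exp4(x, x1, x2, x3, x4):
    return x1 * np.exp(-x / x2) + x3 * np.exp(-x / x4)


_FORMS = {2: _exp2, 3: _exp3, 4: _exp4}


@dataclass
class ExpFit:
    """Least-squares exponential-decay fit with AIC-based order selection."""

    params: np.ndarray
    cov: np.ndarray
    order: int  # number of parameters (2, 3 or 4)
    aic: float
    n_obs: int

    @property
    def param_ci95(self) -> np.ndarray:
        """Half-widths of asymptotic 95% CIs on the parameters."""
        return 1.96 * np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def __call__(self, x):
        return _FORMS[self.order](np.asarray(x, dtype=float), *self.params)

    def prediction_ci95(self, x):
        """Delta-method 95% CI half-width on the fitted curve at ``x``."""
        x = np.asarray(x, dtype=float)
        eps = 1e-6
        g = np.empty((len(self.params), x.size))
        for i in range(len(self.params)):
            p_hi = self.params.copy()
            p_lo = self.params.copy()
            h = eps * max(1.0, abs(self.params[i]))
            p_hi[i] += h
            p_lo[i] -= h
            g[i] = (_FORMS[self.order](x, *p_hi) - _FORMS[self.order](x, *p_lo)) / (2 * h)
        var = np.einsum("ix,ij,jx->x", g, self.cov, g)
        return 1.96 * np.sqrt(np.clip(var, 0, None))


def _fit_one_order(x, y, order, p0=None):
    f = _FORMS[order]
    if p0 is None:
        amp = y[0] - y[-1]
        p0 = {
            2: (max(y[0], 0.1), 5.0),
            3: (amp if amp != 0 else 0.5, 5.0, y[-1]),
            4: (amp if amp != 0 else 0.5, 3.0, y[-1] if y[-1] != 0 else 0.1, 30.0),
        }[order]
    lb = {2: (-np.inf, 1e-3), 3: (-np.inf, 1e-3, -np.inf), 4: (-np.inf, 1e-3, -np.inf, 1e-3)}[order]
    ub = np.full(order, np.inf)
    popt, pcov = curve_fit(
        f, x, y, p0=p0, bounds=(lb, ub), maxfev=20000, method="trf"
    )
    resid = y - f(x, *popt)
    n = len(x)
    rss = float(np.sum(resid**2))
    # Gaussian-likelihood AIC with estimated residual variance
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * (order + 1)
    return popt, pcov, aic


def fit_exponential(x, y, orders=(2, 3, 4), p0=None) -> ExpFit:
    """Fit amplitude*exp(-x/tau)(+offset terms); pick the order by AIC."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("fewer than 5 distinct x values; fit refused")
    best = None
    for order in orders:
        if len(x) <= order + 1:
            continue
        try:
            popt, pcov, aic = _fit_one_order(x, y, order, p0 if order == max(orders) else None)
        except RuntimeError:
            continue
        if best is None or aic < best[2]:
            best = (popt, pcov, aic, order)
    if best is None:
        raise RuntimeError("exponential fit failed for all model orders")
    popt, pcov, aic, order = best
    return ExpFit(params=np.asarray(popt), cov=np.asarray(pcov), order=order, aic=aic, n_obs=len(x))


# ---------------------------------------------------------------------------
# event identification
# ---------------------------------------------------------------------------


@dataclass
class DoubletEvent:
    """Per-trial first/second spike times for one repeatable doublet."""

    t_first: np.ndarray
    t_second: np.ndarray
    window_ms: tuple = (0.0, 0.0)

    @property
    def n_trials(self) -> int:
        return int(self.t_first.size)

    @property
    def mean_isi_ms(self) -> float:
        return float(np.mean(self.t_second - self.t_first))

    @property
    def onset_jitter_ms(self) -> float:
        return float(np.std(self.t_first, ddof=1))

    @property
    def isi_sd_ms(self) -> float:
        return float(np.std(self.t_second - self.t_first, ddof=1))

    @property
    def correlation(self) -> float:
        return event_precision(self)[2]


@dataclass
class SingleSpikeEvent:
    latencies: np.ndarray
    window_ms: tuple = (0.0, 0.0)

    @property
    def jitter_ms(self) -> float:
        return float(np.std(self.latencies, ddof=1))


def _trial_counts_matrix(raster: TrialRaster, bin_ms: float):
    n_bins = int(np.ceil(raster.duration_ms / bin_ms))
    mat = np.zeros((raster.n_trials, n_bins))
    edges = np.arange(0.0, (n_bins + 1) * bin_ms, bin_ms)[: n_bins + 1]
    for i, tr in enumerate(raster.trials):
        mat[i], _ = np.histogram(tr.times_ms, bins=edges)
    return mat, edges


def _adapted_trials(raster: TrialRaster, adaptation_factor: float):
    """Drop the leading run of trials firing above adaptation_factor x mean."""
    rates = np.array([t.rate_hz for t in raster.trials])
    mean_rate = rates.mean()
    start = 0
    while start < len(rates) and rates[start] > adaptation_factor * mean_rate:
        start += 1
    return list(range(start, len(rates)))


def _event_windows(psth_counts, edges, n_trials, threshold_factor, pad_ms):
    mean_count = psth_counts.mean()
    thr = threshold_factor * mean_count
    above = psth_counts > thr
    windows = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            windows.append((max(edges[i] - pad_ms, 0.0), edges[j + 1] + pad_ms))
            i = j + 1
        else:
            i += 1
    return windows


def identify_events(
    raster: TrialRaster,
    psth_bin_ms: float = 1.0,
    adaptation_factor: float = 1.2,
    contamination_max: float = 0.2,
    threshold_factor: float = 2.0,
    pad_ms: float = 1.0,
    min_trials: int = 20,
) -> list:
    """Identify repeatable doublet events in a frozen-noise raster.

    Leading trials firing >120% of the mean rate are excluded
    (adaptation), a 1 ms PSTH is thresholded at ``threshold_factor`` times
    its mean to delimit candidate windows (padded by ``pad_ms``), and
    windows in which at least (1 - contamination_max) of the trials contain
    exactly two spikes are kept.
    """
    if raster.n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    kept = _adapted_trials(raster, adaptation_factor)
    trials = [raster.trials[i] for i in kept]
    sub = TrialRaster(trials=trials)
    mat, edges = _trial_counts_matrix(sub, psth_bin_ms)
    windows = _event_windows(mat.sum(axis=0), edges, len(trials), threshold_factor, pad_ms)
    events = []
    for lo, hi in windows:
        pairs = []
        n_ok = 0
        for tr in trials:
            inside = tr.times_ms[(tr.times_ms >= lo) & (tr.times_ms < hi)]
            if inside.size == 2:
                n_ok += 1
                pairs.append(inside)
        if n_ok >= (1.0 - contamination_max) * len(trials) and n_ok >= 2:
            pairs = np.asarray(pairs)
            events.append(
                DoubletEvent(t_first=pairs[:, 0], t_second=pairs[:, 1], window_ms=(lo, hi))
            )
    return events


def identify_single_spike_events(
    raster: TrialRaster,
    psth_bin_ms: float = 1.0,
    adaptation_factor: float = 1.2,
    contamination_max: float = 0.2,
    threshold_factor: float = 2.0,
    pad_ms: float = 5.0,
    isolation_ms: float = 20.0,
    min_trials: int = 20,
) -> list:
    """Isolated single-spike events (no other spikes within ``isolation_ms``)."""
    if raster.n_trials < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    kept = _adapted_trials(raster, adaptation_factor)
    trials = [raster.trials[i] for i in kept]
    sub = TrialRaster(trials=trials)
    mat, edges = _trial_counts_matrix(sub, psth_bin_ms)
    windows = _event_windows(mat.sum(axis=0), edges, len(trials), threshold_factor, pad_ms)
    events = []
    for lo, hi in windows:
        lats = []
        n_ok = 0
        for tr in trials:
            inside = tr.times_ms[(tr.times_ms >= lo) & (tr.times_ms < hi)]
            near = tr.times_ms[
                (tr.times_ms >= lo - isolation_ms) & (tr.times_ms < hi + isolation_ms)
            ]
            if inside.size == 1 and near.size == 1:
                n_ok += 1
                lats.append(inside[0])
        if n_ok >= (1.0 - contamination_max) * len(trials) and n_ok >= 2:
            events.append(SingleSpikeEvent(latencies=np.asarray(lats), window_ms=(lo, hi)))
    return events


# ---------------------------------------------------------------------------
# precision statistics
# ---------------------------------------------------------------------------


def event_precision(event: DoubletEvent):
    """(onset jitter, ISI SD, Pearson R) for one doublet event."""
    if event.n_trials < 2:
        raise ValueError("need at least 2 trials")
    t1, t2 = event.t_first, event.t_second
    sd1 = float(np.std(t1, ddof=1))
    isi_sd = float(np.std(t2 - t1, ddof=1))
    if sd1 == 0 or np.std(t2, ddof=1) == 0:
        return sd1, isi_sd, float("nan")
    r = float(np.corrcoef(t1, t2)[0, 1])
    return sd1, isi_sd, r


def independent_isi_sd(sd_first_ms: float, sd_second_ms: float) -> float:
    """ISI SD predicted if the two spike times were independent."""
    return float(np.hypot(sd_first_ms, sd_second_ms))


def pool_events(events):
    """(mean ISI, onset jitter, ISI SD, R) arrays over a list of events."""
    isi = np.array([e.mean_isi_ms for e in events])
    jit = np.array([e.onset_jitter_ms for e in events])
    isd = np.array([e.isi_sd_ms for e in events])
    r = np.array([event_precision(e)[2] for e in events])
    return isi, jit, isd, r


def fit_jitter_vs_isi(isi_ms, jitter_ms, orders=(2, 3, 4)) -> ExpFit:
    """Onset jitter as a function of the following ISI (Eq-1-style fit)."""
    return fit_exponential(isi_ms, jitter_ms, orders=orders)


def fit_correlation_vs_isi(isi_ms, r, p0=(2.0, 2.0, 0.2, 30.0)) -> ExpFit:
    """First/second spike correlation vs ISI as a double exponential."""
    x = np.asarray(isi_ms, dtype=float)
    y = np.asarray(r, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("fewer than 5 distinct ISI values; fit refused")
    popt, pcov, aic = _fit_one_order(x, y, 4, p0=p0)
    return ExpFit(params=np.asarray(popt), cov=np.asarray(pcov), order=4, aic=aic, n_obs=len(x))


# ---------------------------------------------------------------------------
# single-spike jitter estimators
# ---------------------------------------------------------------------------


def raster_jitter(raster_or_events, **kwargs) -> float:
    """Frozen-noise jitter: mean across events of the across-trial latency SD."""
    if isinstance(raster_or_events, TrialRaster):
        events = identify_single_spike_events(raster_or_events, **kwargs)
    else:
        events = list(raster_or_events)
    if not events:
        raise ValueError("no isolated single-spike events found")
    return float(np.mean([e.jitter_ms for e in events]))


def dejitter_latencies(
    segments: np.ndarray,
    rate_hz: float = 10_000.0,
    max_shift_ms: float = 5.0,
    tol_ms: float = 0.05,
    max_iter: int = 50,
):
    """Iterative alignment of spike-conditioned stimulus segments.

    Each segment is shifted (bounded by ``max_shift_ms``) to maximize its
    cross-correlation with the ensemble mean; the mean is recomputed and
    the procedure iterates until the largest shift update falls below
    ``tol_ms``.  The returned jitter is the SD of the final shifts.
    Sub-sample precision comes from parabolic interpolation of the
    cross-correlation peak.

    Returns (shifts_ms, jitter_ms, converged).
    """
    X = np.asarray(segments, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_segments, n_samples) array")
    n, T = X.shape
    dt = 1000.0 / rate_hz
    max_lag = int(round(max_shift_ms / dt))
    idx = np.arange(T)
    shifts = np.zeros(n)
    aligned = X.copy()
    converged = False
    for _ in range(max_iter):
        m = aligned.mean(axis=0)
        m = m - m.mean()
        new_shifts = np.empty(n)
        nfft = int(2 ** np.ceil(np.log2(2 * T)))
        Fm = np.conj(np.fft.rfft(m, nfft))
        Y = X - X.mean(axis=1, keepdims=True)
        cc = np.fft.irfft(np.fft.rfft(Y, nfft, axis=1) * Fm, nfft, axis=1)
        # lag k means segment matches mean when advanced by k samples
        lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
        cols = np.concatenate([np.arange(0, max_lag + 1), nfft + np.arange(-max_lag, 0)])
        ccw = cc[:, cols]
        best = np.argmax(ccw, axis=1)
        for i in range(n):
            b = best[i]
            lag = lags[b]
            # parabolic refinement around the integer peak
            c0 = ccw[i, b]
            cm = cc[i, (lag - 1) % nfft]
            cp = cc[i, (lag + 1) % nfft]
            denom = cm - 2 * c0 + cp
            frac = 0.5 * (cm - cp) / denom if denom < 0 else 0.0
            frac = float(np.clip(frac, -0.5, 0.5))
            # positive shift = the spike lagged the ensemble-mean latency,
            # so its stimulus feature sits earlier in the window
            new_shifts[i] = np.clip(-(lag + frac) * dt, -max_shift_ms, max_shift_ms)
        new_shifts -= new_shifts.mean()  # anchor the ensemble (no global drift)
        delta = np.max(np.abs(new_shifts - shifts))
        shifts = new_shifts
        for i in range(n):
            aligned[i] = np.interp(idx - shifts[i] / dt, idx, X[i])
        if delta < tol_ms:
            converged = True
            break
    jitter = float(np.std(shifts, ddof=1))
    return shifts, jitter, converged
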