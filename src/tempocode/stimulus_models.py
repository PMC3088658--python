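"""Pattern-conditioned Gaussian stimulus models.

For every isolated spike pattern (singlets, and doublets grouped in 1 ms
ISI bins) the 50 ms of stimulus preceding the pattern-defining spike is
collected at 1 kHz and summarized by a Gaussian model (mean + covariance):
the singlet-triggered model (STSM), the doublet-triggered models
(DTSM(ISI)), and the synthetic doublet model (sDTSM) built from two
time-offset copies of the STSM -- the decodable prediction of linear
superposition.  All models and test data are projected into a reduced
space spanned by the significant eigenvectors of the unconditioned
band-limited stimulus covariance before likelihoods are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import SpikeTrain, Stimulus

WINDOW_MS = 50  # model window: offsets -50..-1 ms before the defining spike
MODEL_RATE_HZ = 1000.0


@dataclass
class GaussianStimulusModel:
    mu: np.ndarray  # mm/s, oldest sample first (offset -50 ms .. -1 ms)
    cov: np.ndarray  # mm^2/s^2
    n_events: int
    label: str = ""
    isi_ms: float = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mu.size, self.mu.size):
            raise ValueError("covariance shape inconsistent with mean")

    @property
    def dim(self) -> int:
        return int(self.mu.size)


@dataclass
class ReducedSpace:
    basis: np.ndarray  # (full_dim, d), orthonormal columns
    eigenvalues: np.ndarray  # retained eigenvalues of the stimulus covariance
    eig_threshold: float

    @property
    def dim(self) -> int:
        return int(self.basis.shape[1])

    def orthonormality_residual(self) -> float:
        g = self.basis.T @ self.basis
        return float(np.max(np.abs(g - np.eye(self.dim))))

    def project_segments(self, segments: np.ndarray) -> np.ndarray:
        return np.asarray(segments, dtype=float) @ self.basis


@dataclass
class EventEnsemble:
    """Stimulus segments for one pattern, with 10-fold CV assignments."""

    segments: np.ndarray  # (n_events, WINDOW_MS)
    label: str
    isi_ms: float = None
    folds: np.ndarray = None
    n_folds: int = 10

    def __post_init__(self):
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        if self.folds is None:
            # deterministic round-robin assignment of a fixed permutation
            rng = np.random.default_rng(2029)
            perm = rng.permutation(self.n_events)
            self.folds = np.empty(self.n_events, dtype=int)
            self.folds[perm] = np.arange(self.n_events) % self.n_folds

    @property
    def n_events(self) -> int:
        return int(self.segments.shape[0])

    def train_segments(self, fold: int) -> np.ndarray:
        return self.segments[self.folds != fold]

    def test_segments(self, fold: int) -> np.ndarray:
        return self.segments[self.folds == fold]


# ---------------------------------------------------------------------------
# pattern collection
# ---------------------------------------------------------------------------


def _isolated_patterns(times: np.ndarray, isolation_ms: float, max_isi_ms: float):
    """Indices of isolated singlets and isolated doublet (i, i+1) pairs."""
    n = len(times)
    prev_gap = np.diff(times, prepend=-np.inf)
    next_gap = np.diff(times, append=np.inf)
    singlets = np.flatnonzero((prev_gap >= isolation_ms) & (next_gap >= isolation_ms))
    isi = np.diff(times)
    pair_ok = (
        (isi <= max_isi_ms)
        & (prev_gap[:-1] >= isolation_ms)
        & (next_gap[1:] >= isolation_ms)
    )
    doublets = np.flatnonzero(pair_ok)
    return singlets, doublets


def _extract_segments(stimulus: Stimulus, spike_times: np.ndarray) -> np.ndarray:
    """50-sample (1 kHz) stimulus windows at offsets -50..-1 ms per spike."""
    offsets = np.arange(-WINDOW_MS, 0) + 0.0  # -50 .. -1 ms
    grid = spike_times[:, None] + offsets[None, :]
    return stimulus.value_at(grid)


def collect_isolated_patterns(
    spike_train: SpikeTrain,
    stimulus: Stimulus,
    isolation_ms: float = 20.0,
    max_isi_ms: float = 30.0,
    min_events: int = 80,
    n_folds: int = 10,
):
    """Collect singlet and per-ISI doublet stimulus ensembles.

    Doublet windows end at the second spike of the pair; ISIs are grouped
    in 1 ms bins (bin k covers [k, k+1) ms); bins with fewer than
    ``min_events`` events are dropped.  Returns
    (singlet_ensemble, {isi_bin: doublet_ensemble}).
    """
    if spike_train.duration_ms > stimulus.duration_ms + 1e-6:
        raise ValueError("spike train longer than stimulus")
    # isolation is judged on the full train; the window bound is applied per event
    times = spike_train.times_ms
    singlet_idx, doublet_idx = _isolated_patterns(times, isolation_ms, max_isi_ms)
    singlet_times = times[singlet_idx]
    singlet_times = singlet_times[
        (singlet_times >= WINDOW_MS) & (singlet_times < stimulus.duration_ms)
    ]
    singlet = EventEnsemble(
        segments=_extract_segments(stimulus, singlet_times),
        label="singlet",
        n_folds=n_folds,
    )
    doublets = {}
    if doublet_idx.size:
        t2 = times[doublet_idx + 1]
        isi = times[doublet_idx + 1] - times[doublet_idx]
        keep = (t2 >= WINDOW_MS) & (t2 < stimulus.duration_ms)
        t2, isi = t2[keep], isi[keep]
        bins = np.floor(isi).astype(int)
        for b in np.unique(bins):
            sel = bins == b
            if int(sel.sum()) < min_events:
                continue
            doublets[int(b)] = EventEnsemble(
                segments=_extract_segments(stimulus, t2[sel]),
                label=f"doublet-{b}ms",
                isi_ms=float(b),
                n_folds=n_folds,
            )
    return singlet, doublets


def fit_gaussian_model(
    segments: np.ndarray, label: str = "", isi_ms: float = None
) -> GaussianStimulusModel:
    """Sample mean and covariance of a stimulus ensemble."""
    X = np.atleast_2d(np.asarray(segments, dtype=float))
    mu = X.mean(axis=0)
    if X.shape[0] > 1:
        cov = np.cov(X, rowvar=False, ddof=1)
    else:
        cov = np.zeros((X.shape[1], X.shape[1]))
    return GaussianStimulusModel(
        mu=mu, cov=np.atleast_2d(cov), n_events=X.shape[0], label=label, isi_ms=isi_ms
    )


# ---------------------------------------------------------------------------
# reduced space
# ---------------------------------------------------------------------------


def stimulus_window_covariance(stimulus: Stimulus, window: int = WINDOW_MS) -> np.ndarray:
    """Toeplitz covariance of ``window``-sample (1 kHz) stimulus snippets."""
    from scipy.linalg import toeplitz

    # autocovariance of the stimulus at 1 ms lags
    x = stimulus.samples - stimulus.samples.mean()
    step = int(round(stimulus.rate_hz / MODEL_RATE_HZ))
    xs = x[::step]
    n = len(xs)
    acf = np.array(
        [np.dot(xs[: n - k], xs[k:]) / (n - k) for k in range(window)]
    )
    return toeplitz(acf)


def fit_reduced_space(source, eig_threshold: float = 0.01) -> ReducedSpace:
    """PCA basis of the unconditioned stimulus covariance.

    ``source`` is either a Stimulus (Toeplitz covariance from its
    autocorrelation) or an (n >= 500, window) array of stimulus segments.
    Eigenvectors with eigenvalue >= eig_threshold x largest are retained;
    for a 10-200 Hz band and a 50 ms window the 2BT count gives ~19-20
    dimensions.
    """
    if isinstance(source, Stimulus):
        cov = stimulus_window_covariance(source)
    else:
        X = np.asarray(source, dtype=float)
        if X.shape[0] < 500:
            raise ValueError("need >= 500 segments (or a Stimulus) for the reduced space")
        cov = np.cov(X, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w >= eig_threshold * w[0]
    return ReducedSpace(basis=v[:, keep], eigenvalues=w[keep], eig_threshold=eig_threshold)


def project_model(
    model: GaussianStimulusModel, space: ReducedSpace
) -> GaussianStimulusModel:
    """Project a model into the reduced space (mu' = B^T mu, C' = B^T C B)."""
    B = space.basis
    if B.shape[0] != model.dim:
        raise ValueError("dimension mismatch between model and reduced space")
    return GaussianStimulusModel(
        mu=B.T @ model.mu,
        cov=B.T @ model.cov @ B,
        n_events=model.n_events,
        label=model.label,
        isi_ms=model.isi_ms,
    )


# ---------------------------------------------------------------------------
# synthetic doublet model (offset-summed singlet models)
# ---------------------------------------------------------------------------


def _shift_vector(mu: np.ndarray, shift: int) -> np.ndarray:
    """Shift a window-aligned mean ``shift`` samples further into the past."""
    out = np.zeros_like(mu)
    n = len(mu)
    if shift >= 0:
        if shift < n:
            out[: n - shift] = mu[shift:]
    else:
        s = -shift
        if s < n:
            out[s:] = mu[: n - s]
    return out


def _shift_diag(
    cov: np.ndarray, shift: int, prior_cov: np.ndarray = None
) -> np.ndarray:
    """Shift a covariance along both axes by ``shift`` samples.

    The entries the shifted window still covers come from ``cov``; entries
    involving samples beyond the shifted window's support are filled from
    ``prior_cov``, the stationary covariance of the unconditioned
    stimulus (zero if not given).  The stationary extension is the unique
    choice under which summing a model with its own shifted copy exactly
    doubles a stationary covariance: zero padding deletes the shifted
    copy's variance from the most recent ``shift`` samples, and a
    periodic shift breaks the cross-correlation between those samples and
    the rest of the window, so either would make the synthetic doublet
    model differ from the data even when the superposition null is
    exactly true.
    """
    n = cov.shape[0]
    out = np.zeros_like(cov) if prior_cov is None else np.array(prior_cov, dtype=float)
    idx = np.arange(n) + shift
    valid = np.flatnonzero((idx >= 0) & (idx < n))
    out[np.ix_(valid, valid)] = cov[np.ix_(idx[valid], idx[valid])]
    return out


def synthesize_doublet_model(
    stsm: GaussianStimulusModel,
    isi_ms: float,
    dtsm_for_scaling: GaussianStimulusModel,
    space: ReducedSpace,
    label: str = None,
) -> GaussianStimulusModel:
    """Build the sDTSM: two offset copies of the singlet model, rescaled.

    The synthetic mean is mu_s(t) + mu_s(t + ISI) (copies aligned to the
    second and first spike, zero outside the singlet support), the
    synthetic covariance is k (C_s + shift_diag(C_s, ISI)) with the
    shifted copy extended by the stationary stimulus covariance where its
    window gives no data -- the cross-covariance between the two copies
    is deliberately omitted; that omission is the linear-independence
    hypothesis under test.  k matches the generalized variance
    (eigenvalue product) of the reduced-space synthetic covariance to
    that of the reference DTSM ("same volume in stimulus space").
    Negative offsets mirror positive ones with added response latency.
    """
    shift = int(round(isi_ms))
    if abs(shift) >= stsm.dim:
        raise ValueError("ISI at least as long as the model window")
    mu = stsm.mu + _shift_vector(stsm.mu, shift)
    prior_cov = (space.basis * space.eigenvalues) @ space.basis.T
    c_sum = stsm.cov + _shift_diag(stsm.cov, shift, prior_cov)
    B = space.basis
    sign_d, logdet_d = np.linalg.slogdet(B.T @ dtsm_for_scaling.cov @ B)
    sign_s, logdet_s = np.linalg.slogdet(B.T @ c_sum @ B)
    if sign_d <= 0 or sign_s <= 0:
        raise ValueError("non-positive-definite covariance in the reduced space")
    k = float(np.exp((logdet_d - logdet_s) / space.dim))
    return GaussianStimulusModel(
        mu=mu,
        cov=k * c_sum,
        n_events=stsm.n_events,
        label=label or f"sDTSM-{isi_ms:g}ms",
        isi_ms=float(isi_ms),
    )
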