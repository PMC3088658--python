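"""Interspike-interval statistics.

ISI histograms, the Normal-CDF fit to the relative refractory recovery
(after Berry & Meister), and a Bonferroni-corrected test of independence
of consecutive ISIs against the product of the marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import ndtr
from scipy.stats import binom, norm

from .synthetic import SpikeTrain


@dataclass
class IsiHistogram:
    bin_edges: np.ndarray  # half-open bins [lo, hi)
    counts: np.ndarray
    n_events: int  # ISIs within max_isi
    n_total: int  # all ISIs in the train
    bin_width_ms: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def fraction_within(self) -> float:
        """Fraction of all ISIs that fall within the histogram range."""
        return self.n_events / self.n_total if self.n_total else np.nan

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum() if self.n_events else self.counts

    @property
    def empty(self) -> bool:
        return self.n_total == 0


@dataclass
class RecoveryFunction:
    """Normal-CDF model of the relative refractory recovery."""

    mu_ms: float
    sigma_ms: float
    fit_range_ms: tuple = (2.0, 3.0)

    def __post_init__(self):
        if self.sigma_ms <= 0:
            raise ValueError("sigma_ms must be positive")

    def __call__(self, t_ms) -> np.ndarray:
        return ndtr((np.asarray(t_ms, dtype=float) - self.mu_ms) / self.sigma_ms)


@dataclass
class JointIsiTestResult:
    bin_edges: np.ndarray
    joint_p: np.ndarray  # observed p(ISI1, ISI2)
    independent_p: np.ndarray  # p(ISI1) * p(ISI2)
    significant: np.ndarray  # -1 / 0 / +1 per bin (sign of obs - expected)
    tested: np.ndarray  # bool, expected count >= minimum
    alpha: float
    alpha_corrected: float
    n_pairs: int

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.significant))

    @property
    def fraction_significant(self) -> float:
        n_tested = int(self.tested.sum())
        return self.n_significant / n_tested if n_tested else 0.0


def isi_histogram(
    spike_train: SpikeTrain, bin_width_ms: float = 0.1, max_isi_ms: float = 70.0
) -> IsiHistogram:
    """Histogram of consecutive ISIs up to ``max_isi_ms`` (half-open bins)."""
    isis = spike_train.isis()
    edges = np.arange(0.0, max_isi_ms + bin_width_ms / 2, bin_width_ms)
    if isis.size == 0:
        return IsiHistogram(edges, np.zeros(len(edges) - 1, int), 0, 0, bin_width_ms)
    counts, _ = np.histogram(isis, bins=edges)
    n_in = int(np.count_nonzero(isis < edges[-1]))
    return IsiHistogram(edges, counts, n_in, int(isis.size), bin_width_ms)


def fit_recovery_function(hist: IsiHistogram, mode_max_ms: float = 10.0) -> RecoveryFunction:
    """Fit a Normal CDF to the rising edge of the short-ISI histogram.

    The histogram is normalized to 1 at the modal short-ISI bin and the CDF
    is least-squares fit between the minimum observed ISI and the mode.
    """
    centers = hist.centers
    short = centers < mode_max_ms
    if hist.empty or not np.any(hist.counts[short] > 0):
        raise ValueError("no short-ISI mode below %.1f ms; fit refused" % mode_max_ms)
    mode_idx = int(np.argmax(np.where(short, hist.counts, -1)))
    if centers[mode_idx] >= mode_max_ms:
        raise ValueError("no short-ISI mode below %.1f ms; fit refused" % mode_max_ms)
    first_idx = int(np.argmax(hist.counts > 0))
    if mode_idx <= first_idx + 1:
        raise ValueError("too few bins between minimum ISI and mode to fit")
    y = hist.counts[first_idx : mode_idx + 1] / hist.counts[mode_idx]
    x = centers[first_idx : mode_idx + 1]

    def f(t, mu, sigma):
        return ndtr((t - mu) / np.abs(sigma))

    p0 = (0.5 * (x[0] + x[-1]), 0.25 * (x[-1] - x[0]))
    popt, _ = curve_fit(f, x, y, p0=p0, maxfev=10000)
    return RecoveryFunction(
        mu_ms=float(popt[0]), sigma_ms=float(abs(popt[1])), fit_range_ms=(x[0], x[-1])
    )


def joint_isi_independence_test(
    spike_train: SpikeTrain,
    bin_width_ms: float = 1.0,
    max_isi_ms: float = 70.0,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> JointIsiTestResult:
    """Test consecutive-ISI pairs against the independent joint distribution.

    Each tested bin gets a two-sided test of the observed pair count against
    a Binomial(n_pairs, p_ind) expectation -- exact for expected counts up
    to 30, normal approximation beyond.  The level is Bonferroni-corrected
    by the number of tested bins; bins with expected count below
    ``min_expected`` are excluded.  ``significant`` holds the sign of
    (observed - expected) for rejected bins: negative values mark pairs the
    independent model overpredicts.
    """
    isis = spike_train.isis()
    if isis.size < 2:
        raise ValueError("need at least 3 spikes (2 consecutive ISI pairs)")
    a, b = isis[:-1], isis[1:]
    keep = (a < max_isi_ms) & (b < max_isi_ms)
    a, b = a[keep], b[keep]
    edges = np.arange(0.0, max_isi_ms + bin_width_ms / 2, bin_width_ms)
    n_pairs = int(a.size)
    joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
    p1 = joint.sum(axis=1) / n_pairs
    p2 = joint.sum(axis=0) / n_pairs
    p_ind = np.outer(p1, p2)
    expected = n_pairs * p_ind
    tested = expected >= min_expected
    n_tested = int(tested.sum())
    sig = np.zeros_like(joint, dtype=int)
    if n_tested:
        alpha_c = alpha / n_tested
        ti, tj = np.nonzero(tested)
        k = joint[ti, tj]
        p = p_ind[ti, tj]
        mu = expected[ti, tj]
        pval = np.empty(len(k))
        small = mu <= 30
        if np.any(small):
            # two-sided exact binomial via tail doubling
            ks, ps, ns = k[small], p[small], n_pairs
            lo = binom.cdf(ks, ns, ps)
            hi = binom.sf(ks - 1, ns, ps)
            pval[small] = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
        big = ~small
        if np.any(big):
            sd = np.sqrt(n_pairs * p[big] * (1 - p[big]))
            z = (k[big] - mu[big]) / sd
            pval[big] = 2.0 * norm.sf(np.abs(z))
        rej = pval < alpha_c
        sig[ti[rej], tj[rej]] = np.sign(k[rej] - mu[rej]).astype(int)
    else:
        alpha_c = alpha
    return JointIsiTestResult(
        bin_edges=edges,
        joint_p=joint / n_pairs,
        independent_p=p_ind,
        significant=sig,
        tested=tested,
        alpha=alpha,
        alpha_corrected=alpha_c,
        n_pairs=n_pairs,
    )


def isi_to_rate_hz(isi_ms: float) -> float:
    """Firing rate (Hz) corresponding to a regular train at this ISI."""
    return 1000.0 / isi_ms
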