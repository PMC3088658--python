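"""Log-likelihood model comparison for pattern-conditioned stimuli.

Held-out stimulus segments are scored under pairs of Gaussian models in
the reduced space; per-sample log-likelihood ratios (LLRs) are pooled over
the 10 cross-validation folds, 3-SD outliers removed, and summarized by
mean and 95% CI.  LLR > 0 means the data-based doublet model explains the
held-out stimuli better than the competing (singlet or synthetic) model.
The LLR-vs-ISI decay is fit with the same double-exponential family as the
correlation model, and a best-offset scan over synthetic models exposes
the compressive nonlinearity (short doublets matching superimposed rather
than offset singlet kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .events import ExpFit, fit_exponential, _fit_one_order
from .stimulus_models import (
    EventEnsemble,
    GaussianStimulusModel,
    ReducedSpace,
    fit_gaussian_model,
    project_model,
    synthesize_doublet_model,
)


@dataclass
class LlrResult:
    llr: np.ndarray  # per-sample LLRs after outlier removal
    isi_ms: float
    models: tuple
    n_used: int
    n_outliers_removed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.llr))

    @property
    def ci95(self) -> float:
        return float(1.96 * np.std(self.llr, ddof=1) / np.sqrt(self.n_used))

    @property
    def ci(self) -> tuple:
        return (self.mean - self.ci95, self.mean + self.ci95)

    @property
    def significant(self) -> bool:
        """True when the 95% CI of the mean excludes zero."""
        lo, hi = self.ci
        return lo > 0 or hi < 0


@dataclass
class OffsetScan:
    matrix: np.ndarray  # (n_offsets, n_isis), columns sum to 1
    offsets_ms: np.ndarray
    isis_ms: np.ndarray

    @property
    def peak_offset_ms(self) -> np.ndarray:
        return self.offsets_ms[np.argmax(self.matrix, axis=0)]


def gaussian_loglik(x: np.ndarray, model: GaussianStimulusModel) -> np.ndarray:
    """Gaussian log density (natural log) of rows of ``x`` under ``model``.

    L = -1/2 [n log(2 pi) + log|C| + (x - mu)^T C^-1 (x - mu)].
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    n = model.dim
    try:
        c, low = cho_factor(model.cov)
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError(f"singular covariance in model {model.label!r}") from e
    if not np.all(np.diag(c) > 0):
        raise ValueError(f"singular covariance in model {model.label!r}")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    d = X - model.mu
    maha = np.einsum("ij,ij->i", d, cho_solve((c, low), d.T).T)
    out = -0.5 * (n * np.log(2.0 * np.pi) + logdet + maha)
    return out[0] if np.ndim(x) == 1 else out


def gaussian_optimism_nats(d: int, n: int) -> float:
    """Expected held-out log-likelihood deficit of a d-dim Gaussian MLE.

    For data truly drawn from a d-dimensional Gaussian, a model fit by
    sample mean and sample covariance (ddof=1) on n training points scores
    an independent test point, in expectation, this many nats below the
    true distribution.  Exact under Gaussianity (Wishart expectations):

        1/2 [ sum_i psi((n-i)/2) - d ln((n-1)/2)
              + (1 + 1/n) d (n-1)/(n-d-2) - d ]

    Cross-validated log-likelihood ratios between models estimated from
    very different training-set sizes are biased by the difference of
    these deficits; subtracting it makes the mean LLR an approximately
    unbiased estimate of the predictive divergence.
    """
    from scipy.special import digamma

    if n <= d + 2:
        raise ValueError("need n > d + 2 training samples for a stable Gaussian fit")
    i = np.arange(1, d + 1)
    e_logdet_excess = float(np.sum(digamma((n - i) / 2.0))) - d * np.log((n - 1) / 2.0)
    e_maha = (1.0 + 1.0 / n) * d * (n - 1) / (n - d - 2)
    return 0.5 * (e_logdet_excess + e_maha - d)


def _remove_outliers(llr: np.ndarray, n_sd: float = 3.0):
    m, s = llr.mean(), llr.std(ddof=1)
    keep = np.abs(llr - m) <= n_sd * s
    return llr[keep], int(np.count_nonzero(~keep))


def llr_test(
    test_segments: np.ndarray,
    model_a: GaussianStimulusModel,
    model_b: GaussianStimulusModel,
    isi_ms: float = None,
) -> LlrResult:
    """Per-sample L_a - L_b on one set of held-out (projected) segments."""
    if model_a.dim != model_b.dim:
        raise ValueError("models live in different spaces")
    la = gaussian_loglik(test_segments, model_a)
    lb = gaussian_loglik(test_segments, model_b)
    llr, n_out = _remove_outliers(np.atleast_1d(la - lb))
    return LlrResult(
        llr=llr,
        isi_ms=isi_ms,
        models=(model_a.label, model_b.label),
        n_used=int(llr.size),
        n_outliers_removed=n_out,
    )


def cross_validated_llr(
    doublet_ensemble: EventEnsemble,
    singlet_ensemble: EventEnsemble,
    space: ReducedSpace,
    comparison: str = "sdtsm",
    min_test: int = 8,
    correct_optimism: bool = True,
) -> LlrResult:
    """Pooled 10-fold LLR of the DTSM against the STSM or the sDTSM.

    Per fold, the DTSM is fit on the training split of the doublet
    ensemble; the competing model is the STSM (full singlet ensemble) or
    the sDTSM synthesized from it at this ISI and volume-matched to the
    fold's DTSM.  Held-out doublet segments are scored under both models
    in the reduced space; LLRs are pooled over folds before outlier
    removal.

    Doublet ensembles are typically 1-2 orders of magnitude smaller than
    the singlet ensemble, so the raw cross-validated LLR is biased against
    the DTSM by the difference in Gaussian-MLE optimism; with
    ``correct_optimism`` (default) the exact expected deficits
    (``gaussian_optimism_nats``) of both models are added back.
    """
    isi = doublet_ensemble.isi_ms
    stsm = fit_gaussian_model(singlet_ensemble.segments, label="STSM")
    llrs = []
    for fold in range(doublet_ensemble.n_folds):
        train = doublet_ensemble.train_segments(fold)
        test = doublet_ensemble.test_segments(fold)
        if test.shape[0] < min_test or train.shape[0] <= space.dim + 3:
            continue
        dtsm = fit_gaussian_model(train, label=f"DTSM-{isi:g}ms", isi_ms=isi)
        if comparison == "stsm":
            other = stsm
        elif comparison == "sdtsm":
            other = synthesize_doublet_model(stsm, isi, dtsm, space)
        else:
            raise ValueError(f"unknown comparison {comparison!r}")
        dtsm_r = project_model(dtsm, space)
        other_r = project_model(other, space)
        xt = space.project_segments(test)
        llr = gaussian_loglik(xt, dtsm_r) - gaussian_loglik(xt, other_r)
        if correct_optimism:
            llr = llr + gaussian_optimism_nats(space.dim, train.shape[0])
            llr = llr - gaussian_optimism_nats(space.dim, singlet_ensemble.n_events)
        llrs.append(llr)
    if not llrs:
        raise ValueError("no usable folds (test splits too small)")
    pooled = np.concatenate(llrs)
    llr, n_out = _remove_outliers(pooled)
    return LlrResult(
        llr=llr,
        isi_ms=isi,
        models=(f"DTSM-{isi:g}ms", "STSM" if comparison == "stsm" else f"sDTSM-{isi:g}ms"),
        n_used=int(llr.size),
        n_outliers_removed=n_out,
    )


def llr_curve(
    doublet_ensembles: dict,
    singlet_ensemble: EventEnsemble,
    space: ReducedSpace,
    comparison: str = "sdtsm",
) -> dict:
    """{isi: LlrResult} over all ISI bins with usable ensembles.

    Ensembles too small for stable fold models (or with no test fold of
    adequate size) are skipped rather than failing the whole curve.
    """
    out = {}
    for isi, ens in sorted(doublet_ensembles.items()):
        try:
            out[isi] = cross_validated_llr(ens, singlet_ensemble, space, comparison)
        except ValueError:
            continue
    return out


def fit_llr_decay(isi_ms, mean_llr) -> tuple:
    """Double-exponential fit of the LLR-vs-ISI decay.

    Returns (ExpFit, zero_isi_ms) where zero_isi_ms is the smallest ISI at
    which the fit's 95% prediction band first includes zero (the ISI
    beyond which synthetic and data-based models are indistinguishable).
    """
    x = np.asarray(isi_ms, dtype=float)
    y = np.asarray(mean_llr, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("fewer than 5 distinct ISI values; fit refused")
    popt, pcov, aic = _fit_one_order(x, y, 4, p0=(max(y[0], 0.1), 2.0, 0.0, 100.0))
    fit = ExpFit(params=np.asarray(popt), cov=np.asarray(pcov), order=4, aic=aic, n_obs=len(x))
    grid = np.arange(x.min(), x.max() + 0.05, 0.05)
    lower = fit(grid) - fit.prediction_ci95(grid)
    below = np.flatnonzero(lower <= 0)
    zero_isi = float(grid[below[0]]) if below.size else float("inf")
    return fit, zero_isi


# ---------------------------------------------------------------------------
# compressive-nonlinearity offset scan
# ---------------------------------------------------------------------------


def offset_scan(
    test_ensembles_by_isi: dict,
    singlet_ensemble: EventEnsemble,
    space: ReducedSpace,
    offsets_ms=None,
) -> OffsetScan:
    """Posterior over sDTSM offsets for doublet data of each test ISI.

    For each test ISI, every held-out segment gets a posterior (uniform
    prior) over sDTSMs built at offsets -3..29 ms, each volume-matched to
    the DTSM of the test ISI; per-sample posteriors are averaged and the
    columns normalized to 1.
    """
    if offsets_ms is None:
        offsets_ms = np.arange(-3, 30)
    offsets_ms = np.asarray(offsets_ms, dtype=float)
    isis = np.array(sorted(test_ensembles_by_isi))
    stsm = fit_gaussian_model(singlet_ensemble.segments, label="STSM")
    matrix = np.zeros((len(offsets_ms), len(isis)))
    for j, isi in enumerate(isis):
        ens = test_ensembles_by_isi[isi]
        dtsm = fit_gaussian_model(ens.segments, label=f"DTSM-{isi:g}ms", isi_ms=isi)
        models = [
            project_model(synthesize_doublet_model(stsm, o, dtsm, space), space)
            for o in offsets_ms
        ]
        # pool the held-out segments over folds (models here are offset
        # hypotheses, not fit to the doublet data, so no leakage)
        X = space.project_segments(ens.segments)
        L = np.stack([gaussian_loglik(X, m) for m in models])  # offsets x samples
        L -= L.max(axis=0, keepdims=True)
        post = np.exp(L)
        post /= post.sum(axis=0, keepdims=True)
        col = post.mean(axis=1)
        matrix[:, j] = col / col.sum()
    return OffsetScan(matrix=matrix, offsets_ms=offsets_ms, isis_ms=isis.astype(float))


def build_csdtsm(
    singlet_ensemble: EventEnsemble,
    test_isi_ms: float,
    scan: OffsetScan,
    dtsm_for_scaling: GaussianStimulusModel,
    space: ReducedSpace,
) -> GaussianStimulusModel:
    """sDTSM built at the best-match offset for this test ISI (csDTSM)."""
    j = int(np.argmin(np.abs(scan.isis_ms - test_isi_ms)))
    best = float(scan.peak_offset_ms[j])
    stsm = fit_gaussian_model(singlet_ensemble.segments, label="STSM")
    m = synthesize_doublet_model(
        stsm, best, dtsm_for_scaling, space, label=f"csDTSM-{test_isi_ms:g}ms"
    )
    m.isi_ms = float(test_isi_ms)
    return m


def subspace_corrected_llr(
    doublet_ensemble: EventEnsemble,
    singlet_ensemble: EventEnsemble,
    space: ReducedSpace,
    scan: OffsetScan,
    m: int = 3,
    cross: str = "data",
    istac_seed: int = 5,
    min_test: int = 8,
) -> dict:
    """Pooled 10-fold LLRs of the DTSM against the csDTSM and the mcsDTSM.

    Per fold: the csDTSM is the best-offset synthetic model volume-matched
    to the fold DTSM; the m-dimensional iSTAC basis between them defines
    the mcsDTSM (data statistics imposed inside the subspace).  The
    mcsDTSM mixes data- and singlet-estimated parameters, so its optimism
    is allocated proportionally to the parameter counts.

    Returns {"csdtsm": LlrResult, "mcsdtsm": LlrResult}.
    """
    from .istac import istac_subspace, modified_synthetic_model, whiten

    isi = doublet_ensemble.isi_ms
    d = space.dim
    p_total = d * (d + 3) / 2.0
    p_data = m * (m + 3) / 2.0 + (m * (d - m) if cross == "data" else 0.0)
    frac = p_data / p_total
    opt_s = gaussian_optimism_nats(d, singlet_ensemble.n_events)
    llr_cs, llr_mcs = [], []
    for fold in range(doublet_ensemble.n_folds):
        train = doublet_ensemble.train_segments(fold)
        test = doublet_ensemble.test_segments(fold)
        if test.shape[0] < min_test:
            continue
        dtsm = fit_gaussian_model(train, label=f"DTSM-{isi:g}ms", isi_ms=isi)
        dtsm_r = project_model(dtsm, space)
        cs = build_csdtsm(singlet_ensemble, isi, scan, dtsm, space)
        cs_r = project_model(cs, space)
        w = whiten(cs_r, dtsm_r)
        sub = istac_subspace(w, m, seed=istac_seed)
        mcs_r = modified_synthetic_model(cs_r, dtsm_r, sub.basis, cross=cross)
        xt = space.project_segments(test)
        opt_d = gaussian_optimism_nats(d, train.shape[0])
        base = gaussian_loglik(xt, dtsm_r) + opt_d
        llr_cs.append(base - gaussian_loglik(xt, cs_r) - opt_s)
        llr_mcs.append(
            base
            - gaussian_loglik(xt, mcs_r)
            - (frac * opt_d + (1.0 - frac) * opt_s)
        )
    if not llr_cs:
        raise ValueError("no usable folds")
    out = {}
    for name, chunks, label in (
        ("csdtsm", llr_cs, f"csDTSM-{isi:g}ms"),
        ("mcsdtsm", llr_mcs, f"mcsDTSM-{isi:g}ms"),
    ):
        pooled = np.concatenate(chunks)
        llr, n_out = _remove_outliers(pooled)
        out[name] = LlrResult(
            llr=llr,
            isi_ms=isi,
            models=(f"DTSM-{isi:g}ms", label),
            n_used=int(llr.size),
            n_outliers_removed=n_out,
        )
    return out


def cross_validated_llr_vs_model(
    doublet_ensemble: EventEnsemble,
    build_other,
    space: ReducedSpace,
    min_test: int = 8,
    label: str = "model",
    optimism_b=None,
) -> LlrResult:
    """Pooled 10-fold LLR of the DTSM against an arbitrary competing model.

    ``build_other(dtsm_fold)`` returns the competing full-space model for a
    given training-fold DTSM (used for the csDTSM and mcsDTSM variants).
    ``optimism_b(n_train_fold)`` returns the competing model's expected
    per-sample optimism in nats (see ``gaussian_optimism_nats``); the
    DTSM's own optimism is always corrected.
    """
    isi = doublet_ensemble.isi_ms
    llrs = []
    for fold in range(doublet_ensemble.n_folds):
        train = doublet_ensemble.train_segments(fold)
        test = doublet_ensemble.test_segments(fold)
        if test.shape[0] < min_test:
            continue
        dtsm = fit_gaussian_model(train, label=f"DTSM-{isi:g}ms", isi_ms=isi)
        other = build_other(dtsm)
        xt = space.project_segments(test)
        llr = (
            gaussian_loglik(xt, project_model(dtsm, space))
            - gaussian_loglik(xt, project_model(other, space))
            + gaussian_optimism_nats(space.dim, train.shape[0])
        )
        if optimism_b is not None:
            llr = llr - optimism_b(train.shape[0])
        llrs.append(llr)
    if not llrs:
        raise ValueError("no usable folds")
    pooled = np.concatenate(llrs)
    llr, n_out = _remove_outliers(pooled)
    return LlrResult(
        llr=llr,
        isi_ms=isi,
        models=(f"DTSM-{isi:g}ms", label),
        n_used=int(llr.size),
        n_outliers_removed=n_out,
    )
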