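"""Information-theoretic spike-triggered analysis (iSTAC).

Quantifies where two pattern-conditioned Gaussian stimulus models differ:
the comparison model is whitened against the base model (which becomes
zero-mean, identity-covariance), their KL divergence in bits follows the
closed Gaussian form, and an orthonormal basis B maximizing the KL
restricted to an m-dimensional subspace is found by projected-gradient
ascent on the Stiefel manifold with eigenvector-seeded restarts.  The
mcsDTSM replaces the synthetic model's mean and covariance inside such a
subspace with the data model's, leaving the remaining dimensions
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, qr

from .stimulus_models import GaussianStimulusModel

_LN2 = np.log(2.0)


@dataclass
class WhitenedModel:
    mu_w: np.ndarray
    cov_w: np.ndarray

    @property
    def dim(self) -> int:
        return int(self.mu_w.size)


@dataclass
class IstacBasis:
    basis: np.ndarray  # (n, m) orthonormal columns
    kl_bits: float  # KL captured by the subspace
    kl_total_bits: float

    @property
    def m(self) -> int:
        return int(self.basis.shape[1])

    @property
    def fraction(self) -> float:
        return self.kl_bits / self.kl_total_bits if self.kl_total_bits > 0 else 1.0


def _sqrtm_inv(cov: np.ndarray) -> np.ndarray:
    w, v = eigh(cov)
    if np.min(w) <= 0:
        raise ValueError("base covariance is not positive definite")
    return (v / np.sqrt(w)) @ v.T


def whiten(
    base: GaussianStimulusModel, comparison: GaussianStimulusModel
) -> WhitenedModel:
    """Whiten ``comparison`` against ``base`` (base maps to (0, I) exactly)."""
    if base.dim != comparison.dim:
        raise ValueError("models live in different spaces")
    s = _sqrtm_inv(base.cov)
    return WhitenedModel(mu_w=s @ (comparison.mu - base.mu), cov_w=s @ comparison.cov @ s)


def _kl_bits(mu: np.ndarray, cov: np.ndarray) -> float:
    n = mu.size
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance not positive definite")
    return 0.5 * (np.trace(cov) + mu @ mu - n - logdet) / _LN2


def kl_gaussian_whitened(w: WhitenedModel, basis: np.ndarray = None) -> float:
    """KL divergence in bits of the whitened model from (0, I).

    D = (Tr(C_W) + mu_W^T mu_W - n - ln|C_W|) / (2 ln 2); supplying an
    orthonormal ``basis`` restricts the divergence to that subspace.
    """
    if basis is None:
        return float(_kl_bits(w.mu_w, w.cov_w))
    B = np.atleast_2d(np.asarray(basis, dtype=float))
    if B.ndim == 2 and B.shape[0] == w.dim:
        pass
    else:
        B = B.T
    return float(_kl_bits(B.T @ w.mu_w, B.T @ w.cov_w @ B))


def kl_gaussian(
    base: GaussianStimulusModel, comparison: GaussianStimulusModel
) -> float:
    """Gaussian KL divergence D(comparison || base) in bits (unwhitened form)."""
    n = base.dim
    cb_inv = np.linalg.inv(base.cov)
    d = comparison.mu - base.mu
    _, ld_b = np.linalg.slogdet(base.cov)
    sign, ld_c = np.linalg.slogdet(comparison.cov)
    if sign <= 0:
        raise ValueError("covariance not positive definite")
    return float(
        0.5
        * (np.trace(cb_inv @ comparison.cov) + d @ cb_inv @ d - n - (ld_c - ld_b))
        / _LN2
    )


# ---------------------------------------------------------------------------
# subspace optimization
# ---------------------------------------------------------------------------


def _objective_and_grad(B, mu, cov):
    M = B.T @ cov @ B
    Minv = np.linalg.inv(M)
    mB = B.T @ mu
    sign, logdet = np.linalg.slogdet(M)
    f = 0.5 * (np.trace(M) + mB @ mB - B.shape[1] - logdet) / _LN2
    g = (cov @ B + np.outer(mu, mB) - cov @ B @ Minv) / _LN2
    return f, g


def _retract(B):
    q, r = qr(B, mode="economic")
    return q * np.sign(np.diag(r))


def _ascend(B, mu, cov, max_iter=300, tol=1e-10):
    f, g = _objective_and_grad(B, mu, cov)
    step = 0.1
    for _ in range(max_iter):
        improved = False
        while step > 1e-12:
            Bn = _retract(B + step * g)
            fn, gn = _objective_and_grad(Bn, mu, cov)
            if fn > f + tol:
                B, f, g = Bn, fn, gn
                step *= 1.5
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return B, f


def istac_subspace(
    w: WhitenedModel, m: int, n_restarts: int = 5, seed: int = 0
) -> IstacBasis:
    """Orthonormal basis maximizing the subspace-restricted KL (Eq-15 sense).

    Seeds: extreme eigenvectors of C_W (largest |lambda - 1 - ln lambda|
    contribution), the mean direction, and random orthonormal frames;
    each seed is refined by projected-gradient ascent with QR retraction.
    """
    n = w.dim
    if not (1 <= m <= n):
        raise ValueError("m must be in [1, dim]")
    mu, cov = w.mu_w, w.cov_w
    evals, evecs = eigh(cov)
    contrib = evals - 1.0 - np.log(evals)
    order = np.argsort(contrib)[::-1]
    seeds = [evecs[:, order[:m]]]
    if np.linalg.norm(mu) > 1e-12:
        cand = np.column_stack([mu / np.linalg.norm(mu), evecs[:, order[: max(m - 1, 0)]]])
        seeds.append(_retract(cand[:, :m]) if cand.shape[1] >= m else None)
    rng = np.random.default_rng(seed)
    while len([s for s in seeds if s is not None]) < n_restarts:
        seeds.append(_retract(rng.standard_normal((n, m))))
    best_B, best_f = None, -np.inf
    for s in seeds:
        if s is None or s.shape[1] < m:
            continue
        B, f = _ascend(s, mu, cov)
        if f > best_f:
            best_B, best_f = B, f
    total = float(_kl_bits(mu, cov))
    return IstacBasis(basis=best_B, kl_bits=float(best_f), kl_total_bits=total)


def cumulative_kl_curve(w: WhitenedModel, m_max: int, **kwargs) -> np.ndarray:
    """Normalized subspace KL for m = 1..m_max (nondecreasing, 1 at m = n)."""
    total = float(_kl_bits(w.mu_w, w.cov_w))
    out = np.empty(m_max)
    prev = 0.0
    for i, m in enumerate(range(1, m_max + 1)):
        if m == w.dim:
            val = total
        else:
            val = istac_subspace(w, m, **kwargs).kl_bits
        prev = max(prev, min(val, total))  # optimizer noise cannot break monotonicity
        out[i] = prev / total if total > 0 else 1.0
    return out


# ---------------------------------------------------------------------------
# subspace-corrected synthetic model
# ---------------------------------------------------------------------------


def modified_synthetic_model(
    synthetic: GaussianStimulusModel,
    data: GaussianStimulusModel,
    basis_whitened: np.ndarray,
    label: str = None,
    cross: str = "data",
) -> GaussianStimulusModel:
    """Subspace-corrected synthetic model (mcsDTSM) via whitened coordinates.

    The iSTAC basis lives in the coordinates in which the synthetic
    (base) model is (0, I); there the data model's mean and covariance are
    imposed inside the subspace (``modify_model_in_subspace``) and the
    composite is mapped back to the original space.
    """
    w = whiten(synthetic, data)
    ident = GaussianStimulusModel(
        mu=np.zeros(w.dim), cov=np.eye(w.dim), n_events=synthetic.n_events
    )
    target = GaussianStimulusModel(mu=w.mu_w, cov=w.cov_w, n_events=data.n_events)
    mod = modify_model_in_subspace(ident, target, basis_whitened, cross=cross)
    evals, evecs = eigh(synthetic.cov)
    s_half = (evecs * np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    return GaussianStimulusModel(
        mu=synthetic.mu + s_half @ mod.mu,
        cov=s_half @ mod.cov @ s_half,
        n_events=synthetic.n_events,
        label=label or f"mcs-{synthetic.label}",
        isi_ms=synthetic.isi_ms,
    )


def modify_model_in_subspace(
    synthetic: GaussianStimulusModel,
    data: GaussianStimulusModel,
    basis: np.ndarray,
    label: str = None,
    cross: str = "data",
) -> GaussianStimulusModel:
    """Replace the synthetic model's statistics inside a subspace (mcsDTSM).

    In coordinates aligned with the orthonormal ``basis`` (completed to a
    full frame), the subspace block of the mean and the subspace-subspace
    covariance block are taken from the data model; the complement block
    keeps the synthetic statistics.  ``cross`` selects whether the
    subspace/complement cross-covariance blocks come from the data model
    (the subspace marginal then matches the data model exactly) or stay
    synthetic (far fewer data-estimated parameters).  If the composite
    covariance loses positive semidefiniteness, eigenvalues are clipped at
    a small floor (nearest-PSD repair) and this is flagged via the label.
    """
    n = synthetic.dim
    B = np.atleast_2d(np.asarray(basis, dtype=float))
    if B.shape[0] != n:
        B = B.T
    m = B.shape[1]
    if m == 0:
        return GaussianStimulusModel(
            mu=synthetic.mu.copy(), cov=synthetic.cov.copy(),
            n_events=synthetic.n_events, label=label or synthetic.label,
            isi_ms=synthetic.isi_ms,
        )
    # complete the basis to an orthonormal frame
    q, _ = qr(np.column_stack([B, np.eye(n)]), mode="economic")
    Q = q[:, :n]
    Q[:, :m] = B  # keep the supplied subspace vectors exactly
    Q = _retract(Q)
    mu_s = Q.T @ synthetic.mu
    mu_d = Q.T @ data.mu
    cs = Q.T @ synthetic.cov @ Q
    cd = Q.T @ data.cov @ Q
    mu_new = mu_s.copy()
    mu_new[:m] = mu_d[:m]
    c_new = cs.copy()
    c_new[:m, :m] = cd[:m, :m]
    if cross == "data":
        c_new[:m, m:] = cd[:m, m:]
        c_new[m:, :m] = cd[m:, :m]
    c_new = 0.5 * (c_new + c_new.T)
    repaired = False
    evals, evecs = eigh(c_new)
    if np.min(evals) <= 0:
        floor = 1e-10 * np.max(evals)
        c_new = (evecs * np.clip(evals, floor, None)) @ evecs.T
        repaired = True
    out_label = label or f"mcs-{synthetic.label}"
    if repaired:
        out_label += "+psd-repaired"
    return GaussianStimulusModel(
        mu=Q @ mu_new,
        cov=Q @ c_new @ Q.T,
        n_events=synthetic.n_events,
        label=out_label,
        isi_ms=synthetic.isi_ms,
    )
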