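"""Pattern-conditioned Gaussian stimulus models and the reduced space."""

import numpy as np
import pytest

import tempocode as tc
from tempocode import istac as ist
from tempocode import stimulus_models as sm
from tempocode import synthetic as syn


class TestCollectIsolatedPatterns:
    def _stim(self):
        return tc.generate_stimulus(1_000.0, seed=20)

    def test_rule_application(self):
        tr = syn.SpikeTrain(np.array([100.0, 102.5, 200.0]), 1_000.0)
        singlet, doublets = sm.collect_isolated_patterns(
            tr, self._stim(), min_events=1
        )
        assert 2 in doublets and doublets[2].n_events == 1
        assert singlet.n_events == 1  # the isolated spike at 200 ms

    def test_follower_breaks_isolation(self):
        tr = syn.SpikeTrain(np.array([100.0, 102.5, 110.0, 300.0]), 1_000.0)
        _, doublets = sm.collect_isolated_patterns(tr, self._stim(), min_events=1)
        assert 2 not in doublets

    def test_small_ensembles_dropped(self, rng):
        # 79 well-separated doublets at 3 ms: below the 80-event floor
        t0 = 100.0 + 60.0 * np.arange(79)
        times = np.sort(np.concatenate([t0, t0 + 3.2]))
        tr = syn.SpikeTrain(times, times[-1] + 100.0)
        stim = tc.generate_stimulus(times[-1] + 100.0, seed=21)
        _, doublets = sm.collect_isolated_patterns(tr, stim)
        assert doublets == {}

    def test_folds_partition_each_ensemble(self, linear_session):
        for ens in linear_session["doublets"].values():
            counts = np.bincount(ens.folds, minlength=10)
            assert counts.sum() == ens.n_events
            assert counts.max() - counts.min() <= 1


class TestFitGaussianModel:
    def test_identical_segments_zero_covariance(self):
        X = np.tile(np.arange(50.0), (10, 1))
        m = sm.fit_gaussian_model(X)
        assert np.allclose(m.cov, 0.0)

    def test_covariance_error_shrinks_with_n(self, rng):
        c = np.diag(np.linspace(1.0, 3.0, 8))
        errs = []
        for n in (400, 6400):
            X = rng.multivariate_normal(np.zeros(8), c, size=n)
            errs.append(np.linalg.norm(sm.fit_gaussian_model(X).cov - c))
        assert errs[1] < 0.4 * errs[0]  # ~ n^(-1/2) scaling

    def test_singlet_mean_matches_filter_prediction(self, stim600, linear_session):
        # for Gaussian inputs and an exponential nonlinearity the
        # spike-triggered average is the prior-filtered (reversed) kernel
        mu = sm.fit_gaussian_model(linear_session["singlet"].segments).mu
        k = linear_session["spec"].kernel(1000.0)  # 50 taps at 1 kHz
        sta = np.zeros(50)
        sta[-len(k):] = k[::-1][-50:]  # reversed kernel, most recent last
        pred = sm.stimulus_window_covariance(stim600) @ sta
        assert np.corrcoef(mu, pred)[0, 1] > 0.95


class TestReducedSpace:
    def test_band_limited_dimension_count(self, space600):
        assert 17 <= space600.dim <= 24

    def test_white_segments_keep_full_dimension(self, rng):
        X = rng.standard_normal((2_000, 50))
        space = sm.fit_reduced_space(X)
        assert space.dim == 50

    def test_orthonormality(self, space600):
        assert space600.orthonormality_residual() < 1e-10

    def test_band_limited_mean_survives_projection(self, stim600, linear_session):
        mu = sm.fit_gaussian_model(linear_session["singlet"].segments).mu
        B = sm.fit_reduced_space(stim600).basis
        recon = B @ (B.T @ mu)
        lost = np.sum((mu - recon) ** 2) / np.sum(mu**2)
        assert lost < 0.01

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValueError):
            sm.fit_reduced_space(rng.standard_normal((100, 50)))


class TestProjectModel:
    def test_identity_basis_is_noop(self, rng):
        m = sm.fit_gaussian_model(rng.standard_normal((200, 6)))
        space = sm.ReducedSpace(basis=np.eye(6), eigenvalues=np.ones(6), eig_threshold=0.0)
        p = sm.project_model(m, space)
        assert np.allclose(p.mu, m.mu) and np.allclose(p.cov, m.cov)

    def test_kl_invariant_when_difference_lies_in_subspace(self, rng):
        # two models share complement statistics; KL in the full space
        # equals KL computed in the subspace
        n, d = 10, 4
        B = np.linalg.qr(rng.standard_normal((n, n)))[0]
        Bs, Bc = B[:, :d], B[:, d:]
        a = rng.standard_normal((d, d))
        c1 = a @ a.T + d * np.eye(d)
        b = rng.standard_normal((d, d))
        c2 = b @ b.T + d * np.eye(d)
        comp = np.eye(n - d) * 2.0
        m1 = sm.GaussianStimulusModel(
            mu=Bs @ rng.standard_normal(d), cov=Bs @ c1 @ Bs.T + Bc @ comp @ Bc.T, n_events=1
        )
        m2 = sm.GaussianStimulusModel(
            mu=Bs @ rng.standard_normal(d), cov=Bs @ c2 @ Bs.T + Bc @ comp @ Bc.T, n_events=1
        )
        space = sm.ReducedSpace(basis=Bs, eigenvalues=np.ones(d), eig_threshold=0.0)
        full = ist.kl_gaussian(m1, m2)
        sub = ist.kl_gaussian(sm.project_model(m1, space), sm.project_model(m2, space))
        assert abs(full - sub) < 1e-8


class TestSynthesizeDoubletModel:
    def test_zero_offset_doubles_the_mean(self, linear_session, space600):
        stsm = sm.fit_gaussian_model(linear_session["singlet"].segments)
        dtsm = sm.fit_gaussian_model(linear_session["doublets"][3].segments)
        sd = sm.synthesize_doublet_model(stsm, 0.0, dtsm, space600)
        assert np.allclose(sd.mu, 2 * stsm.mu)

    def test_generalized_variance_matched(self, linear_session, space600):
        stsm = sm.fit_gaussian_model(linear_session["singlet"].segments)
        dtsm = sm.fit_gaussian_model(linear_session["doublets"][3].segments)
        sd = sm.synthesize_doublet_model(stsm, 3.0, dtsm, space600)
        B = space600.basis
        _, ld_s = np.linalg.slogdet(B.T @ sd.cov @ B)
        _, ld_d = np.linalg.slogdet(B.T @ dtsm.cov @ B)
        assert abs(np.exp(ld_s - ld_d) - 1.0) < 1e-6

    def test_negative_offset_is_latency_shifted_positive(self, linear_session, space600):
        stsm = sm.fit_gaussian_model(linear_session["singlet"].segments)
        dtsm = sm.fit_gaussian_model(linear_session["doublets"][3].segments)
        neg = sm.synthesize_doublet_model(stsm, -3.0, dtsm, space600)
        pos = sm.synthesize_doublet_model(stsm, 3.0, dtsm, space600)
        # mu(-3)[j] = mu_s[j] + mu_s[j-3] is mu(+3) delayed by 3 samples
        assert np.allclose(neg.mu[3:], pos.mu[:-3], atol=1e-12)

    def test_construction_exact_for_stationary_null(self, stim600, space600):
        # a singlet model equal to the stationary prior must synthesize
        # back to the prior at every offset (the superposition null)
        C = sm.stimulus_window_covariance(stim600)
        prior = sm.GaussianStimulusModel(mu=np.zeros(50), cov=C, n_events=10**6)
        for isi in (2.0, 6.0, 11.0, 25.0):
            sd = sm.synthesize_doublet_model(prior, isi, prior, space600)
            w = ist.whiten(
                sm.project_model(sd, space600), sm.project_model(prior, space600)
            )
            assert ist.kl_gaussian_whitened(w) < 1e-3

    def test_overlong_isi_rejected(self, linear_session, space600):
        stsm = sm.fit_gaussian_model(linear_session["singlet"].segments)
        with pytest.raises(ValueError):
            sm.synthesize_doublet_model(stsm, 50.0, stsm, space600)
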