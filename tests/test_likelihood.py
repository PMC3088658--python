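"""Gaussian log-likelihoods, LLR tests, decay fit, offset scan, model variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tempocode import likelihood as lk
from tempocode import stimulus_models as sm


def _random_model(rng, d, scale=1.0):
    a = rng.standard_normal((d, d))
    return sm.GaussianStimulusModel(
        mu=scale * rng.standard_normal(d), cov=a @ a.T + d * np.eye(d), n_events=1000
    )


class TestGaussianLoglik:
    def test_standard_normal_at_origin(self):
        m = sm.GaussianStimulusModel(mu=np.zeros(1), cov=np.eye(1), n_events=1)
        assert abs(lk.gaussian_loglik(np.zeros(1), m) + 0.9189) < 1e-4

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_density(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_model(rng, 5)
        x = rng.standard_normal((4, 5))
        brute = -0.5 * (
            5 * np.log(2 * np.pi)
            + np.log(np.linalg.det(m.cov))
            + np.einsum("ij,jk,ik->i", x - m.mu, np.linalg.inv(m.cov), x - m.mu)
        )
        assert np.allclose(lk.gaussian_loglik(x, m), brute, atol=1e-10)

    def test_monotone_in_distance(self):
        m = sm.GaussianStimulusModel(mu=np.zeros(3), cov=np.eye(3), n_events=1)
        steps = [lk.gaussian_loglik(np.full(3, r), m) for r in (0.0, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(steps) < 0)

    def test_singular_covariance_named_error(self):
        m = sm.GaussianStimulusModel(mu=np.zeros(2), cov=np.zeros((2, 2)), n_events=1, label="bad")
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            lk.gaussian_loglik(np.zeros(2), m)


class TestLlrBasics:
    def test_identical_models_give_zero(self, rng):
        m = _random_model(rng, 6)
        x = rng.standard_normal((50, 6))
        res = lk.llr_test(x, m, m)
        assert res.mean == 0.0

    def test_gibbs_nonnegativity(self, rng):
        # data drawn from model A scores A above any B in expectation
        a = _random_model(rng, 6)
        for seed in range(3):
            b = _random_model(np.random.default_rng(seed), 6)
            x = rng.multivariate_normal(a.mu, a.cov, size=4000)
            res = lk.llr_test(x, a, b)
            assert res.mean > 0

    def test_outlier_removal_bounded_on_gaussian_data(self, rng):
        a = _random_model(rng, 6)
        b = _random_model(rng, 6)
        x = rng.multivariate_normal(a.mu, a.cov, size=2000)
        res = lk.llr_test(x, a, b)
        assert res.n_outliers_removed / (res.n_used + res.n_outliers_removed) < 0.05

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            lk.llr_test(rng.standard_normal((5, 4)), _random_model(rng, 4), _random_model(rng, 5))

    def test_optimism_correction_positive_and_decreasing(self):
        d = 23
        vals = [lk.gaussian_optimism_nats(d, n) for n in (50, 100, 1000, 10000)]
        assert np.all(np.diff(vals) < 0) and vals[-1] > 0
        # asymptotically d(d+3)/(4n)
        assert abs(vals[-1] / (d * (d + 3) / 4.0 / 10000) - 1.0) < 0.05


@pytest.fixture(scope="module")
def linear_curve(linear_session, space600):
    return lk.llr_curve(
        linear_session["doublets"], linear_session["singlet"], space600, "sdtsm"
    )


@pytest.fixture(scope="module")
def bursty_curve(bursty_session, space600):
    return lk.llr_curve(
        bursty_session["doublets"], bursty_session["singlet"], space600, "sdtsm"
    )


class TestLlrControls:
    """The pipeline's specificity and sensitivity on the two surrogates."""

    def test_negative_control_covers_zero_everywhere(self, linear_curve):
        for isi, res in linear_curve.items():
            lo, hi = res.ci
            assert lo <= 0.0 <= hi, f"ISI {isi}: CI ({lo:.3f}, {hi:.3f})"

    def test_bursty_positive_at_short_isis(self, bursty_curve):
        for isi in (2, 3, 4, 5):
            res = bursty_curve[isi]
            assert res.mean > 0 and res.significant, f"ISI {isi}"

    def test_bursty_decays_with_isi(self, bursty_curve):
        short = np.mean([bursty_curve[i].mean for i in (2, 3)])
        long = np.mean([bursty_curve[i].mean for i in (8, 9, 10, 11)])
        assert short > long + 0.3

    def test_bursty_not_significant_at_long_isis(self, bursty_curve):
        flags = [bursty_curve[i].significant for i in (8, 9, 10, 11)]
        assert sum(flags) <= 1  # allow one marginal false positive

    def test_stsm_rejected_for_doublets(self, bursty_session, space600):
        # singlet-conditioned stimuli cannot account for doublet stimuli
        curve = lk.llr_curve(
            bursty_session["doublets"], bursty_session["singlet"], space600, "stsm"
        )
        for isi, res in curve.items():
            assert res.mean > 0
            if isi <= 8:
                assert res.significant


class TestLlrDecayFit:
    def test_parameter_recovery(self, rng):
        grid = np.arange(2.0, 26.0)
        y = 2.7 * np.exp(-grid / 2.0) + rng.normal(0, 0.02, grid.size)
        fit, zero_isi = lk.fit_llr_decay(grid, y)
        assert 1.8 <= fit.params[1] <= 2.2
        assert 2.0 < zero_isi < 26.0

    def test_all_zero_input(self):
        grid = np.arange(2.0, 26.0)
        fit, zero_isi = lk.fit_llr_decay(grid, np.zeros(grid.size))
        assert abs(fit.params[0]) < 1e-6
        assert zero_isi == 2.0

    def test_fast_term_negligible_at_four_time_constants(self, rng):
        grid = np.arange(2.0, 26.0)
        y = 2.7 * np.exp(-grid / 2.0) + rng.normal(0, 0.02, grid.size)
        fit, _ = lk.fit_llr_decay(grid, y)
        x1, x2 = fit.params[0], fit.params[1]
        assert x1 * np.exp(-4.0) < 0.06  # amplitude decayed to ~e^-4


class TestOffsetScan:
    def test_columns_sum_to_one(self, bursty_scan):
        assert np.allclose(bursty_scan.matrix.sum(axis=0), 1.0)

    def test_self_consistency_peak_recovery(self, linear_session, space600, stim600, rng):
        # data sampled from a given offset model must peak at that offset
        stsm = sm.fit_gaussian_model(linear_session["singlet"].segments, label="STSM")
        C = sm.stimulus_window_covariance(stim600)
        prior = sm.GaussianStimulusModel(mu=np.zeros(50), cov=C, n_events=10**6)
        fake = {}
        for ostar in (2, 5, 9):
            model = sm.synthesize_doublet_model(stsm, ostar, prior, space600)
            w, v = np.linalg.eigh(model.cov)
            x = rng.standard_normal((400, 50)) * np.sqrt(np.clip(w, 0, None)) @ v.T + model.mu
            fake[ostar] = sm.EventEnsemble(x, label="synthetic", isi_ms=float(ostar))
        scan = lk.offset_scan(fake, linear_session["singlet"], space600,
                              offsets_ms=np.arange(-3, 13))
        for ostar, peak in zip(scan.isis_ms, scan.peak_offset_ms):
            assert abs(peak - ostar) <= 1.0

    def test_compressive_mapping_at_short_isis(self, bursty_scan):
        # burst-driven short doublets match synthetic models built at
        # offsets below the actual ISI; at 2 ms the best match is the
        # (near-)superimposed-copies model
        for isi in (2.0, 3.0):
            j = int(np.argmin(np.abs(bursty_scan.isis_ms - isi)))
            assert bursty_scan.peak_offset_ms[j] < isi
        j2 = int(np.argmin(np.abs(bursty_scan.isis_ms - 2.0)))
        assert abs(bursty_scan.peak_offset_ms[j2]) <= 1.0

    def test_best_offset_tracks_test_isi(self, bursty_scan):
        from scipy.stats import spearmanr

        rho, _ = spearmanr(bursty_scan.isis_ms, bursty_scan.peak_offset_ms)
        assert rho > 0.8


@pytest.fixture(scope="module")
def corrected(bursty_session, space600, bursty_scan):
    return {
        isi: lk.subspace_corrected_llr(
            bursty_session["doublets"][isi],
            bursty_session["singlet"],
            space600,
            bursty_scan,
            m=3,
        )
        for isi in (2, 3, 5)
    }


class TestModelVariants:

    def test_csdtsm_at_peak_offset_inherits_volume(self, bursty_session, space600, bursty_scan):
        ens = bursty_session["doublets"][3]
        dtsm = sm.fit_gaussian_model(ens.segments, isi_ms=3.0)
        cs = lk.build_csdtsm(bursty_session["singlet"], 3.0, bursty_scan, dtsm, space600)
        B = space600.basis
        _, ld_c = np.linalg.slogdet(B.T @ cs.cov @ B)
        _, ld_d = np.linalg.slogdet(B.T @ dtsm.cov @ B)
        assert abs(np.exp(ld_c - ld_d) - 1.0) < 1e-6

    def test_subspace_correction_reduces_short_isi_llr(self, corrected):
        for isi in (2, 3, 5):
            assert corrected[isi]["mcsdtsm"].mean < corrected[isi]["csdtsm"].mean

    def test_parity_restored_where_difference_is_low_rank(self, corrected):
        # at 3 ms the 3-dim subspace captures essentially the whole model
        # difference: the corrected synthetic model reaches statistical
        # parity with the data-based model
        lo, hi = corrected[3]["mcsdtsm"].ci
        assert lo <= 0.0 <= hi

    def test_large_relative_reduction_at_mid_range(self, corrected):
        res = corrected[5]
        assert res["mcsdtsm"].mean < 0.5 * res["csdtsm"].mean
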