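import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from ercflow.mvar import (
    MVARModel,
    SingularCovarianceError,
    WindowGrid,
    aic,
    check_sufficiency,
    default_freq_grid,
    fit_mvar,
    fit_mvar_window,
    sddtf,
    select_order_aic,
    sliding_sddtf,
    spectral_decomposition,
)
from ercflow.synthetic import mvar_generate

from conftest import make_epochset
from oracles import (
    oracle_aic,
    oracle_dtf_mag,
    oracle_ordinary_coherence_mag,
    oracle_partial_coherence_mag,
    oracle_sddtf,
    oracle_transfer,
    oracle_yule_walker,
)


class TestSufficiency:
    def test_pass_case(self):
        res = check_sufficiency(K=10, p=12, Ns=175, nt=60)
        assert res.ratio == pytest.approx(130 / 10500)
        assert res.passed

    def test_fail_case(self):
        res = check_sufficiency(K=60, p=20, Ns=175, nt=5)
        assert res.ratio == pytest.approx(1260 / 875)
        assert not res.passed

    def test_threshold_is_point_one(self):
        assert check_sufficiency(1, 1, 1, 1).threshold == 0.1

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            check_sufficiency(0, 1, 175, 60)


class TestWindowGrid:
    def test_one_second_epoch_gives_154_windows(self):
        grid = WindowGrid(n_epoch_samples=1250, sampling_rate=1250.0)
        assert grid.Ns == 175
        assert grid.step == 7
        assert grid.n_windows == 154

    def test_baseline_epoch_windows(self):
        grid = WindowGrid(n_epoch_samples=650, sampling_rate=1250.0)
        assert grid.n_windows == (650 - 175) // 7 + 1

    def test_too_short_epoch(self):
        with pytest.raises(ValueError, match="shorter"):
            WindowGrid(n_epoch_samples=100, sampling_rate=1250.0)


class TestFitMvar:
    def test_univariate_ar1_matches_autocovariance_ratio(self):
        model = MVARModel(np.array([[[0.9]]]), np.eye(1))
        x = mvar_generate(model, 20000, seed=5)
        est = fit_mvar(x[None, :, :], 1)
        xd = x[0] - x[0].mean()
        r0 = (xd * xd).mean()
        r1 = (xd[1:] * xd[:-1]).sum() / len(xd)
        assert est.coeffs[0, 0, 0] == pytest.approx(r1 / r0, abs=1e-12)

    def test_white_noise_null_model(self):
        rng = np.random.default_rng(0)
        cov = np.diag([1.0, 2.0, 0.5])
        data = rng.standard_normal((200, 3, 175)) * np.sqrt(np.diag(cov))[None, :, None]
        est = fit_mvar(data, 2)
        assert np.max(np.abs(est.coeffs)) < 0.05
        assert np.allclose(est.noise_cov, cov, atol=0.1)

    def test_recovers_known_order2_model(self):
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = [[0.5, 0, 0], [0.4, 0.4, 0], [0, 0.35, 0.45]]
        coeffs[1] = [[-0.1, 0, 0], [0, -0.1, 0.15], [0, 0, -0.1]]
        model = MVARModel(coeffs, np.eye(3))
        x = mvar_generate(model, 200 * 185, seed=2)
        data = np.stack([x[:, i * 185 : i * 185 + 175] for i in range(200)])
        est = fit_mvar(data, 2)
        assert np.max(np.abs(est.coeffs - coeffs)) < 0.1

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 2, 40))
        est = fit_mvar(data, 2)
        oc, onoise = oracle_yule_walker(data, 2)
        assert np.allclose(est.coeffs, oc, atol=1e-10)
        assert np.allclose(est.noise_cov, onoise, atol=1e-10)

    def test_singular_covariance_names_channels(self):
        data = np.zeros((10, 2, 50))
        data[:, 0] = np.random.default_rng(0).standard_normal((10, 50))
        with pytest.raises(SingularCovarianceError, match="1"):
            fit_mvar(data, 1)

    def test_fit_mvar_window_slices_grid(self):
        rng = np.random.default_rng(1)
        ep = make_epochset(rng.standard_normal((20, 2, 1250)))
        grid = WindowGrid(n_epoch_samples=1250, sampling_rate=1250.0)
        m = fit_mvar_window(ep, window=3, p=2, grid=grid)
        start = int(grid.starts[3])
        direct = fit_mvar(ep.data[:, :, start : start + 175], 2)
        assert np.allclose(m.coeffs, direct.coeffs)


class TestAicOrderSelection:
    def test_aic_matches_direct_computation(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((4, 2, 60))
        for p in (1, 2, 3):
            assert aic(data, p) == pytest.approx(oracle_aic(data, p), rel=1e-9)

    def test_recovers_true_order_two(self):
        coeffs = np.zeros((2, 2, 2))
        coeffs[0] = [[0.5, 0.2], [0.1, 0.4]]
        coeffs[1] = [[-0.3, 0.0], [0.15, -0.25]]
        model = MVARModel(coeffs, np.eye(2))
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            x = mvar_generate(model, 40 * 200, seed=seed)
            data = np.stack([x[:, i * 200 : i * 200 + 175] for i in range(40)])
            ep = make_epochset(data, window=(0.0, 0.14))
            hits += select_order_aic(ep, range(1, 11)) == 2
        assert hits >= 0.8 * n_seeds

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_white_noise_selects_minimum_order(self, seed):
        rng = np.random.default_rng(seed)
        ep = make_epochset(rng.standard_normal((100, 3, 400)), window=(0.0, 0.32))
        assert select_order_aic(ep, range(1, 6)) == 1

    def test_empty_p_range(self):
        ep = make_epochset(np.random.default_rng(0).standard_normal((5, 2, 200)))
        with pytest.raises(ValueError, match="empty"):
            select_order_aic(ep, [])


class TestSpectralDecomposition:
    @staticmethod
    def _random_stable_model(seed, K=3, p=2):
        rng = np.random.default_rng(seed)
        while True:
            coeffs = rng.uniform(-0.4, 0.4, size=(p, K, K))
            model = MVARModel(coeffs, np.eye(K))
            if model.is_stable(0.95):
                return model

    def test_diagonal_model_has_no_cross_terms(self):
        coeffs = np.zeros((1, 3, 3))
        np.fill_diagonal(coeffs[0], [0.5, -0.3, 0.2])
        dec = spectral_decomposition(MVARModel(coeffs, np.eye(3)), default_freq_grid())
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(np.abs(dec.h[:, off]), 0.0, atol=1e-12)
        assert np.allclose(np.abs(dec.c[:, off]), 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partial_coherence_bounded_by_one(self, seed):
        model = self._random_stable_model(seed)
        dec = spectral_decomposition(model, default_freq_grid())
        assert np.all(np.abs(dec.c) <= 1.0 + 1e-9)

    def test_transfer_matches_adjugate_oracle(self):
        model = self._random_stable_model(42)
        freqs = default_freq_grid()
        dec = spectral_decomposition(model, freqs)
        for fi in (0, 15, 30):
            H = oracle_transfer(model.coeffs, freqs[fi], model.sampling_rate)
            assert np.allclose(dec.h[fi], H, atol=1e-10)

    def test_partial_coherence_matches_minors_oracle(self):
        model = self._random_stable_model(42)
        freqs = default_freq_grid()
        dec = spectral_decomposition(model, freqs)
        for fi in (0, 30):
            cmag = oracle_partial_coherence_mag(np.asarray(dec.s[fi]))
            assert np.allclose(np.abs(dec.c[fi]), cmag, atol=1e-9)

    def test_chain_partial_coherence_suppresses_indirect_link(self):
        # 1 -> 2 -> 3 with no direct 1 -> 3 term
        coeffs = np.zeros((1, 3, 3))
        coeffs[0] = [[0.5, 0, 0], [0.6, 0.4, 0], [0, 0.6, 0.3]]
        model = MVARModel(coeffs, np.eye(3))
        freqs = default_freq_grid()
        dec = spectral_decomposition(model, freqs)
        ratio = []
        for fi in range(len(freqs)):
            S = np.asarray(dec.s[fi])
            ordinary = oracle_ordinary_coherence_mag(S)[2, 0]
            partial = abs(dec.c[fi][2, 0])
            ratio.append(partial / ordinary)
        assert np.median(ratio) < 0.2

    def test_unstable_model_rejected(self):
        from ercflow.mvar import UnstableModelError

        with pytest.raises(UnstableModelError, match="radius"):
            spectral_decomposition(
                MVARModel(np.array([[[1.05]]]), np.eye(1)), default_freq_grid()
            )


class TestSddtf:
    def test_independent_channels_zero_offdiagonal(self):
        coeffs = np.zeros((1, 3, 3))
        np.fill_diagonal(coeffs[0], [0.5, -0.3, 0.2])
        dec = spectral_decomposition(MVARModel(coeffs, np.eye(3)), default_freq_grid())
        z = sddtf(dec)
        assert np.allclose(z, 0.0, atol=1e-10)

    def test_normalization_sums_to_one(self):
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = [[0.5, 0, 0], [0.4, 0.4, 0], [0, 0.35, 0.45]]
        coeffs[1] = [[-0.1, 0, 0], [0, -0.1, 0.15], [0, 0, -0.1]]
        dec = spectral_decomposition(MVARModel(coeffs, np.eye(3)), default_freq_grid())
        z = sddtf(dec)
        assert np.sum(z**2) == pytest.approx(1.0, abs=1e-10)
        assert np.all(z >= 0) and np.all(z <= 1)

    def test_unidirectional_bivariate_matches_oracle(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.5, 0.0], [0.5, 0.5]]  # 1 -> 2 only
        noise = np.eye(2)
        model = MVARModel(coeffs, noise)
        freqs = default_freq_grid()
        z = sddtf(spectral_decomposition(model, freqs))
        zo = oracle_sddtf(coeffs, noise, 1250.0, freqs)
        assert np.allclose(z, zo, atol=1e-10)
        assert np.all(z[1, 0] > 0)  # flow 1 -> 2 present across the band
        assert np.all(z[0, 1] < 1e-10)  # no reverse flow

    def test_oracle_equivalence_from_estimated_coefficients(self):
        """Pipeline SdDTF from a 500-trial fit vs oracle from true coefficients."""
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = [[0.5, 0, 0], [0.4, 0.4, 0], [0, 0.35, 0.45]]
        coeffs[1] = [[-0.1, 0, 0], [0, -0.1, 0.15], [0, 0, -0.1]]
        noise = np.diag([1.0, 0.8, 1.2])
        model = MVARModel(coeffs, noise)
        x = mvar_generate(model, 500 * 185, seed=3)
        data = np.stack([x[:, i * 185 : i * 185 + 175] for i in range(500)])
        est = fit_mvar(data, 2)
        freqs = default_freq_grid()
        zp = sddtf(spectral_decomposition(est, freqs))
        zo = oracle_sddtf(coeffs, noise, 1250.0, freqs)
        assert np.max(np.abs(zp - zo)) < 0.05

    def test_partialization_suppresses_indirect_flow(self):
        """In a 1->2->3 chain, SdDTF 1->3 is small relative to plain DTF 1->3."""
        coeffs = np.zeros((1, 3, 3))
        coeffs[0] = [[0.5, 0, 0], [0.6, 0.4, 0], [0, 0.6, 0.3]]
        model = MVARModel(coeffs, np.eye(3))
        freqs = default_freq_grid()
        z = sddtf(spectral_decomposition(model, freqs))
        dtf13 = np.array([oracle_dtf_mag(coeffs, f, 1250.0)[2, 0] for f in freqs])
        # compare on a common scale: each normalized by its own 2<-1 flow
        z21 = z[1, 0]
        dtf21 = np.array([oracle_dtf_mag(coeffs, f, 1250.0)[1, 0] for f in freqs])
        assert np.median(z[2, 0] / z21) < 0.3 * np.median(dtf13 / dtf21)


class TestSlidingSddtf:
    def test_window_count_and_range(self):
        rng = np.random.default_rng(0)
        ep = make_epochset(rng.standard_normal((30, 2, 1250)))
        ft = sliding_sddtf(ep, p=2)
        assert ft.z.shape[3] == 154
        assert np.all(ft.z >= 0) and np.all(ft.z <= 1)
        assert ft.times[0] == pytest.approx(-0.6 + 175 / 2 / 1250)

    def test_stationary_coupling_gives_flat_timecourse(self):
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.5, 0.0], [0.4, 0.4]]
        model = MVARModel(coeffs, np.eye(2))
        x = mvar_generate(model, 60 * 1260, seed=9)
        data = np.stack([x[:, i * 1260 : i * 1260 + 1250] for i in range(60)])
        ft = sliding_sddtf(make_epochset(data), p=1)
        tc = ft.z[1, 0].mean(axis=0)
        assert tc.std() / tc.mean() < 0.2

    def test_sufficiency_violation_raises_with_ratio(self):
        rng = np.random.default_rng(0)
        ep = make_epochset(rng.standard_normal((2, 12, 200)))
        with pytest.raises(ValueError, match="sufficiency"):
            sliding_sddtf(ep, p=6)

    def test_epoch_shorter_than_window(self):
        rng = np.random.default_rng(0)
        ep = make_epochset(rng.standard_normal((10, 2, 100)), window=(0.0, 0.08))
        with pytest.raises(ValueError, match="shorter"):
            sliding_sddtf(ep, p=1)

    def test_determinism(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((20, 2, 400))
        a = sliding_sddtf(make_epochset(data, window=(0.0, 0.32)), p=2)
        b = sliding_sddtf(make_epochset(data, window=(0.0, 0.32)), p=2)
        assert np.array_equal(a.z, b.z)


@given(
    hst.integers(min_value=1, max_value=50),
    hst.integers(min_value=1, max_value=30),
    hst.integers(min_value=1, max_value=500),
    hst.integers(min_value=1, max_value=500),
)
@settings(max_examples=50, deadline=None)
def test_sufficiency_ratio_formula(K, p, Ns, nt):
    res = check_sufficiency(K, p, Ns, nt)
    assert res.ratio == pytest.approx(K * (p + 1) / (Ns * nt))
    assert res.passed == (res.ratio < 0.1)
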