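import itertools

import numpy as np
import pytest

from oscdecode import (
    EpochSet,
    build_window_mask,
    constrained_forward_backward,
    fit_tuda,
    m_step_decoders,
    pca_reduce,
    state_onsets,
)
from oscdecode.synthgen import generate_switching_trials
from oscdecode.tuda import fit_state_alignment, tuda_accuracy_curve, infer_gamma


def enumerate_monotone_paths(T, K):
    """All left-to-right no-skip state sequences from state 0 to K-1."""
    for switches in itertools.combinations(range(1, T), K - 1):
        seq = np.zeros(T, dtype=int)
        for i, s in enumerate(switches):
            seq[s:] = i + 1
        yield seq


def brute_force_posterior(E, M, mask):
    T, K = E.shape
    gamma = np.zeros((T, K))
    total = 0.0
    for seq in enumerate_monotone_paths(T, K):
        if not all(mask.allowed[t, seq[t]] for t in range(T)):
            continue
        logp = sum(E[t, seq[t]] for t in range(T))
        logp += sum(np.log(M[seq[t], seq[t + 1]]) for t in range(T - 1))
        w = np.exp(logp)
        total += w
        for t in range(T):
            gamma[t, seq[t]] += w
    return gamma / total, np.log(total)


class TestWindowMask:
    def test_band_formula_worked_example(self):
        m = build_window_mask(12, 3, 1).allowed
        ranges = [(np.flatnonzero(m[:, k]) + 1) for k in range(3)]
        assert (ranges[0].min(), ranges[0].max()) == (1, 8)
        assert (ranges[1].min(), ranges[1].max()) == (1, 12)
        assert (ranges[2].min(), ranges[2].max()) == (5, 12)

    def test_large_slack_all_true(self):
        m = build_window_mask(10, 2, 2).allowed
        assert m.all()

    def test_every_time_has_a_state(self):
        for T, K in ((20, 5), (100, 8), (12, 12)):
            m = build_window_mask(T, K, 1).allowed
            assert m.any(axis=1).all()


class TestForwardBackward:
    @pytest.mark.parametrize("T,K,seed", [(6, 3, 0), (7, 2, 1), (12, 3, 2), (9, 3, 3)])
    def test_matches_brute_force_enumeration(self, T, K, seed):
        rng = np.random.default_rng(seed)
        E = rng.normal(size=(T, K))
        M = np.zeros((K, K))
        for k in range(K - 1):
            M[k, k], M[k, k + 1] = 0.6, 0.4
        M[K - 1, K - 1] = 1.0
        mask = build_window_mask(T, K, 1)
        gamma, logev = constrained_forward_backward(E, M, mask)
        g_oracle, logev_oracle = brute_force_posterior(E, M, mask)
        assert np.allclose(gamma, g_oracle, atol=1e-12)
        assert logev == pytest.approx(logev_oracle, abs=1e-10)

    def test_single_state(self):
        E = np.random.default_rng(0).normal(size=(5, 1))
        gamma, logev = constrained_forward_backward(E, np.array([[1.0]]))
        assert np.allclose(gamma, 1.0)
        assert logev == pytest.approx(E.sum())

    def test_endpoint_constraints(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(8, 4, 3))
        M = np.array([[0.5, 0.5, 0], [0, 0.5, 0.5], [0, 0, 1.0]])
        gamma, _ = constrained_forward_backward(E, M, build_window_mask(8, 3, 3))
        assert np.allclose(gamma[0, :, 0], 1.0)
        assert np.allclose(gamma[-1, :, -1], 1.0)
        assert np.allclose(gamma.sum(axis=2), 1.0)

    def test_dominant_emissions_pin_the_switch(self):
        """Emissions overwhelmingly favouring a switch at t*: the posterior
        switches exactly there (enumeration Viterbi oracle)."""
        T, K, tstar = 10, 2, 6
        E = np.full((T, K), -50.0)
        E[:tstar, 0] = 0.0
        E[tstar:, 1] = 0.0
        M = np.array([[0.8, 0.2], [0, 1.0]])
        gamma, _ = constrained_forward_backward(E, M, build_window_mask(T, K, K))
        hard = np.argmax(gamma, axis=1)
        assert np.array_equal(hard, (np.arange(T) >= tstar).astype(int))

    def test_infeasible_mask_rejected(self):
        E = np.zeros((3, 5))
        M = np.eye(5)
        with pytest.raises(ValueError):
            constrained_forward_backward(E, M)


class TestMStep:
    def test_two_state_weighted_normal_equations(self):
        """Hand-computable 2-state problem: gamma-weighted ridge solution
        checked against an explicit solve."""
        rng = np.random.default_rng(0)
        N, P, T = 12, 2, 6
        X = rng.normal(size=(N, P, T))
        y = rng.choice([-1.0, 1.0], size=N)
        gamma = rng.dirichlet([1, 1], size=(T, N))
        alpha, s2 = 0.5, 1.0
        means, covs, _ = m_step_decoders(X, y, gamma, alpha=alpha,
                                         noise_var=np.array([s2, s2]),
                                         equalize_sums=False)
        Xf = np.transpose(X, (2, 0, 1)).reshape(T * N, P)
        yf = np.tile(y, T)
        for k in range(2):
            w = gamma.reshape(T * N, 2)[:, k]
            A = alpha * np.eye(P) + (Xf * w[:, None]).T @ Xf / s2
            b = (Xf * w[:, None]).T @ yf / s2
            assert np.allclose(means[k], np.linalg.solve(A, b), atol=1e-8)

    def test_constraint_equalizes_sums(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3, 8))
        y = rng.choice([-1.0, 1.0], size=20)
        gamma = rng.dirichlet(np.ones(3), size=(8, 20))
        means, _, _ = m_step_decoders(X, y, gamma, equalize_sums=True)
        sums = means.sum(axis=1)
        assert np.allclose(sums, sums[0], atol=1e-8)

    def test_symmetric_states_get_identical_betas(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 2, 4))
        y = rng.choice([-1.0, 1.0], size=15)
        gamma = np.full((4, 15, 2), 0.5)
        means, _, _ = m_step_decoders(X, y, gamma)
        assert np.allclose(means[0], means[1], atol=1e-10)


class TestPCA:
    def test_exact_low_rank_data(self, rng):
        basis = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        scores = rng.normal(size=(20 * 30, 3))
        data = (scores @ basis.T).reshape(20, 30, 6).transpose(0, 2, 1)
        ep = EpochSet(data=data, fs=100.0, labels=np.zeros(20))
        red, pb = pca_reduce(ep, var_threshold=0.98)
        assert pb.n_pc == 3

    def test_explicit_n_pc_and_errors(self, small_epochs):
        epochs, _ = small_epochs
        red, pb = pca_reduce(epochs, n_pc=2)
        assert red.data.shape[1] == 2
        assert np.allclose(pb.components.T @ pb.components, np.eye(2), atol=1e-10)
        with pytest.raises(ValueError):
            pca_reduce(epochs, n_pc=99)

    def test_known_covariance_eigenratios(self, rng):
        evals = np.array([5.0, 3.0, 1.0, 0.5, 0.25])
        basis = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        scores = rng.normal(size=(40 * 100, 5)) * np.sqrt(evals)
        data = (scores @ basis.T).reshape(40, 100, 5).transpose(0, 2, 1)
        ep = EpochSet(data=data, fs=100.0, labels=np.zeros(40))
        _, pb = pca_reduce(ep, var_threshold=1.0)
        assert np.allclose(pb.explained_variance_ratio, evals / evals.sum(), atol=0.02)


class TestFit:
    def test_free_energy_monotone_and_invariants(self):
        epochs, truth = generate_switching_trials(
            n_trials=60, n_channels=12, n_time=60, n_states=3, seed=0
        )
        red, basis = pca_reduce(epochs, n_pc=8)
        fit = fit_tuda(red, epochs.labels, K=3, restarts=2, seed=0,
                       constraint_vector=basis.uniform_image)
        fe = fit.free_energy
        assert np.all(np.diff(fe) >= -1e-6 * (np.abs(fe[:-1]) + 1))
        assert np.allclose(fit.gamma.sum(axis=2), 1.0)
        assert np.allclose(fit.transitions.sum(axis=1), 1.0)
        # upper-bidiagonal transitions
        K = fit.K
        off = ~(np.eye(K, dtype=bool) | np.eye(K, k=1, dtype=bool))
        assert np.all(fit.transitions[off] == 0)
        # endpoint constraints
        assert np.all(np.argmax(fit.gamma[0], axis=1) == 0)
        assert np.all(np.argmax(fit.gamma[-1], axis=1) == K - 1)

    def test_k1_matches_pooled_regression(self):
        epochs, truth = generate_switching_trials(
            n_trials=40, n_channels=8, n_time=30, n_states=2, seed=1
        )
        red, _ = pca_reduce(epochs, n_pc=5)
        fit = fit_tuda(red, epochs.labels, K=1, restarts=1, seed=0)
        assert np.allclose(fit.gamma, 1.0)
        # pooled ridge on all samples should match the single decoder
        X = np.transpose(red.data, (2, 0, 1)).reshape(-1, 5)
        y = np.tile(np.where(epochs.labels == 1, 1.0, -1.0), 30)
        A = 0.1 * np.eye(5) + X.T @ X / fit.noise_var[0]
        expected = np.linalg.solve(A, X.T @ y / fit.noise_var[0])
        # the sum constraint is a no-op at K=1
        assert np.allclose(fit.betas[0], expected, atol=1e-6)

    def test_degeneracy_constraint_demonstration(self):
        """Classes with unequal same-sign DC offsets, EM started from the
        degenerate class-split configuration with tied noise: the coefficient
        -sum constraint releases the split, disabling it keeps the split."""
        rng = np.random.default_rng(0)
        N, C, T, K = 120, 10, 100, 2
        y = rng.choice([-1.0, 1.0], size=N)
        offset = np.where(y > 0, 2.0, 0.5)
        data = rng.normal(0, 1.0, size=(N, C, T)) + offset[:, None, None]
        ep = EpochSet(data=data, fs=250.0, labels=((y + 1) // 2).astype(int))
        g0 = np.zeros((T, N, K))
        for i in range(N):
            sw = 2 if y[i] > 0 else T - 1
            g0[:sw, i, 0] = 1
            g0[sw:, i, 1] = 1
        diffs = {}
        for eq in (True, False):
            fit = fit_tuda(ep, ep.labels, K=K, slack=K, restarts=1, seed=0,
                           equalize_sums=eq, init_gamma=g0, max_iter=100,
                           tie_noise=True)
            occ_a = fit.gamma[:, y > 0, :].mean(axis=(0, 1))
            occ_b = fit.gamma[:, y < 0, :].mean(axis=(0, 1))
            diffs[eq] = np.abs(occ_a - occ_b).max()
        assert diffs[True] < 0.2
        assert diffs[False] > 0.2


class TestOnsetsAndCurve:
    def test_hard_gamma_onsets(self):
        T, N, K = 20, 3, 3
        gamma = np.zeros((T, N, K))
        switch = [(5, 12), (8, 9), (1, 19)]
        for n, (s1, s2) in enumerate(switch):
            gamma[:s1, n, 0] = 1
            gamma[s1:s2, n, 1] = 1
            gamma[s2:, n, 2] = 1
        onsets = state_onsets(gamma)
        assert onsets.shape == (N, K - 1)
        for n, (s1, s2) in enumerate(switch):
            assert onsets[n, 0] == s1
            assert onsets[n, 1] == s2

    def test_never_active_state_is_nan(self):
        gamma = np.zeros((10, 1, 3))
        gamma[:5, 0, 0] = 1
        gamma[5:, 0, 2] = 1  # state 2 skipped in the hard path
        onsets = state_onsets(gamma)
        assert np.isnan(onsets[0, 0])
        assert onsets[0, 1] == 5

    def test_alignment_tracks_switching_onsets(self):
        """Label-free alignment recovers per-trial latency on data whose
        stages move together (global jitter)."""
        from oscdecode import SimConfig, generate_trials, lowpass_filter
        from oscdecode import split_components, standardize_trial
        cfg = SimConfig(n_trials=60, n_channels=8, noise_sd=0.5, seed=5)
        epochs, gt = generate_trials(cfg)
        comps = split_components(standardize_trial(lowpass_filter(epochs, 10.0)))
        red, _ = pca_reduce(
            EpochSet(data=comps.oscillatory, fs=250.0, labels=epochs.labels),
            var_threshold=0.98,
        )
        gamma, _ = fit_state_alignment(red.data)
        onsets = state_onsets(gamma)
        shift = gt.latency_shift * 250
        ok = np.isfinite(onsets[:, 2])
        assert np.corrcoef(onsets[ok, 2], shift[ok])[0, 1] > 0.6

    def test_accuracy_curve_exceeds_envelope_on_strong_effect(self):
        epochs, truth = generate_switching_trials(
            n_trials=60, n_channels=10, n_time=40, n_states=2,
            signal_scale=1.5, seed=2,
        )
        red, basis = pca_reduce(epochs, n_pc=6)
        res = tuda_accuracy_curve(red, epochs.labels, K=2, n_folds=3, n_perm=5,
                                  seed=0, constraint_vector=basis.uniform_image)
        mid = slice(5, 35)
        assert (res["accuracy"][mid] > res["envelope_max"][mid]).mean() > 0.5

    def test_infer_gamma_consistent_with_training(self):
        epochs, _ = generate_switching_trials(
            n_trials=30, n_channels=8, n_time=40, n_states=2, seed=3
        )
        red, basis = pca_reduce(epochs, n_pc=5)
        fit = fit_tuda(red, epochs.labels, K=2, restarts=1, seed=0)
        y = np.where(epochs.labels == 1, 1.0, -1.0)
        g = infer_gamma(fit, red.data, y)
        assert np.allclose(g, fit.gamma, atol=1e-8)
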