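import numpy as np
import pytest

from oscdecode import (
    CVScheme,
    SimConfig,
    TGM,
    compute_tgm,
    decode_timepoint,
    fit_ridge,
    generate_trials,
    lowpass_filter,
    ordered_pair_count,
    n_standard_decoders,
    split_components,
    standardize_trial,
    tgm_attribution,
    tgm_for_components,
    tgm_sections,
)
from oscdecode.synthgen import EpochSet


def test_bookkeeping_counts():
    assert ordered_pair_count(118) == 13806
    assert n_standard_decoders(250.0, 1.0) == 250


class TestStandardize:
    def test_mean_zero_sd_one(self, small_epochs):
        epochs, _ = small_epochs
        std = standardize_trial(epochs)
        assert np.all(np.abs(std.data.mean(axis=-1)) < 1e-12)
        assert np.all(np.abs(std.data.std(axis=-1) - 1) < 1e-12)

    def test_constant_channel_zeroed(self):
        data = np.random.default_rng(0).normal(size=(2, 2, 50))
        data[0, 1] = 4.2
        ep = EpochSet(data=data, fs=100.0, labels=np.zeros(2))
        std = standardize_trial(ep)
        assert np.all(std.data[0, 1] == 0)

    def test_idempotent(self, small_epochs):
        epochs, _ = small_epochs
        once = standardize_trial(epochs)
        twice = standardize_trial(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestRidge:
    def test_hand_solved_example(self):
        """(X'X + lam) b = X'y with X=[[1],[-1]], y=[1,-1], lam=1 -> b=2/3."""
        dec = fit_ridge(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), 1.0)
        assert dec.weights[0] == pytest.approx(2.0 / 3.0)

    def test_lam_zero_equals_ols(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.sign(rng.normal(size=30))
        y[y == 0] = 1
        dec = fit_ridge(X, y, 0.0)
        Xc = X - X.mean(0)
        beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(dec.weights, beta_ols, atol=1e-10)

    def test_huge_penalty_shrinks_weights(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.sign(rng.normal(size=40))
        y[y == 0] = 1
        dec = fit_ridge(X, y, 1e9)
        assert np.linalg.norm(dec.weights) < 1e-6

    def test_singular_unpenalized_rejected(self):
        X = np.ones((10, 2))  # rank 1 after centering -> rank 0
        y = np.array([1.0, -1.0] * 5)
        with pytest.raises(ValueError, match="lam"):
            fit_ridge(X, y, 0.0)


def _separable_epochs(n=60, c=4, t=20, margin=3.0, seed=0):
    # balanced classes: with an intercept, label imbalance alone lifts
    # accuracy to the majority fraction, so null calibration assumes balance
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.repeat([0, 1], n // 2))
    w = rng.normal(size=c)
    w /= np.linalg.norm(w)
    data = rng.normal(size=(n, c, t))
    data += margin * np.where(labels == 1, 1.0, -1.0)[:, None, None] * w[None, :, None]
    return EpochSet(data=data, fs=100.0, labels=labels), labels


class TestDecoding:
    def test_separable_classes_high_accuracy(self):
        epochs, labels = _separable_epochs()
        cv = CVScheme(n_outer=5, n_inner=3, lambdas=np.logspace(-2, 2, 5), seed=0)
        acc = decode_timepoint(epochs, labels, 5, cv)
        assert acc > 0.95

    def test_null_calibration_of_accuracy(self):
        """Permuted labels: accuracy within the binomial band around 0.5."""
        rng = np.random.default_rng(3)
        accs = []
        for r in range(20):
            epochs, labels = _separable_epochs(seed=r)
            perm = rng.permutation(labels)
            cv = CVScheme(n_outer=5, n_inner=3, lambdas=np.logspace(-2, 2, 5), seed=r)
            accs.append(decode_timepoint(epochs, perm, 5, cv))
        # mean of 20 runs x 60 trials: se ~ 0.014
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_feature_scale_invariance(self):
        epochs, labels = _separable_epochs()
        cv = CVScheme(n_outer=5, n_inner=3, lambdas=np.logspace(-2, 2, 5), seed=0)
        a1 = decode_timepoint(epochs, labels, 3, cv)
        scaled = epochs.copy_with(epochs.data * 2.0)
        a2 = decode_timepoint(scaled, labels, 3, cv)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_tgm_diagonal_matches_timepoint_decoding(self):
        epochs, labels = _separable_epochs(n=40, t=8)
        cv = CVScheme(n_outer=4, n_inner=3, lambdas=np.logspace(-1, 1, 3), seed=1)
        tgm = compute_tgm(epochs, labels, cv)
        for t in (0, 3, 7):
            assert tgm.accuracy[t, t] == pytest.approx(
                decode_timepoint(epochs, labels, t, cv), abs=1e-12
            )

    def test_tgm_determinism(self):
        epochs, labels = _separable_epochs(n=30, t=6)
        cv = CVScheme(n_outer=3, n_inner=2, lambdas=np.array([1.0]), seed=7)
        t1 = compute_tgm(epochs, labels, cv)
        t2 = compute_tgm(epochs, labels, cv)
        assert np.array_equal(t1.accuracy, t2.accuracy)

    def test_stationary_effect_generalizes(self):
        """A constant additive class effect yields off-diagonal accuracy
        close to the diagonal (stationary generative effect)."""
        epochs, labels = _separable_epochs(n=80, t=12, margin=2.0, seed=5)
        cv = CVScheme(n_outer=5, n_inner=3, lambdas=np.logspace(-1, 1, 3), seed=0)
        tgm = compute_tgm(epochs, labels, cv)
        diag = np.diag(tgm.accuracy).mean()
        off = tgm.accuracy[~np.eye(12, dtype=bool)].mean()
        assert abs(diag - off) < 0.05


class TestComponentsTGM:
    def test_phase_only_effect_power_at_chance(self):
        """Constant-amplitude phase opposition: envelope is class-invariant,
        so the power TGM stays at chance while the oscillatory TGM decodes."""
        cfg = SimConfig(n_trials=60, n_channels=4, fs=100.0, noise_sd=0.4,
                        relative_phase=np.pi * np.ones(4),
                        center_relative_phase=False,
                        latency_jitter_sd=0.0, trend_amplitude=0.0, seed=8)
        epochs, _ = generate_trials(cfg)
        comps = split_components(standardize_trial(lowpass_filter(epochs, 10.0)))
        cv = CVScheme(n_outer=4, n_inner=3, lambdas=np.logspace(-1, 1, 3), seed=0)
        times = np.arange(15, 60, 3)
        tgms = tgm_for_components(comps, epochs.attributes["animacy"], cv,
                                  train_times=times, test_times=times)
        assert np.diag(tgms["oscillatory"].accuracy).mean() > 0.8
        assert abs(np.diag(tgms["power"].accuracy).mean() - 0.5) < 0.1

    def test_identical_seeds_identical_tgms(self, small_epochs):
        epochs, _ = small_epochs
        comps = split_components(standardize_trial(lowpass_filter(epochs, 10.0)))
        cv = CVScheme(n_outer=3, n_inner=2, lambdas=np.array([1.0]), seed=3)
        times = np.arange(0, 250, 25)
        a = tgm_for_components(comps, epochs.attributes["animacy"], cv,
                               train_times=times, test_times=times)
        b = tgm_for_components(comps, epochs.attributes["animacy"], cv,
                               train_times=times, test_times=times)
        for name in a:
            assert np.array_equal(a[name].accuracy, b[name].accuracy)


class TestAttributionAndSections:
    def test_exact_affine_mixture_r2_one(self, rng):
        a = TGM(accuracy=rng.uniform(0.3, 0.9, size=(20, 20)))
        b = TGM(accuracy=rng.uniform(0.3, 0.9, size=(20, 20)))
        target = TGM(accuracy=np.clip(0.6 * a.accuracy + 0.3 * b.accuracy + 0.05, 0, 1))
        assert tgm_attribution(target, [a, b]) == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_r2_near_zero(self, rng):
        a = TGM(accuracy=rng.uniform(0.3, 0.9, size=(60, 60)))
        target = TGM(accuracy=rng.uniform(0.3, 0.9, size=(60, 60)))
        assert tgm_attribution(target, [a]) < 0.05

    def test_constructed_mixture_r2_recovered(self):
        """target = 0.7 A + 0.3 B + noise tuned to R^2 = 0.8; the analytic
        construction is the oracle for the recovered R^2."""
        rng = np.random.default_rng(0)
        r2s = []
        for rep in range(100):
            a = rng.uniform(0.0, 1.0, size=(30, 30))
            b = rng.uniform(0.0, 1.0, size=(30, 30))
            signal = 0.7 * a + 0.3 * b
            sig_var = signal.var()
            noise_var = sig_var * (1 - 0.8) / 0.8
            target = signal + rng.normal(0, np.sqrt(noise_var), size=signal.shape)
            tt = (target - target.min()) / (target.max() - target.min())
            r2s.append(tgm_attribution(
                TGM(accuracy=tt),
                [TGM(accuracy=a), TGM(accuracy=b)],
            ))
        assert np.mean(r2s) == pytest.approx(0.80, abs=0.03)

    def test_sections_symmetric_and_chance(self):
        flat = TGM(accuracy=np.full((40, 40), 0.5))
        s = tgm_sections(flat, t=20, half_window=5)
        assert s["diagonal_mean"] == pytest.approx(0.5)
        assert s["offdiagonal_mean"] == pytest.approx(0.5)
        sym = np.full((40, 40), 0.5)
        sym[18:23, 18:23] = 0.9
        s2 = tgm_sections(TGM(accuracy=sym), t=20, half_window=4)
        sec = s2["section"]
        assert np.allclose(sec, sec[::-1], equal_nan=True)

    def test_section_truncated_at_edges(self):
        tgm = TGM(accuracy=np.full((10, 10), 0.5))
        s = tgm_sections(tgm, t=1, half_window=4)
        assert np.isnan(s["section"][0])
        assert s["section_valid"].sum() < len(s["section"])
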