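"""Temporally unconstrained decoding analysis (TUDA): K regression decoders
with per-trial activation time courses.

The model assumes that at each time point t of trial n exactly one of K
linear decoders predicts the label y_n from the multichannel sample x_tn,
with Gaussian residuals. The hidden decoder sequence is left-to-right
(k -> k or k -> k+1 only), every trial starting with decoder 1 and ending
with decoder K, so trial-to-trial differences in the activation times
absorb *global* latency differences while the decoder weights capture the
spatial (relative, cross-channel) pattern. Three constraints prevent the
degenerate solution where decoders specialize by label instead of by time:

1. the strict left-to-right sequence with fixed endpoints;
2. a window mask forbidding each decoder from activating too far from its
   nominal position k/K of the trial;
3. all decoders' regression weights are constrained to sum to a common
   value, so no decoder can "take" trials via an overall offset.

Inference is variational: Gaussian posteriors over decoder weights,
exact constrained forward-backward over the state paths with expected
log-predictive emissions, point updates for noise variances and the
transition matrix, and a free-energy (evidence lower bound) trace that is
non-decreasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .synthgen import EpochSet

__all__ = [
    "TUDAFit",
    "PCABasis",
    "StateWindowMask",
    "pca_reduce",
    "build_window_mask",
    "constrained_forward_backward",
    "m_step_decoders",
    "fit_tuda",
    "state_onsets",
    "tuda_accuracy_curve",
]

_NEG_INF = -1e30  # finite stand-in for log(0); keeps array ops NaN-free


@dataclass
class PCABasis:
    components: np.ndarray  # (C, n_pc), orthonormal columns
    explained_variance_ratio: np.ndarray
    n_pc: int

    @property
    def uniform_image(self) -> np.ndarray:
        """Projection of the all-ones channel vector into component space.

        The decoder-sum constraint uses this direction on reduced data, so
        "coefficients sum to the same value" keeps referring to the
        channels rather than to the rotated coordinates.
        """
        return self.components.T @ np.ones(self.components.shape[0])


@dataclass
class StateWindowMask:
    """T x K boolean matrix of when each decoder may be active."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool)
        if not self.allowed.any(axis=1).all():
            raise AssertionError("window mask leaves some time point with no state")


@dataclass
class TUDAFit:
    K: int
    betas: np.ndarray  # (K, P) posterior means
    beta_covs: np.ndarray  # (K, P, P)
    gamma: np.ndarray  # (T, N, K)
    transitions: np.ndarray  # (K, K) row-stochastic, upper-bidiagonal
    noise_var: np.ndarray  # (K,)
    free_energy: np.ndarray  # per-iteration trace
    mask: StateWindowMask | None = None
    config: dict = field(default_factory=dict)


def pca_reduce(
    epochs: EpochSet,
    var_threshold: float | None = 0.98,
    n_pc: int | None = None,
) -> tuple[EpochSet, PCABasis]:
    """Project channels onto the leading principal components.

    PCA is computed over the (trial*time) x channel matrix; the number of
    components is the smallest reaching ``var_threshold`` cumulative
    explained variance, unless ``n_pc`` is given explicitly.
    """
    n, c, t = epochs.data.shape
    if n_pc is not None:
        if n_pc > c:
            raise ValueError(f"n_pc={n_pc} exceeds channel count {c}")
        k = n_pc
    else:
        if not 0 < var_threshold <= 1:
            raise ValueError("var_threshold must be in (0, 1]")
        k = None
    flat = np.transpose(epochs.data, (0, 2, 1)).reshape(n * t, c)
    pca = PCA(n_components=c, svd_solver="full")
    pca.fit(flat)
    evr = pca.explained_variance_ratio_
    if k is None:
        k = int(np.searchsorted(np.cumsum(evr), var_threshold - 1e-12) + 1)
        k = min(k, c)
    comp = pca.components_[:k].T  # (C, k)
    reduced = np.einsum("nct,ck->nkt", epochs.data - flat.mean(axis=0)[None, :, None], comp)
    red = EpochSet(
        data=reduced,
        fs=epochs.fs,
        labels=epochs.labels.copy(),
        attributes={key: v.copy() for key, v in epochs.attributes.items()},
        channel_ids=[f"pc{i:03d}" for i in range(k)],
    )
    return red, PCABasis(components=comp, explained_variance_ratio=evr, n_pc=k)


def build_window_mask(T: int, K: int, slack: int = 1) -> StateWindowMask:
    """Allowed activation windows: decoder k (1-based) may be active at the
    1-based time points t with (k-1-slack)*T/K < t <= (k+slack)*T/K."""
    if K > T:
        raise ValueError(f"K={K} exceeds T={T}")
    if slack < 1:
        raise ValueError("slack must be >= 1")
    t1 = np.arange(1, T + 1)[:, None]  # 1-based time
    k1 = np.arange(1, K + 1)[None, :]
    lower = (k1 - 1 - slack) * T / K
    upper = (k1 + slack) * T / K
    allowed = (t1 > lower) & (t1 <= upper)
    return StateWindowMask(allowed=allowed)


def _log_bidiagonal(M: np.ndarray) -> np.ndarray:
    logM = np.full_like(M, _NEG_INF)
    pos = M > 0
    logM[pos] = np.log(M[pos])
    return logM


def constrained_forward_backward(
    log_emissions: np.ndarray,
    M: np.ndarray,
    mask: StateWindowMask | np.ndarray | None = None,
    return_xi: bool = False,
):
    """Exact posterior over monotone left-to-right state paths.

    ``log_emissions`` is (T, K) for one trial or (T, N, K) for a batch; the
    path starts in state 1, ends in state K, moves only k -> k or k -> k+1,
    and has zero probability wherever the window mask is False.

    Returns ``(gamma, log_evidence)`` with gamma matching the emission
    shape; with ``return_xi=True`` also the expected transition counts
    summed over time and trials, as a (K, K) matrix.
    """
    E = np.asarray(log_emissions, dtype=float)
    single = E.ndim == 2
    if single:
        E = E[:, None, :]
    T, N, K = E.shape
    if mask is not None:
        allowed = mask.allowed if isinstance(mask, StateWindowMask) else np.asarray(mask, bool)
        E = np.where(allowed[:, None, :], E, _NEG_INF)
    if K > T:
        raise ValueError(f"no admissible path: K={K} > T={T}")
    logM = _log_bidiagonal(np.asarray(M, dtype=float))

    # forward, with running normalization for numerical stability
    alpha = np.full((T, N, K), _NEG_INF)
    alpha[0, :, 0] = E[0, :, 0]
    log_c = np.zeros(N)
    for t in range(1, T):
        stay = alpha[t - 1] + logM.diagonal()[None, :]
        move = np.full((N, K), _NEG_INF)
        move[:, 1:] = alpha[t - 1, :, :-1] + np.diag(logM, 1)[None, :]
        a = np.logaddexp(stay, move) + E[t]
        m = a.max(axis=1)
        finite = m > _NEG_INF / 2
        if not finite.all():
            raise ValueError("no admissible path under the given mask/transitions")
        a -= m[:, None]
        log_c += m
        alpha[t] = a
    log_evidence = log_c + alpha[-1, :, -1]
    if not np.all(np.isfinite(log_evidence)):
        raise ValueError("no admissible path reaching state K at the final time")

    beta = np.full((T, N, K), _NEG_INF)
    beta[-1, :, -1] = 0.0
    for t in range(T - 2, -1, -1):
        nxt = E[t + 1] + beta[t + 1]  # (N, K)
        stay = nxt + logM.diagonal()[None, :]
        move = np.full((N, K), _NEG_INF)
        move[:, :-1] = nxt[:, 1:] + np.diag(logM, 1)[None, :]
        b = np.logaddexp(stay, move)
        b -= b.max(axis=1)[:, None]
        beta[t] = b

    log_gamma = alpha + beta
    log_gamma -= log_gamma.max(axis=2, keepdims=True)
    gamma = np.exp(np.maximum(log_gamma, _NEG_INF))
    gamma /= gamma.sum(axis=2, keepdims=True)

    if not return_xi:
        if single:
            return gamma[:, 0, :], float(log_evidence[0])
        return gamma, log_evidence

    # expected transition counts (normalized per trial/time, summed over both)
    xi = np.zeros((K, K))
    for t in range(T - 1):
        nxt = E[t + 1] + beta[t + 1]
        stay = alpha[t] + logM.diagonal()[None, :] + nxt
        move = np.full((N, K - 1), _NEG_INF)
        move = alpha[t, :, :-1] + np.diag(logM, 1)[None, :] + nxt[:, 1:]
        both = np.concatenate([stay, move], axis=1)
        mx = both.max(axis=1, keepdims=True)
        w = np.exp(both - mx)
        w /= w.sum(axis=1, keepdims=True)
        xi[np.arange(K), np.arange(K)] += w[:, :K].sum(axis=0)
        xi[np.arange(K - 1), np.arange(1, K)] += w[:, K:].sum(axis=0)
    if single:
        return gamma[:, 0, :], float(log_evidence[0]), xi
    return gamma, log_evidence, xi


def m_step_decoders(
    X: np.ndarray,
    y: np.ndarray,
    gamma: np.ndarray,
    alpha: float = 0.1,
    noise_var: np.ndarray | None = None,
    equalize_sums: bool = True,
    constraint_vector: np.ndarray | None = None,
    tie_noise: bool = False,
    min_occupancy: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Responsibility-weighted Bayesian ridge update of the K decoders.

    ``X``: (N, P, T) reduced data; ``y``: (N,) labels in {-1, +1}; ``gamma``:
    (T, N, K). Each decoder's posterior is Gaussian with prior N(0, 1/alpha I).
    With ``equalize_sums`` the posterior means are then moved, along the
    minimum-loss direction given by their posterior covariances, onto the
    subspace where every decoder's coefficients sum to the same value (the
    anti-degeneracy constraint: no decoder may exploit a spatially uniform
    signal offset differently from the others). When the features are a
    rotation of the channels (e.g. principal components), pass the image of
    the uniform channel vector as ``constraint_vector`` so the constraint
    keeps its meaning in the rotated basis; the default (all ones)
    constrains the literal coefficient sums. Returns (means (K,P),
    covs (K,P,P), noise_vars (K,)).
    """
    T, N, K = gamma.shape
    P = X.shape[1]
    if noise_var is None:
        noise_var = np.ones(K)
    Xf = np.transpose(X, (2, 0, 1)).reshape(T * N, P)  # sample (t, n)
    yf = np.tile(y, T)  # broadcast over time: y constant within trial
    gf = gamma.reshape(T * N, K)
    occ = gf.sum(axis=0)  # (K,)
    means = np.zeros((K, P))
    covs = np.zeros((K, P, P))
    new_noise = np.zeros(K)
    for k in range(K):
        w = gf[:, k]
        if occ[k] < min_occupancy:
            covs[k] = np.eye(P) / alpha
            new_noise[k] = noise_var[k]
            continue
        Xw = Xf * w[:, None]
        A = alpha * np.eye(P) + (Xw.T @ Xf) / noise_var[k]
        S = np.linalg.inv(A)
        means[k] = S @ (Xw.T @ yf) / noise_var[k]
        covs[k] = S

    if equalize_sums:
        u = np.ones(P) if constraint_vector is None else np.asarray(constraint_vector, float)
        sums = means @ u
        v = np.einsum("p,kpq,q->k", u, covs, u)  # u' S_k u
        v = np.maximum(v, 1e-12)
        c = float(np.sum(sums / v) / np.sum(1.0 / v))
        for k in range(K):
            means[k] -= covs[k] @ u * (sums[k] - c) / v[k]

    for k in range(K):
        w = gf[:, k]
        if occ[k] < min_occupancy:
            new_noise[k] = noise_var[k]
            continue
        resid = yf - Xf @ means[k]
        quad = np.einsum("ip,pq,iq->i", Xf, covs[k], Xf)
        # inverse-gamma prior a0=b0=1e-3 keeps the variance away from 0
        new_noise[k] = (1e-3 + 0.5 * np.sum(w * (resid**2 + quad))) / (1e-3 + 0.5 * occ[k])
    if tie_noise:
        # pooled residual variance shared by all decoders
        live = occ >= min_occupancy
        pooled = float(np.sum(new_noise[live] * occ[live]) / np.sum(occ[live]))
        new_noise[:] = pooled
    return means, covs, new_noise


def _expected_log_emissions(X, y, means, covs, noise_var):
    """E_q[log N(y | x'b_k, s_k^2)] for every (t, n, k)."""
    pred = np.einsum("npt,kp->tnk", X, means)
    quad = np.einsum("npt,kpq,nqt->tnk", X, covs, X)
    resid2 = (y[None, :, None] - pred) ** 2
    return -0.5 * (np.log(2 * np.pi * noise_var)[None, None, :] + (resid2 + quad) / noise_var[None, None, :])


def _kl_gauss(means, covs, alpha):
    """Sum over states of KL(q(b_k) || N(0, 1/alpha I))."""
    K, P = means.shape
    kl = 0.0
    for k in range(K):
        sign, logdet = np.linalg.slogdet(covs[k])
        kl += 0.5 * (alpha * (np.trace(covs[k]) + means[k] @ means[k]) - P - P * np.log(alpha) - logdet)
    return kl


def fit_tuda(
    epochs: EpochSet | np.ndarray,
    labels: np.ndarray | None = None,
    K: int = 8,
    slack: int = 1,
    alpha: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-6,
    restarts: int = 3,
    seed: int = 0,
    equalize_sums: bool = True,
    constraint_vector: np.ndarray | None = None,
    tie_noise: bool = False,
    init_gamma: np.ndarray | None = None,
) -> TUDAFit:
    """Fit the constrained decoder-sequence model by variational inference.

    ``epochs`` is an EpochSet (or raw (N, P, T) array) of — typically —
    PCA-reduced oscillatory-component data; ``labels`` any binary coding
    (internally mapped to -1/+1; defaults to the epochs' animacy attribute).
    Alternates the exact constrained forward-backward E-step with decoder,
    noise and transition M-steps until the free energy changes by less than
    ``tol`` (relative) or ``max_iter`` is reached. ``restarts`` runs with
    jittered initializations keep the best free energy.
    """
    if isinstance(epochs, EpochSet):
        X = epochs.data
        if labels is None:
            labels = epochs.attributes["animacy"]
    else:
        X = np.asarray(epochs, dtype=float)
        if labels is None:
            raise ValueError("labels required for raw-array input")
    N, P, T = X.shape
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must have exactly 2 classes")
    y = np.where(np.asarray(labels) == classes[1], 1.0, -1.0)
    if K < 1:
        raise ValueError("K must be >= 1")
    mask = build_window_mask(T, K, slack)
    rng = np.random.default_rng(seed)

    best: TUDAFit | None = None
    for r in range(max(restarts, 1)):
        if init_gamma is not None:
            gamma = np.array(init_gamma, dtype=float)
            if gamma.shape != (T, N, K):
                raise ValueError(f"init_gamma must be (T={T}, N={N}, K={K})")
        else:
            centers = (np.arange(K) + 0.5) * T / K
            if r > 0:
                centers = centers + rng.normal(0, T / (4 * K), size=K)
            width = T / K
            g0 = np.exp(-0.5 * ((np.arange(T)[:, None] - centers[None, :]) / width) ** 2)
            g0 = np.where(mask.allowed, g0, 0.0)
            g0 /= g0.sum(axis=1, keepdims=True)
            gamma = np.repeat(g0[:, None, :], N, axis=1)

        M = np.zeros((K, K))
        idx = np.arange(K - 1)
        M[idx, idx] = 1 - K / T
        M[idx, idx + 1] = K / T
        M[K - 1, K - 1] = 1.0

        noise_var = np.ones(K)
        trace = []
        means = covs = None
        for it in range(max_iter):
            means, covs, noise_var = m_step_decoders(
                X, y, gamma, alpha=alpha, noise_var=noise_var,
                equalize_sums=equalize_sums, constraint_vector=constraint_vector,
                tie_noise=tie_noise,
            )
            E = _expected_log_emissions(X, y, means, covs, noise_var)
            gamma, log_ev, xi = constrained_forward_backward(E, M, mask, return_xi=True)
            fe = float(np.sum(log_ev) - _kl_gauss(means, covs, alpha))
            if not np.isfinite(fe):
                raise RuntimeError(f"non-finite free energy at iteration {it}: trace={trace}")
            trace.append(fe)
            # transition update (Dirichlet(1) prior on the two allowed moves)
            M = np.zeros((K, K))
            for k in range(K - 1):
                stay, move = xi[k, k] + 1.0, xi[k, k + 1] + 1.0
                M[k, k] = stay / (stay + move)
                M[k, k + 1] = move / (stay + move)
            M[K - 1, K - 1] = 1.0
            if it > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
                break
        # final E-step so the stored gamma is consistent with the stored
        # (final) decoders, noise variances and transition matrix
        E = _expected_log_emissions(X, y, means, covs, noise_var)
        gamma, _ = constrained_forward_backward(E, M, mask)
        fit = TUDAFit(
            K=K,
            betas=means,
            beta_covs=covs,
            gamma=gamma,
            transitions=M,
            noise_var=noise_var,
            free_energy=np.asarray(trace),
            mask=mask,
            config={"alpha": alpha, "slack": slack, "seed": seed, "restart": r,
                    "classes": classes.tolist()},
        )
        if best is None or fit.free_energy[-1] > best.free_energy[-1]:
            best = fit
    return best


def state_onsets(gamma: np.ndarray) -> np.ndarray:
    """First activation time (samples) of each decoder k >= 2, per trial.

    Activation uses the argmax rule (ties to the lowest k). Decoder 1 is
    excluded — it always starts at the first time point. States that never
    win in a trial yield NaN.
    """
    T, N, K = gamma.shape
    hard = np.argmax(gamma, axis=2)  # (T, N)
    onsets = np.full((N, K - 1), np.nan)
    for k in range(1, K):
        active = hard == k  # (T, N)
        any_active = active.any(axis=0)
        first = active.argmax(axis=0)
        onsets[any_active, k - 1] = first[any_active]
    return onsets


def infer_gamma(fit: TUDAFit, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """E-step only: state time courses for (possibly new) trials."""
    E = _expected_log_emissions(X, y, fit.betas, fit.beta_covs, fit.noise_var)
    gamma, _ = constrained_forward_backward(E, fit.transitions, fit.mask)
    return gamma


def estimate_trial_lags(X: np.ndarray, max_lag: int, n_iter: int = 4) -> np.ndarray:
    """Per-trial global latency (samples) by template cross-correlation.

    The template is the across-trial average; it is re-estimated from the
    re-aligned trials ``n_iter`` times. Label-free by construction.
    """
    N, P, T = X.shape
    lags = np.zeros(N, dtype=int)
    grid = np.arange(-max_lag, max_lag + 1)
    for _ in range(n_iter):
        aligned = np.empty_like(X)
        for i in range(N):
            aligned[i] = np.roll(X[i], -lags[i], axis=-1)
        template = aligned.mean(axis=0)
        scores = np.empty((N, grid.size))
        for gi, L in enumerate(grid):
            if L >= 0:
                scores[:, gi] = np.einsum("npt,pt->n", X[:, :, L:], template[:, : T - L])
            else:
                scores[:, gi] = np.einsum("npt,pt->n", X[:, :, : T + L], template[:, -L:])
        lags = grid[np.argmax(scores, axis=1)]
    return lags


def fit_state_alignment(
    X: np.ndarray,
    K: int = 8,
    slack: int = 1,
    max_iter: int = 100,
    tol: float = 1e-6,
    lag_init: bool = True,
    max_lag: int | None = None,
    align_on: str = "envelope",
    refine: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-free left-to-right temporal alignment of the trials.

    Same constrained lattice as the decoder-sequence model (monotone
    k -> k/k+1 paths, fixed endpoints, window mask) but with per-state
    Gaussian observation means over the data x itself and no label term, fit
    by EM. The resulting state time courses track each trial's response
    latency as a function of the data alone, which makes them a valid
    realignment for label-permutation tests: permuting the labels cannot
    change the windows, so the tests stay exactly calibrated under the null.

    With ``align_on='envelope'`` (default) both the lag estimate and the EM
    observations use the per-trial amplitude envelope (centered within each
    trial): the envelope is aperiodic, so latency is identifiable, whereas
    alignment on the raw band-limited signal is ambiguous modulo the carrier
    period. With ``lag_init`` (default) the state ramp of each trial starts
    shifted by a per-trial global lag estimated by iterated template
    cross-correlation, so every state inherits the trial's overall latency
    and EM only refines the per-state timing.

    Returns ``(gamma (T, N, K), state_means (K, P))``.
    """
    from scipy.signal import hilbert

    X = np.asarray(X, dtype=float)
    N, P, T = X.shape
    if align_on == "envelope":
        feats = np.abs(hilbert(X, axis=-1))
        feats -= feats.mean(axis=-1, keepdims=True)
    elif align_on == "signal":
        feats = X
    else:
        raise ValueError("align_on must be 'envelope' or 'signal'")
    mask = build_window_mask(T, K, slack)
    centers = (np.arange(K) + 0.5) * T / K
    width = T / K
    if lag_init:
        lags = estimate_trial_lags(feats, max_lag=max_lag or max(int(0.15 * T), 1))
    else:
        lags = np.zeros(N, dtype=int)
    tt = np.arange(T)[:, None, None]
    g0 = np.exp(
        -0.5 * ((tt - (centers[None, None, :] + lags[None, :, None])) / width) ** 2
    )
    g0 = np.where(mask.allowed[:, None, :], g0, 0.0)
    g0 /= g0.sum(axis=2, keepdims=True)
    gamma = g0
    M = np.zeros((K, K))
    idx = np.arange(K - 1)
    M[idx, idx] = 1 - K / T
    M[idx, idx + 1] = K / T
    M[K - 1, K - 1] = 1.0
    Xf = np.transpose(feats, (2, 0, 1)).reshape(T * N, P)
    trace: list[float] = []
    mu = np.zeros((K, P))
    for it in range(max_iter if refine else 0):
        gf = gamma.reshape(T * N, K)
        occ = np.maximum(gf.sum(axis=0), 1e-9)
        mu = (gf.T @ Xf) / occ[:, None]
        d2 = ((Xf[:, None, :] - mu[None, :, :]) ** 2).sum(axis=-1)  # (TN, K)
        tau2 = (gf * d2).sum(axis=0) / (P * occ) + 1e-9
        E = (-(0.5 * P) * np.log(2 * np.pi * tau2)[None, :] - d2 / (2 * tau2[None, :]))
        gamma, log_ev, xi = constrained_forward_backward(
            E.reshape(T, N, K), M, mask, return_xi=True
        )
        trace.append(float(np.sum(log_ev)))
        M = np.zeros((K, K))
        for k in range(K - 1):
            stay, move = xi[k, k] + 1.0, xi[k, k + 1] + 1.0
            M[k, k] = stay / (stay + move)
            M[k, k + 1] = move / (stay + move)
        M[K - 1, K - 1] = 1.0
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            break
    return gamma, mu


def unsupervised_gamma(fit: TUDAFit, X: np.ndarray) -> np.ndarray:
    """State time courses inferred without the labels.

    Emissions marginalize the label out with equal class weights,
    log p(x active under k) = logsumexp_y [log p(y | x, b_k)] - log 2, so the
    resulting time courses are a function of the data alone. Downstream
    label-permutation tests on onsets or state-aligned windows derived from
    these time courses are exactly valid under the null: permuting labels
    cannot change the windows. Label-dependent (supervised) time courses
    would couple the windows to the very labels being permuted and inflate
    false positives.
    """
    N = X.shape[0]
    Ep = _expected_log_emissions(X, np.ones(N), fit.betas, fit.beta_covs, fit.noise_var)
    Em = _expected_log_emissions(X, -np.ones(N), fit.betas, fit.beta_covs, fit.noise_var)
    E = np.logaddexp(Ep, Em) - np.log(2.0)
    gamma, _ = constrained_forward_backward(E, fit.transitions, fit.mask)
    return gamma


def tuda_accuracy_curve(
    epochs: EpochSet | np.ndarray,
    labels: np.ndarray,
    K: int = 8,
    n_folds: int = 5,
    n_perm: int = 20,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, np.ndarray]:
    """Cross-validated per-time-point accuracy of the decoder mixture, with a
    max-over-permutations significance envelope.

    For each fold the model is fit on the training trials; held-out trials
    get state time courses from the E-step, and the prediction at time t is
    the responsibility-weighted mixture of the K decoders. The envelope is
    the per-t maximum accuracy over ``n_perm`` label-permuted refits.
    """
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    N, P, T = X.shape
    classes = np.unique(labels)
    y = np.where(np.asarray(labels) == classes[1], 1.0, -1.0)
    rng = np.random.default_rng(seed)

    def _cv_curve(y_use):
        folds = _simple_folds(N, n_folds, rng)
        correct = np.zeros(T)
        for tr, te in folds:
            fit = fit_tuda(X[tr], (y_use[tr] > 0).astype(int), K=K,
                           restarts=1, seed=seed, **fit_kwargs)
            g_te = infer_gamma(fit, X[te], y_use[te])
            pred = np.einsum("tnk,npt,kp->tn", g_te, X[te], fit.betas)
            sgn = np.sign(pred)
            correct += ((sgn == y_use[te][None, :]).astype(float)
                        + 0.5 * (sgn == 0)).sum(axis=1)
        return correct / N

    observed = _cv_curve(y)
    envelope = np.zeros((n_perm, T))
    for p in range(n_perm):
        envelope[p] = _cv_curve(rng.permutation(y))
    return {
        "accuracy": observed,
        "envelope_max": envelope.max(axis=0) if n_perm else np.full(T, np.nan),
        "envelope": envelope,
    }


def _simple_folds(n, k, rng):
    order = rng.permutation(n)
    return [(np.setdiff1d(np.arange(n), te), te) for te in np.array_split(order, k)]
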