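"""Time-resolved ridge decoding, temporal generalization matrices (TGMs),
and TGM component-attribution analyses.

One L2-penalized linear regression ("ridge") decoder is trained per time
point on per-trial-standardized data, with labels encoded -1/+1 and the
penalty chosen by nested cross-validation (inner selection by mean squared
error). The TGM entry (t, t') is the accuracy of the decoder trained at t
applied to held-out trials at t'; its diagonal is conventional time-resolved
decoding. Attribution regressions quantify how much of the original
signal's TGM is explained by the component TGMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, KFold
from scipy.signal import hilbert

from .synthgen import EpochSet
from .decompose import SignalComponents

__all__ = [
    "CVScheme",
    "TGM",
    "RidgeDecoder",
    "standardize_trial",
    "fit_ridge",
    "decode_timepoint",
    "compute_tgm",
    "tgm_for_components",
    "tgm_attribution",
    "tgm_sections",
    "ordered_pair_count",
    "n_standard_decoders",
]


def ordered_pair_count(n_categories: int) -> int:
    """Number of ordered stimulus pairs (each unordered pair both ways)."""
    return n_categories * (n_categories - 1)


def n_standard_decoders(fs: float, trial_dur: float) -> int:
    """Decoder count for standard decoding: one per time point of the trial."""
    return int(round(fs * trial_dur))


@dataclass
class CVScheme:
    """Nested cross-validation layout for decoder training."""

    n_outer: int = 10
    n_inner: int = 5
    lambdas: np.ndarray | None = None  # scaled by n_features at fit time
    seed: int = 0

    def resolved_lambdas(self, n_features: int) -> np.ndarray:
        if self.lambdas is None:
            grid = np.logspace(-3, 3, 10)
        else:
            grid = np.asarray(self.lambdas, dtype=float)
        return grid * n_features

    def outer_folds(self, y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        return _stratified_folds(y, self.n_outer, self.seed)

    def inner_folds(self, y: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        return _stratified_folds(y, self.n_inner, self.seed + 1)


def _stratified_folds(y, k, seed):
    classes = np.unique(y)
    try:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(np.zeros(len(y)), y))
    except ValueError:
        folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(y))
    for tr, _ in folds:
        if len(np.unique(np.asarray(y)[tr])) < len(classes):
            raise ValueError("a training fold is missing one of the classes")
    return folds


@dataclass
class RidgeDecoder:
    weights: np.ndarray  # (P,)
    intercept: float
    penalty: float
    t: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


@dataclass
class TGM:
    accuracy: np.ndarray  # (T, T), train time x test time
    contrast: str = ""
    cv: CVScheme | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.accuracy, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("TGM must be a square matrix")
        if np.any((a < 0) | (a > 1)):
            raise ValueError("TGM entries must lie in [0, 1]")
        self.accuracy = a

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


def standardize_trial(epochs: EpochSet) -> EpochSet:
    """Z-score each trial/channel time series; zero-variance series -> zeros."""
    mu = epochs.data.mean(axis=-1, keepdims=True)
    sd = epochs.data.std(axis=-1, keepdims=True)
    # relative threshold: a numerically-constant series has sd at rounding
    # level relative to its mean, not exactly zero
    ok = sd > 1e-12 * (np.abs(mu) + 1.0)
    out = np.where(ok, (epochs.data - mu) / np.where(ok, sd, 1.0), 0.0)
    return epochs.copy_with(out)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float, t: int | None = None) -> RidgeDecoder:
    """Closed-form ridge fit with unpenalized intercept.

    Minimizes ||y - Xb - b0||^2 + lam*||b||^2; lam = 0 reduces to OLS and
    raises for singular designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if len(np.unique(y)) < 2:
        raise ValueError("both labels must be present")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    p = X.shape[1]
    A = Xc.T @ Xc + lam * np.eye(p)
    if lam == 0 and np.linalg.matrix_rank(Xc) < p:
        raise ValueError("singular design with lam=0; use lam > 0")
    beta = np.linalg.solve(A, Xc.T @ yc)
    return RidgeDecoder(weights=beta, intercept=ym - xm @ beta, penalty=lam, t=t)


def _ridge_path(Xc: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty at once via one SVD.

    Returns (n_lambda, P). Inputs must be centered.
    """
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uy = U.T @ yc  # (r,)
    d = s[None, :] / (s[None, :] ** 2 + lams[:, None])  # (L, r)
    return (d * uy[None, :]) @ Vt  # (L, P)


def _accuracy(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean over trials of 1{sign(score) = y}, ties (score == 0) count 0.5."""
    sgn = np.sign(scores)
    correct = (sgn == y).astype(float) + 0.5 * (sgn == 0)
    return correct.mean(axis=0)


def _select_lambda(X_tr: np.ndarray, y_tr: np.ndarray, cv: CVScheme) -> float:
    lams = cv.resolved_lambdas(X_tr.shape[1])
    mse = np.zeros(len(lams))
    for itr, ite in cv.inner_folds(y_tr):
        xm = X_tr[itr].mean(axis=0)
        ym = y_tr[itr].mean()
        betas = _ridge_path(X_tr[itr] - xm, y_tr[itr] - ym, lams)  # (L, P)
        pred = (X_tr[ite] - xm) @ betas.T + ym  # (n, L)
        mse += ((pred - y_tr[ite][:, None]) ** 2).mean(axis=0)
    return float(lams[int(np.argmin(mse))])


def decode_timepoint(epochs: EpochSet, labels: np.ndarray, t: int, cv: CVScheme) -> float:
    """Outer-CV decoding accuracy at one time point."""
    tgm = compute_tgm(epochs, labels, cv, train_times=[t], test_times=[t])
    return float(tgm.accuracy[0, 0])


def _as_signed(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    return np.where(np.asarray(labels) == classes[1], 1.0, -1.0)


def compute_tgm(
    epochs_or_data: EpochSet | np.ndarray,
    labels: np.ndarray,
    cv: CVScheme,
    contrast: str = "",
    train_times: np.ndarray | None = None,
    test_times: np.ndarray | None = None,
) -> TGM:
    """Cross-validated temporal generalization matrix.

    Entry (i, j): accuracy of the decoder trained at train_times[i] applied
    to held-out trials at test_times[j]. The penalty is re-selected per
    outer fold and training time by inner CV on mean squared error.
    """
    data = epochs_or_data.data if isinstance(epochs_or_data, EpochSet) else np.asarray(epochs_or_data)
    y = _as_signed(labels)
    n, _, t_n = data.shape
    if train_times is None:
        train_times = np.arange(t_n)
    if test_times is None:
        test_times = np.arange(t_n)
    train_times = np.asarray(train_times)
    test_times = np.asarray(test_times)

    acc = np.zeros((len(train_times), len(test_times)))
    n_test_total = 0
    for tr, te in cv.outer_folds(y):
        X_te_all = data[te][:, :, test_times]  # (n_te, C, Tte)
        fold_correct = np.zeros((len(train_times), len(test_times)))
        for i, t in enumerate(train_times):
            X_tr = data[tr][:, :, t]
            lam = _select_lambda(X_tr, y[tr], cv)
            xm = X_tr.mean(axis=0)
            ym = y[tr].mean()
            beta = _ridge_path(X_tr - xm, y[tr] - ym, np.array([lam]))[0]
            scores = np.einsum("nct,c->nt", X_te_all - xm[None, :, None], beta) + ym
            fold_correct[i] = _accuracy(scores, y[te][:, None]) * len(te)
        acc += fold_correct
        n_test_total += len(te)
    acc /= n_test_total
    return TGM(accuracy=acc, contrast=contrast, cv=cv)


def oscillatory_envelope(oscillatory: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude (analytic-signal magnitude) of the oscillation."""
    return np.abs(hilbert(oscillatory, axis=-1))


def tgm_for_components(
    components: SignalComponents,
    labels: np.ndarray,
    cv: CVScheme,
    contrast: str = "",
    train_times: np.ndarray | None = None,
    test_times: np.ndarray | None = None,
) -> dict[str, TGM]:
    """TGMs for original signal, trend, oscillation, and oscillation power.

    All four use identical fold assignments (same CVScheme seed). The power
    input is the amplitude envelope of the oscillatory component, with phase
    information removed.
    """
    inputs = {
        "original": components.trend + components.oscillatory,
        "trend": components.trend,
        "oscillatory": components.oscillatory,
        "power": oscillatory_envelope(components.oscillatory),
    }
    return {
        name: compute_tgm(arr, labels, cv, contrast=f"{contrast}:{name}",
                          train_times=train_times, test_times=test_times)
        for name, arr in inputs.items()
    }


def tgm_attribution(target: TGM, predictors: list[TGM]) -> float:
    """R^2 of an OLS fit (with intercept) of the target TGM's entries on the
    predictor TGMs' entries."""
    yv = target.accuracy.ravel()
    Xv = np.column_stack([p.accuracy.ravel() for p in predictors])
    if Xv.shape[1] != len(predictors):
        raise ValueError("predictor shapes inconsistent")
    if any(p.accuracy.shape != target.accuracy.shape for p in predictors):
        raise ValueError("all TGMs must have the same shape")
    if len(yv) < len(predictors) + 1:
        raise ValueError("fewer TGM entries than regression parameters")
    X1 = np.column_stack([np.ones(len(yv)), Xv])
    coef, *_ = np.linalg.lstsq(X1, yv, rcond=None)
    resid = yv - X1 @ coef
    ss_res = float(resid @ resid)
    yc = yv - yv.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def tgm_sections(
    tgm: TGM,
    t: int | None = None,
    half_window: int | None = None,
    fs: float | None = None,
    offdiag_band_ms: float = 100.0,
) -> dict[str, np.ndarray | float]:
    """Diagonal mean, off-diagonal mean, and the anti-diagonal cross-section.

    The off-diagonal mean excludes a band of |t - t'| <= band around the
    diagonal (default 100 ms, wider than a theta half-cycle, when fs is
    given; otherwise the band is half_window samples or 10% of T). The
    orthogonal section runs along the anti-diagonal through (t, t):
    entries (t + d, t - d), truncated at the matrix edge.
    """
    a = tgm.accuracy
    t_n = a.shape[0]
    if t is None:
        t = t_n // 2
    if not 0 <= t < t_n:
        raise ValueError(f"t={t} outside trial [0, {t_n})")
    if half_window is None:
        half_window = t_n // 4
    if fs is not None:
        band = int(round(offdiag_band_ms / 1000.0 * fs))
    else:
        band = max(int(round(0.1 * t_n)), 1)

    ii, jj = np.meshgrid(np.arange(t_n), np.arange(t_n), indexing="ij")
    off_mask = np.abs(ii - jj) > band
    diag_mean = float(np.diag(a).mean())
    off_mean = float(a[off_mask].mean()) if off_mask.any() else np.nan

    offsets = np.arange(-half_window, half_window + 1)
    rows = t + offsets
    cols = t - offsets
    valid = (rows >= 0) & (rows < t_n) & (cols >= 0) & (cols < t_n)
    section = np.full(offsets.shape, np.nan)
    section[valid] = a[rows[valid], cols[valid]]
    return {
        "diagonal_mean": diag_mean,
        "offdiagonal_mean": off_mean,
        "section": section,
        "section_offsets": offsets,
        "section_valid": valid,
        "t": t,
    }
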