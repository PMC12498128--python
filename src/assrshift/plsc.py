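"""Partial least squares correlation (PLSC) between EEG features and symptom
scores.

Both blocks are column z-scored; R = X_z^T Y_z / (n - 1) is the standardized
cross-covariance (i.e. cross-correlation) matrix, and its SVD R = U S V^T
yields EEG saliences U, singular values S and symptom saliences V.  Latent
scores are X_z U and Y_z V; loadings are the correlations of the original
variables with the *opposite* block's latent scores.  Component significance
comes from permuting the rows of Y (1000 times); loading stability from the
bootstrap ratio (bootstrap mean / bootstrap SD of each loading, subjects
resampled with replacement, each resample's saliences Procrustes-aligned to
the original solution before accumulating).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BOOTSTRAP_RATIO_THRESHOLD = 1.96


@dataclass
class PLSCResult:
    R: np.ndarray
    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    eeg_loadings: np.ndarray
    symptom_loadings: np.ndarray
    feature_names: list[str] | None = None
    symptom_names: list[str] | None = None
    perm_p: np.ndarray | None = None
    n_perm: int = 0
    eeg_bootstrap_ratios: np.ndarray | None = None
    symptom_bootstrap_ratios: np.ndarray | None = None
    n_boot: int = 0

    def significant_components(self, alpha: float = 0.05) -> np.ndarray:
        if self.perm_p is None:
            raise ValueError("run plsc_permutation first")
        return np.flatnonzero(self.perm_p < alpha)

    def stable_eeg_loadings(self, component: int = 0) -> np.ndarray:
        return np.flatnonzero(
            np.abs(self.eeg_bootstrap_ratios[:, component]) > BOOTSTRAP_RATIO_THRESHOLD
        )


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; cannot z-score")
    return (a - a.mean(axis=0)) / sd


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve sign indeterminacy: largest-|element| of each U column positive."""
    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
    return U, V


def _corr_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of every column of ``a`` with every column of ``b``."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    az /= np.sqrt((az**2).sum(axis=0))
    bz /= np.sqrt((bz**2).sum(axis=0))
    return az.T @ bz


def plsc_fit(
    X: np.ndarray,
    Y: np.ndarray,
    feature_names: list[str] | None = None,
    symptom_names: list[str] | None = None,
) -> PLSCResult:
    """Point-estimate PLSC of subjects x features X against subjects x factors Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the subject axis")
    if X.shape[0] <= 5:
        raise ValueError("need more than 5 subjects")
    keep = ~np.isnan(Y).any(axis=1) & ~np.isnan(X).any(axis=1)
    X, Y = X[keep], Y[keep]
    Xz, Yz = _zscore_cols(X), _zscore_cols(Y)
    n = X.shape[0]
    R = Xz.T @ Yz / (n - 1)
    if not np.any(R):
        raise ValueError("cross-covariance matrix is identically zero")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _fix_signs(U, V)
    x_scores = Xz @ U
    y_scores = Yz @ V
    return PLSCResult(
        R=R, U=U, S=s, V=V,
        x_scores=x_scores, y_scores=y_scores,
        eeg_loadings=_corr_cols(X, y_scores),
        symptom_loadings=_corr_cols(Y, x_scores),
        feature_names=feature_names, symptom_names=symptom_names,
    )


def plsc_permutation(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    result: PLSCResult | None = None,
) -> PLSCResult:
    """Permutation p per latent component: rows of Y shuffled, singular values
    recomputed and compared by rank order (surrogate s_k vs observed s_k),
    p = (1 + #{surrogate >= observed}) / (1 + n_perm).

    Rank-order matching keeps the comparison maximum-against-maximum for the
    leading component, which makes the null p uniform; aligning surrogate
    axes to the observed saliences instead mixes singular values and is
    anti-conservative.
    """
    res = result if result is not None else plsc_fit(X, Y)
    rng = np.random.default_rng(seed)
    Xz = _zscore_cols(np.asarray(X, float))
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    exceed = np.zeros(res.S.size, dtype=int)
    for _ in range(n_perm):
        Yp = _zscore_cols(Y[rng.permutation(n)])
        Rp = Xz.T @ Yp / (n - 1)
        s_p = np.linalg.svd(Rp, compute_uv=False)
        exceed += s_p >= res.S
    res.perm_p = (1 + exceed) / (1 + n_perm)
    res.n_perm = n_perm
    return res


def plsc_bootstrap(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    result: PLSCResult | None = None,
) -> PLSCResult:
    """Bootstrap ratios (mean / SD over resamples) for every loading.

    Subjects are resampled with replacement; each resample's saliences are
    Procrustes-rotated (with reflection) onto the original U, V before its
    loadings are accumulated, removing axis rotation/reflection across
    resamples.  Degenerate resamples (a single repeated subject, or a
    constant column) are redrawn.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2 for a bootstrap SD")
    res = result if result is not None else plsc_fit(X, Y)
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    eeg_acc = np.zeros((n_boot,) + res.eeg_loadings.shape)
    sym_acc = np.zeros((n_boot,) + res.symptom_loadings.shape)
    b = 0
    guard = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        guard += 1
        if guard > 50 * n_boot:
            raise RuntimeError("bootstrap resampling failed to produce valid samples")
        if np.unique(idx).size < 2:
            continue
        Xb, Yb = X[idx], Y[idx]
        if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
            continue
        Xbz, Ybz = _zscore_cols(Xb), _zscore_cols(Yb)
        Rb = Xbz.T @ Ybz / (n - 1)
        Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        Vb = Vbt.T
        # align bootstrap axes to the original solution (rotation + reflection):
        # orthogonal Procrustes minimizing ||Ub Q - U||^2 + ||Vb Q - V||^2
        M = Ub.T @ res.U + Vb.T @ res.V
        A, _, Bt = np.linalg.svd(M)
        Q = A @ Bt
        Ub, Vb = Ub @ Q, Vb @ Q
        eeg_acc[b] = _corr_cols(Xb, Ybz @ Vb)
        sym_acc[b] = _corr_cols(Yb, Xbz @ Ub)
        b += 1
    res.eeg_bootstrap_ratios = eeg_acc.mean(axis=0) / eeg_acc.std(axis=0, ddof=1)
    res.symptom_bootstrap_ratios = sym_acc.mean(axis=0) / sym_acc.std(axis=0, ddof=1)
    res.n_boot = n_boot
    return res


def run_plsc(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    feature_names: list[str] | None = None,
    symptom_names: list[str] | None = None,
) -> PLSCResult:
    res = plsc_fit(X, Y, feature_names, symptom_names)
    rng = np.random.default_rng(seed)
    res = plsc_permutation(X, Y, n_perm, rng, result=res)
    res = plsc_bootstrap(X, Y, n_boot, rng, result=res)
    return res
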