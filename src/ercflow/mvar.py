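"""Multi-trial short-window MVAR estimation and short-time direct DTF.

The estimation engine: multichannel Yule-Walker fits pooled across trial
realizations in short sliding windows, AIC order selection, the
sample-sufficiency guard, spectral decomposition (transfer function and
partial coherence), and the short-time direct directed transfer function
(SdDTF).

Sign convention
---------------
Models are written ``x(t) = sum_j B_j x(t-j) + e(t)``.  Literature that
writes the autoregression with the coefficient sum on the left-hand side
(``x(t) + sum_j A_j x(t-j) = e(t)``) maps onto this via ``B_j = -A_j``.
Every generator, estimator and oracle in this package uses the ``B_j``
(plus-sum) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "MVARModel",
    "WindowGrid",
    "SpectralDecomposition",
    "FlowTensor",
    "SufficiencyResult",
    "UnstableModelError",
    "SingularCovarianceError",
    "check_sufficiency",
    "lag_covariances",
    "fit_mvar",
    "fit_mvar_window",
    "aic",
    "select_order_aic",
    "spectral_decomposition",
    "sddtf",
    "sliding_sddtf",
    "default_freq_grid",
]

#: Sufficiency threshold for K(p+1)/(Ns*nt).
SUFFICIENCY_THRESHOLD = 0.1

#: Analysis window length and step (175 and 7 samples at 1250 Hz).
WINDOW_LEN_S = 0.140
WINDOW_STEP_S = 0.0056


class UnstableModelError(ValueError):
    """Raised when an MVAR model fails the companion-matrix stability check."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the lag-covariance system is singular."""


def default_freq_grid(low: float = 60.0, high: float = 180.0, step: float = 4.0) -> np.ndarray:
    """Analysis frequency grid: 60-180 Hz in 4 Hz steps (31 bins)."""
    return np.arange(low, high + step / 2, step, dtype=float)


@dataclass(frozen=True)
class MVARModel:
    """MVAR(p) model ``x(t) = sum_j coeffs[j-1] x(t-j) + e(t)``.

    Parameters
    ----------
    coeffs
        Array of shape ``(p, K, K)``; ``coeffs[j-1][k, l]`` couples channel
        ``l`` at lag ``j`` into channel ``k``.
    noise_cov
        Innovation covariance, shape ``(K, K)``, symmetric PSD.
    sampling_rate
        Sampling rate in Hz (used by the spectral transform).
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    sampling_rate: float = 1250.0

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.ndim != 3 or coeffs.shape[1] != coeffs.shape[2]:
            raise ValueError(f"coeffs must be (p, K, K); got {coeffs.shape}")
        noise = np.asarray(self.noise_cov, dtype=float)
        if noise.shape != coeffs.shape[1:]:
            raise ValueError("noise_cov shape does not match coeffs")
        if not np.allclose(noise, noise.T, atol=1e-10):
            raise ValueError("noise_cov must be symmetric")
        object.__setattr__(self, "coeffs", coeffs)
        object.__setattr__(self, "noise_cov", noise)

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """Companion matrix of the coefficient stack (shape Kp x Kp)."""
        p, K = self.order, self.n_channels
        top = np.concatenate(list(self.coeffs), axis=1)
        comp = np.zeros((K * p, K * p))
        comp[:K, :] = top
        if p > 1:
            comp[K:, :-K] = np.eye(K * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1.0) -> bool:
        return self.spectral_radius() < tol

    def require_stable(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise UnstableModelError(
                f"MVAR model is unstable: companion spectral radius {rho:.4f} >= 1"
            )


@dataclass(frozen=True)
class SufficiencyResult:
    """Outcome of the sample-sufficiency inequality K(p+1)/(Ns*nt) < 0.1."""

    ratio: float
    passed: bool
    threshold: float = SUFFICIENCY_THRESHOLD


def check_sufficiency(K: int, p: int, Ns: int, nt: int) -> SufficiencyResult:
    """Evaluate the sample-sufficiency ratio ``K(p+1)/(Ns*nt)``.

    The fit is considered sufficiently determined when the ratio of model
    parameters per channel to available data points is below 0.1.
    """
    for name, v in (("K", K), ("p", p), ("Ns", Ns), ("nt", nt)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    denom = Ns * nt
    if denom == 0:
        raise ZeroDivisionError("Ns * nt is zero")
    ratio = K * (p + 1) / denom
    return SufficiencyResult(ratio=ratio, passed=ratio < SUFFICIENCY_THRESHOLD)


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over an epoch.

    ``Ns`` is the per-window sample count, ``step`` the shift in samples;
    windows are half-open ``[start, start + Ns)`` and must fit inside the
    epoch.
    """

    n_epoch_samples: int
    sampling_rate: float
    window_len_s: float = WINDOW_LEN_S
    step_s: float = WINDOW_STEP_S

    def __post_init__(self) -> None:
        if self.Ns > self.n_epoch_samples:
            raise ValueError(
                f"epoch of {self.n_epoch_samples} samples is shorter than one "
                f"{self.Ns}-sample window"
            )

    @property
    def Ns(self) -> int:
        ns = self.window_len_s * self.sampling_rate
        if abs(ns - round(ns)) > 1e-6:
            raise ValueError(
                f"window length {self.window_len_s}s is not an integer sample "
                f"count at {self.sampling_rate} Hz"
            )
        return int(round(ns))

    @property
    def step(self) -> int:
        st = self.step_s * self.sampling_rate
        if abs(st - round(st)) > 1e-6:
            raise ValueError(
                f"step {self.step_s}s is not an integer sample count at "
                f"{self.sampling_rate} Hz"
            )
        return int(round(st))

    @property
    def n_windows(self) -> int:
        return (self.n_epoch_samples - self.Ns) // self.step + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step

    def centers_s(self, t0_s: float = 0.0) -> np.ndarray:
        """Window-center times in seconds; ``t0_s`` is the epoch-start time."""
        return t0_s + (self.starts + self.Ns / 2.0) / self.sampling_rate


def lag_covariances(data: np.ndarray, p: int) -> np.ndarray:
    """Lag covariance matrices R(0..p) pooled across trials.

    ``data`` has shape ``(n_trials, K, Ns)``.  The per-trial mean over the
    window is removed first (local-stationarity surrogate), then
    ``R(j)[k, l] = E[x_k(t) x_l(t-j)]`` is estimated with the biased
    normalization ``1/(n_trials*Ns)``, which keeps the block-Toeplitz
    system positive semi-definite.
    """
    nt, K, Ns = data.shape
    if p >= Ns:
        raise ValueError(f"order p={p} must be < window length {Ns}")
    x = data - data.mean(axis=2, keepdims=True)
    R = np.empty((p + 1, K, K))
    denom = nt * Ns
    for j in range(p + 1):
        # R(j) = E[x(t) x(t-j)^T]
        R[j] = np.einsum("nkt,nlt->kl", x[:, :, j:], x[:, :, : Ns - j]) / denom
    return R


def _solve_yule_walker(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the multichannel Yule-Walker system from R(0..p).

    Returns ``(coeffs (p,K,K), noise_cov (K,K))`` for the plus-sum
    convention.
    """
    p = R.shape[0] - 1
    K = R.shape[1]
    # Block-Toeplitz covariance of the stacked lag vector [x(t-1);...;x(t-p)]:
    # block (m, j) = R(j - m), with R(-j) = R(j)^T.
    G = np.empty((p * K, p * K))
    for m in range(p):
        for j in range(p):
            d = j - m
            blk = R[d] if d >= 0 else R[-d].T
            G[m * K : (m + 1) * K, j * K : (j + 1) * K] = blk
    C = np.concatenate([R[j] for j in range(1, p + 1)], axis=1)  # K x pK
    try:
        Bstack = scipy.linalg.solve(G.T, C.T, assume_a="sym").T
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        bad = [k for k in range(K) if R[0][k, k] <= 0]
        raise SingularCovarianceError(
            "singular lag-covariance system"
            + (f"; zero-variance channels: {bad}" if bad else "")
        ) from exc
    coeffs = Bstack.reshape(K, p, K).transpose(1, 0, 2)
    noise = R[0] - sum(coeffs[j] @ R[j + 1].T for j in range(p))
    noise = (noise + noise.T) / 2.0
    return coeffs, noise


def fit_mvar(data: np.ndarray, p: int, sampling_rate: float = 1250.0) -> MVARModel:
    """Fit an MVAR(p) model to multi-trial window data by Yule-Walker.

    Parameters
    ----------
    data
        ``(n_trials, K, Ns)`` array of trial realizations of the same
        stochastic process inside one window.
    p
        Model order.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be (n_trials, K, Ns)")
    var = data.var(axis=(0, 2))
    if np.any(var <= 0):
        bad = list(np.nonzero(var <= 0)[0])
        raise SingularCovarianceError(f"zero-variance channels: {bad}")
    R = lag_covariances(data, p)
    coeffs, noise = _solve_yule_walker(R)
    return MVARModel(coeffs=coeffs, noise_cov=noise, sampling_rate=sampling_rate)


def fit_mvar_window(ep, window: int, p: int, grid: WindowGrid | None = None) -> MVARModel:
    """Fit one sliding-window MVAR model from an :class:`~ercflow.preprocess.EpochSet`.

    ``window`` indexes the sliding-window grid (constructed from the epoch
    length if not supplied).
    """
    if grid is None:
        grid = WindowGrid(n_epoch_samples=ep.n_samples, sampling_rate=ep.sampling_rate)
    start = int(grid.starts[window])
    sl = ep.data[:, :, start : start + grid.Ns]
    return fit_mvar(sl, p, sampling_rate=ep.sampling_rate)


def aic(data: np.ndarray, p: int) -> float:
    """Akaike information criterion for an MVAR(p) fit to window data.

    ``AIC(p) = N * log det(noise_cov) + 2 K^2 p`` with ``N`` the pooled
    sample count ``n_trials * Ns``.
    """
    data = np.asarray(data, dtype=float)
    nt, K, Ns = data.shape
    model = fit_mvar(data, p)
    sign, logdet = np.linalg.slogdet(model.noise_cov)
    if sign <= 0:
        return np.inf
    return float(nt * Ns * logdet + 2.0 * K * K * p)


def select_order_aic(
    ep,
    p_range: Sequence[int],
    windows: Sequence[int] | None = None,
    grid: WindowGrid | None = None,
) -> int:
    """Select a single global MVAR order by AIC.

    AIC is evaluated per candidate order on a stratified sample of windows
    and the order minimizing the median AIC is returned.
    """
    p_range = list(p_range)
    if not p_range:
        raise ValueError("empty p_range")
    if grid is None:
        grid = WindowGrid(n_epoch_samples=ep.n_samples, sampling_rate=ep.sampling_rate)
    if windows is None:
        n = grid.n_windows
        windows = sorted(set(np.linspace(0, n - 1, min(5, n), dtype=int).tolist()))
    scores = np.empty((len(p_range), len(windows)))
    for i, p in enumerate(p_range):
        for j, w in enumerate(windows):
            start = int(grid.starts[w])
            scores[i, j] = aic(ep.data[:, :, start : start + grid.Ns], p)
    medians = np.median(scores, axis=1)
    return int(p_range[int(np.argmin(medians))])


@dataclass(frozen=True)
class SpectralDecomposition:
    """Per-frequency transfer matrix, spectral matrix and partial coherence.

    ``h[f]`` is the transfer matrix ``A(f)^-1`` (directed relationships),
    ``s[f]`` the spectral matrix ``H S_e H*``, and ``c[f]`` the partial
    coherence (direct relationships), normalized so ``|c| <= 1``.
    """

    freqs: np.ndarray
    h: np.ndarray  # (F, K, K) complex
    s: np.ndarray  # (F, K, K) complex
    c: np.ndarray  # (F, K, K) complex

    @property
    def n_channels(self) -> int:
        return self.h.shape[1]


def spectral_decomposition(model: MVARModel, freqs: np.ndarray) -> SpectralDecomposition:
    """Frequency-domain decomposition of a stable MVAR model.

    ``A(f) = I - sum_j B_j exp(-2 pi i f j / fs)``; the transfer matrix is
    ``H(f) = A(f)^-1``; the spectral matrix ``S = H S_e H*``; partial
    coherence comes from the inverse spectral matrix ``P = S^-1`` as
    ``c_kl = P_kl / sqrt(P_kk P_ll)``.
    """
    model.require_stable()
    freqs = np.asarray(freqs, dtype=float)
    p, K = model.order, model.n_channels
    fs = model.sampling_rate
    lags = np.arange(1, p + 1)
    # phases: (F, p)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / fs)
    A = np.eye(K)[None, :, :] - np.einsum("fj,jkl->fkl", phase, model.coeffs)
    try:
        H = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        dets = np.abs(np.linalg.det(A))
        f_bad = freqs[int(np.argmin(dets))]
        raise np.linalg.LinAlgError(
            f"coefficient polynomial non-invertible near f={f_bad:g} Hz"
        ) from exc
    S = H @ model.noise_cov @ np.conj(H).transpose(0, 2, 1)
    # Regularize only if numerically singular.
    try:
        P = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        eps = 1e-12 * np.trace(S, axis1=1, axis2=2).real.mean() / K
        P = np.linalg.inv(S + eps * np.eye(K)[None, :, :])
    d = np.sqrt(np.abs(np.einsum("fkk->fk", P).real))
    C = P / (d[:, :, None] * d[:, None, :])
    return SpectralDecomposition(freqs=freqs, h=H, s=S, c=C)


@dataclass(frozen=True)
class FlowTensor:
    """SdDTF values ``z[target, source, f, t]`` on a (freq, window-time) grid.

    The diagonal (self-flow) is excluded from the normalization and held
    at zero.  ``times`` are window centers in seconds relative to the
    epoch's alignment event.
    """

    z: np.ndarray  # (K, K, F, T)
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]

    def pair(self, target: int, source: int) -> np.ndarray:
        """(F, T) flow field for source -> target."""
        return self.z[target, source]


def sddtf(dec: SpectralDecomposition) -> np.ndarray:
    """Short-time direct DTF values for one window.

    ``z_kl(f) = |h_kl(f) c_kl(f)| / sqrt(sum_f sum_kl |h_kl c_kl|^2)``
    with the frequency sum over the supplied grid and the pair sum over
    all ordered pairs (diagonal included in the normalization family, so
    independent channels give exactly zero off-diagonal flow).  Returns
    ``(K, K, F)``; values lie in [0, 1] and their squares sum to 1 over
    the family.  Diagonal entries are self-flows, kept for the
    normalization identity but excluded from all reporting downstream.
    """
    M = np.abs(dec.h) * np.abs(dec.c)  # (F, K, K)
    K = M.shape[1]
    off = ~np.eye(K, dtype=bool)
    denom_sq = float(np.sum(M[:, off] ** 2))
    if denom_sq <= 0.0:
        if float(np.sum(M**2)) <= 0.0:
            raise ValueError("degenerate SdDTF input: all flows are zero")
        # independent channels: no off-diagonal flow at all
        z = np.zeros((K, K, len(dec.freqs)))
        return z
    z = M / np.sqrt(denom_sq)
    z = np.ascontiguousarray(z.transpose(1, 2, 0))  # (K, K, F)
    z[np.eye(K, dtype=bool), :] = 0.0
    return z


def sliding_sddtf(
    ep,
    p: int,
    freqs: np.ndarray | None = None,
    grid: WindowGrid | None = None,
    enforce_sufficiency: bool = True,
) -> FlowTensor:
    """SdDTF over all sliding windows of an epoch set.

    One MVAR model is fitted per 140 ms window (5.6 ms shifts by default)
    from all trials jointly; each yields one ``z(f)`` slice.  Window
    timestamps are window centers relative to the alignment event.
    """
    if freqs is None:
        freqs = default_freq_grid()
    if grid is None:
        grid = WindowGrid(n_epoch_samples=ep.n_samples, sampling_rate=ep.sampling_rate)
    nt, K, _ = ep.data.shape
    suff = check_sufficiency(K, p, grid.Ns, nt)
    if enforce_sufficiency and not suff.passed:
        raise ValueError(
            f"sample-sufficiency check failed: K(p+1)/(Ns*nt) = "
            f"{suff.ratio:.4f} >= {suff.threshold}"
        )
    T = grid.n_windows
    F = len(freqs)
    z = np.empty((K, K, F, T))
    for w, start in enumerate(grid.starts):
        data = ep.data[:, :, start : start + grid.Ns]
        model = fit_mvar(data, p, sampling_rate=ep.sampling_rate)
        dec = spectral_decomposition(model, freqs)
        z[:, :, :, w] = sddtf(dec)
    times = grid.centers_s(t0_s=ep.window[0])
    channels = tuple(ch.id for ch in ep.channels) if ep.channels else ()
    return FlowTensor(
        z=z,
        freqs=np.asarray(freqs, dtype=float),
        times=times,
        channels=channels,
        meta={"order": p, "sufficiency_ratio": suff.ratio, "Ns": grid.Ns, "nt": nt},
    )
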