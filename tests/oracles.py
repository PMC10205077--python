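"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the package's vectorized code paths: transfer
matrices come from adjugate inverses, partial coherence from explicit
minors, Yule-Walker from hand-built block systems, and the Wilcoxon null
from exhaustive sign enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_transfer(coeffs: np.ndarray, f: float, fs: float) -> np.ndarray:
    """H(f) = A(f)^-1 computed via the adjugate (cofactor) formula."""
    p, K, _ = coeffs.shape
    A = np.eye(K, dtype=complex)
    for j in range(1, p + 1):
        A = A - coeffs[j - 1] * np.exp(-2j * np.pi * f * j / fs)
    det = np.linalg.det(A)
    cof = np.zeros((K, K), dtype=complex)
    for r in range(K):
        for c in range(K):
            minor = np.delete(np.delete(A, r, 0), c, 1)
            cof[r, c] = (-1) ** (r + c) * np.linalg.det(minor)
    return cof.T / det


def oracle_partial_coherence_mag(S: np.ndarray) -> np.ndarray:
    """|partial coherence| from minors of the spectral matrix."""
    K = S.shape[0]
    out = np.zeros((K, K))
    for k in range(K):
        for l in range(K):
            Mkl = np.linalg.det(np.delete(np.delete(S, k, 0), l, 1))
            Mkk = np.linalg.det(np.delete(np.delete(S, k, 0), k, 1))
            Mll = np.linalg.det(np.delete(np.delete(S, l, 0), l, 1))
            out[k, l] = abs(Mkl) / np.sqrt(abs(Mkk) * abs(Mll))
    return out


def oracle_sddtf(
    coeffs: np.ndarray, noise_cov: np.ndarray, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """SdDTF (K, K, F) from true model coefficients, loop-by-loop."""
    p, K, _ = coeffs.shape
    M = np.zeros((len(freqs), K, K))
    for fi, f in enumerate(freqs):
        H = oracle_transfer(coeffs, f, fs)
        S = H @ noise_cov @ H.conj().T
        M[fi] = np.abs(H) * oracle_partial_coherence_mag(S)
    off = ~np.eye(K, dtype=bool)
    denom = np.sqrt(np.sum(M[:, off] ** 2))
    if denom == 0:
        return np.zeros((K, K, len(freqs)))
    z = (M / denom).transpose(1, 2, 0).copy()
    z[np.eye(K, dtype=bool), :] = 0.0
    return z


def oracle_ordinary_coherence_mag(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.abs(np.diag(S)))
    return np.abs(S) / np.outer(d, d)


def oracle_dtf_mag(coeffs: np.ndarray, f: float, fs: float) -> np.ndarray:
    """Row-normalized (non-partialized) DTF magnitude at one frequency."""
    H = oracle_transfer(coeffs, f, fs)
    mag2 = np.abs(H) ** 2
    return np.sqrt(mag2 / mag2.sum(axis=1, keepdims=True))


def oracle_yule_walker(data: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-trial Yule-Walker via explicit loops (independent of the package)."""
    nt, K, Ns = data.shape
    x = data - data.mean(axis=2, keepdims=True)
    R = np.zeros((p + 1, K, K))
    for j in range(p + 1):
        for n in range(nt):
            for t in range(j, Ns):
                R[j] += np.outer(x[n, :, t], x[n, :, t - j])
        R[j] /= nt * Ns
    G = np.zeros((p * K, p * K))
    for m in range(p):
        for jj in range(p):
            d = jj - m
            blk = R[d] if d >= 0 else R[-d].T
            G[m * K : (m + 1) * K, jj * K : (jj + 1) * K] = blk
    C = np.hstack([R[j] for j in range(1, p + 1)])
    B = C @ np.linalg.inv(G)
    coeffs = np.stack([B[:, m * K : (m + 1) * K] for m in range(p)])
    noise = R[0] - sum(coeffs[j] @ R[j + 1].T for j in range(p))
    return coeffs, (noise + noise.T) / 2


def oracle_aic(data: np.ndarray, p: int) -> float:
    """N log det(noise cov) + 2 K^2 p with the oracle Yule-Walker fit."""
    nt, K, Ns = data.shape
    _, noise = oracle_yule_walker(data, p)
    sign, logdet = np.linalg.slogdet(noise)
    return float(nt * Ns * logdet + 2 * K * K * p)


def oracle_wilcoxon_exact_p(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    # midranks for ties
    absd = np.abs(d)
    for v in np.unique(absd):
        sel = absd == v
        ranks[sel] = ranks[sel].mean()
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, ranks.sum() - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        w = min(wp, ranks.sum() - wp)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n
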