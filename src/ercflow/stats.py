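"""Event-related causality statistics.

Task-vs-baseline comparison of smoothed SdDTF fields with BH-FDR control,
group pooling across sessions by directed region-pair class, word vs
pseudoword contrasts, and integration of significant flows into directed
graphs.  Only task-related increases are reported.

Session-level testing compares each smoothed task (f, t) point to the
distribution of smoothed baseline values pooled over baseline windows at
the same frequency.  Because overlapping sliding windows make consecutive
baseline values strongly dependent, the reference t test uses an effective
sample size estimated from the baseline autocorrelation (Bartlett-style
shrinkage); without it the test is anticonservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.signal
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .mvar import FlowTensor
from .preprocess import HIGH_GAMMA_BAND

__all__ = [
    "StatsConfig",
    "ERCResult",
    "GroupERCResult",
    "GroupClassCurve",
    "INTEGRATION_PRESETS",
    "smooth_tf",
    "erc_session",
    "erc_group",
    "condition_contrast",
    "integrate_flows",
]

logger = logging.getLogger(__name__)

#: Named integration intervals (s relative to speech onset).
INTEGRATION_PRESETS = {
    "stg_burst": (-0.45, -0.40),
    "lexicality": (-0.208, -0.117),
    "pre_speech": (-0.5, -0.3),
}


@dataclass(frozen=True)
class StatsConfig:
    """Significance settings: alpha, 2D smoothing kernel, increases only."""

    alpha: float = 0.05
    kernel: tuple[int, int] = (9, 5)  # (n_time, n_freq), odd
    increases_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(k % 2 == 0 or k < 1 for k in self.kernel):
            raise ValueError("kernel dims must be odd and >= 1")


def smooth_tf(field: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Centered 2D moving average of an (f, t) field.

    ``kernel`` is ``(n_time, n_freq)``.  At the edges the kernel shrinks
    to the available support (no invented padding values), which preserves
    means at the borders and retains a sharp step response.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be 2D (freq, time)")
    kt, kf = kernel
    if kf > field.shape[0] or kt > field.shape[1]:
        raise ValueError(f"kernel {kernel} larger than field {field.shape}")
    box = np.ones((kf, kt))
    num = scipy.signal.convolve2d(field, box, mode="same", boundary="fill")
    den = scipy.signal.convolve2d(np.ones_like(field), box, mode="same", boundary="fill")
    return num / den


def _effective_sample_size(series: np.ndarray, max_lag: int | None = None) -> float:
    """Bartlett effective sample size of a (possibly multi-row) series.

    ``series`` has shape (rows, n); autocorrelations are averaged across
    rows.  Returns ``n / (1 + 2 sum (1 - k/n) rho_k)`` clipped to [2, n].
    """
    series = np.atleast_2d(series)
    n = series.shape[1]
    if max_lag is None:
        max_lag = min(n - 2, n // 2)
    x = series - series.mean(axis=1, keepdims=True)
    denom = np.sum(x**2, axis=1)
    valid = denom > 0
    if not valid.any():
        return float(n)
    rho_sum = 0.0
    for k in range(1, max_lag + 1):
        num = np.sum(x[:, k:] * x[:, :-k], axis=1)
        rho_k = np.mean(num[valid] / denom[valid])
        if rho_k <= 0:  # truncate at first nonpositive average lag
            break
        rho_sum += (1 - k / n) * rho_k
    n_eff = n / (1 + 2 * rho_sum)
    return float(np.clip(n_eff, 2.0, n))


@dataclass
class ERCResult:
    """Session-level smoothed task-vs-baseline flow change per directed pair.

    Arrays are indexed ``[pair, freq, time]`` with ``pairs[i] = (target,
    source)`` channel indices.  ``mask`` retains only significant
    increases.
    """

    delta: np.ndarray  # (P, F, T) smoothed task - baseline mean
    q: np.ndarray  # (P, F, T)
    mask: np.ndarray  # (P, F, T) bool, increases only
    baseline_mean: np.ndarray  # (P, F)
    pairs: tuple[tuple[int, int], ...]
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple = ()
    regions: tuple = ()
    session_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return self.delta.shape[0]

    def masked_fraction(self) -> float:
        return float(self.mask.mean())


def erc_session(
    task: FlowTensor,
    baseline: FlowTensor,
    cfg: StatsConfig | None = None,
    regions: Sequence[str] | None = None,
    session_id: str = "",
) -> ERCResult:
    """Session-level ERC: smoothed task-vs-baseline comparison with FDR.

    Both flow fields are smoothed with the configured 2D moving average.
    Per pair and frequency, the pooled smoothed baseline values form the
    reference distribution; each task point is tested two-sided against
    it.  BH-FDR runs over the pair's full (f, t) family; the mask keeps
    only significant increases.
    """
    cfg = cfg or StatsConfig()
    if task.z.shape[:2] != baseline.z.shape[:2]:
        raise ValueError("task and baseline channel sets differ")
    if len(task.freqs) != len(baseline.freqs) or not np.allclose(
        task.freqs, baseline.freqs
    ):
        raise ValueError("task and baseline frequency grids differ")
    kt, kf = cfg.kernel
    if baseline.z.shape[3] < kt:
        raise ValueError(
            f"baseline has {baseline.z.shape[3]} windows, fewer than the "
            f"{kt}-point smoothing kernel"
        )
    K = task.n_channels
    F, T = task.z.shape[2], task.z.shape[3]
    nb = baseline.z.shape[3]
    pairs = tuple((k, l) for k in range(K) for l in range(K) if k != l)
    P = len(pairs)
    delta = np.empty((P, F, T))
    qvals = np.empty((P, F, T))
    mask = np.zeros((P, F, T), dtype=bool)
    base_mean = np.empty((P, F))
    for i, (k, l) in enumerate(pairs):
        zt = smooth_tf(task.z[k, l], cfg.kernel)
        zb = smooth_tf(baseline.z[k, l], cfg.kernel)
        m = zb.mean(axis=1)  # (F,)
        resid = zb - m[:, None]
        # Overlapping windows leave only a handful of independent baseline
        # values per frequency, so the variance is pooled across the
        # (approximately homoscedastic) frequency rows; baseline means stay
        # per-frequency.  Effective counts come from the time- and
        # frequency-axis autocorrelation of the smoothed baseline field.
        n_eff_t = _effective_sample_size(zb)
        n_eff_f = _effective_sample_size(zb.T)
        n_eff = max(n_eff_t * n_eff_f, 2.0)
        s2 = resid.var(ddof=0)
        # E[resid var] = sigma^2 (1 - 1/n_eff_t) for row-demeaned
        # stationary noise; undo before forming the t statistic.
        bias = max(1.0 - 1.0 / n_eff_t, 1e-3)
        sigma = np.sqrt(max(s2 / bias, 1e-30))
        d = zt - m[:, None]
        tstat = d / (sigma * np.sqrt(1.0 + 1.0 / n_eff_t))
        df = max(n_eff - 1.0, 1.0)
        p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df)
        rej, q, _, _ = multipletests(p.ravel(), alpha=cfg.alpha, method="fdr_bh")
        rej = rej.reshape(F, T)
        q = q.reshape(F, T)
        delta[i] = d
        qvals[i] = q
        base_mean[i] = m
        mask[i] = rej & (d > 0) if cfg.increases_only else rej
    return ERCResult(
        delta=delta,
        q=qvals,
        mask=mask,
        baseline_mean=base_mean,
        pairs=pairs,
        freqs=task.freqs,
        times=task.times,
        channels=task.channels,
        regions=tuple(regions) if regions is not None else (),
        session_id=session_id,
        meta={"alpha": cfg.alpha, "kernel": cfg.kernel},
    )


@dataclass
class GroupClassCurve:
    """Group result for one directed region-pair class (e.g. STG->STN).

    ``session_curves`` hold the per-session significant (masked) flow
    change; ``session_curves_raw`` the unthresholded change, used for
    condition contrasts where the mask nonlinearity would bias paired
    differences.
    """

    mean: np.ndarray  # (T,)
    sem: np.ndarray  # (T,)
    q: np.ndarray  # (T,)
    mask: np.ndarray  # (T,) bool
    session_curves: np.ndarray  # (n_sessions, T)
    session_curves_raw: np.ndarray  # (n_sessions, T)
    n_sessions: int


@dataclass
class GroupERCResult:
    """Group-level ERC per directed region-pair class."""

    classes: dict  # (source_region, target_region) -> GroupClassCurve
    times: np.ndarray
    session_ids: tuple
    band: tuple[float, float] = HIGH_GAMMA_BAND
    alpha: float = 0.05


def _session_class_curves(
    res: ERCResult, band: tuple[float, float]
) -> dict:
    """Per-class time courses (masked and raw) for one session.

    Class = (source region, target region); curves average over in-band
    frequencies and over the session's pairs in that class.  The masked
    curve zeroes nonsignificant points, mirroring the increases-only
    report; the raw curve keeps the unthresholded change.
    """
    if not res.regions:
        raise ValueError("ERCResult lacks region labels")
    fsel = (res.freqs >= band[0]) & (res.freqs <= band[1])
    masked: dict = {}
    raw: dict = {}
    counts: dict = {}
    for i, (k, l) in enumerate(res.pairs):
        cls = (res.regions[l], res.regions[k])  # (source, target)
        masked[cls] = masked.get(cls, 0.0) + (res.delta[i] * res.mask[i])[fsel].mean(axis=0)
        raw[cls] = raw.get(cls, 0.0) + res.delta[i][fsel].mean(axis=0)
        counts[cls] = counts.get(cls, 0) + 1
    return {
        cls: (masked[cls] / counts[cls], raw[cls] / counts[cls]) for cls in masked
    }


def erc_group(
    sessions: Sequence[ERCResult],
    cfg: StatsConfig | None = None,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    min_sessions: int = 2,
) -> GroupERCResult:
    """Combine session-level ERC results by directed region-pair class.

    Session curves (significant flow change averaged over in-band
    frequencies and class pairs) are tested per time point with a
    two-sided one-sample t test whose standard error is the across-session
    SD of the mean; BH-FDR runs across time points within each class.
    Classes observed in fewer than ``min_sessions`` sessions are excluded
    with a logged warning.
    """
    cfg = cfg or StatsConfig()
    if len(sessions) < min_sessions:
        raise ValueError(f"need >= {min_sessions} sessions")
    times = sessions[0].times
    for s in sessions[1:]:
        if len(s.times) != len(times) or not np.allclose(s.times, times):
            raise ValueError("sessions have mismatched time grids")
    per_class: dict = {}
    for s in sessions:
        for cls, curve_pair in _session_class_curves(s, band).items():
            per_class.setdefault(cls, []).append(curve_pair)
    classes = {}
    for cls, curve_pairs in per_class.items():
        n = len(curve_pairs)
        if n < min_sessions:
            logger.warning(
                "class %s->%s present in only %d session(s); excluded", cls[0], cls[1], n
            )
            continue
        stack = np.vstack([c[0] for c in curve_pairs])
        stack_raw = np.vstack([c[1] for c in curve_pairs])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        sem = sd / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(sd > 0, mean / np.where(sem > 0, sem, np.inf), 0.0)
        p = 2.0 * scipy.stats.t.sf(np.abs(tstat), n - 1)
        p[sd == 0] = 1.0
        rej, q, _, _ = multipletests(p, alpha=cfg.alpha, method="fdr_bh")
        mask = rej & (mean > 0)
        classes[cls] = GroupClassCurve(
            mean=mean, sem=sem, q=q, mask=mask, session_curves=stack,
            session_curves_raw=stack_raw, n_sessions=n,
        )
    return GroupERCResult(
        classes=classes,
        times=times,
        session_ids=tuple(s.session_id for s in sessions),
        band=band,
        alpha=cfg.alpha,
    )


def condition_contrast(
    words: GroupERCResult,
    pseudo: GroupERCResult,
    cfg: StatsConfig | None = None,
) -> dict:
    """Paired word-vs-pseudoword contrast per class and time point.

    Sessions are paired across conditions; per class and time point a
    paired t test of word minus pseudoword session curves is BH-FDR
    corrected across time.  Returns ``class -> (signed mask, q, mean
    difference)`` where the mask sign is the direction of the significant
    difference.
    """
    cfg = cfg or StatsConfig()
    if words.session_ids != pseudo.session_ids:
        raise ValueError("word and pseudoword results cover different sessions")
    if len(words.times) != len(pseudo.times) or not np.allclose(words.times, pseudo.times):
        raise ValueError("mismatched time grids")
    out = {}
    for cls in sorted(set(words.classes) & set(pseudo.classes)):
        w = words.classes[cls].session_curves_raw
        p_ = pseudo.classes[cls].session_curves_raw
        if w.shape != p_.shape:
            raise ValueError(f"class {cls}: session sets differ between conditions")
        d = w - p_
        n = d.shape[0]
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        sem = np.where(sd > 0, sd / np.sqrt(n), np.inf)
        tstat = mean / sem
        p = 2.0 * scipy.stats.t.sf(np.abs(tstat), n - 1)
        p[sd == 0] = 1.0
        rej, q, _, _ = multipletests(p, alpha=cfg.alpha, method="fdr_bh")
        out[cls] = {
            "mask": np.where(rej, np.sign(mean).astype(int), 0),
            "q": q,
            "mean_diff": mean,
        }
    return out


def integrate_flows(
    erc,
    interval: tuple[float, float],
    band: tuple[float, float] = HIGH_GAMMA_BAND,
) -> nx.DiGraph:
    """Mean significant flow change per directed pair over a time interval.

    Accepts a session :class:`ERCResult` (edges between channels) or a
    :class:`GroupERCResult` (edges between region classes).  Pairs/classes
    with no significant points inside the interval get weight 0.
    """
    t0, t1 = interval
    if not t0 < t1:
        raise ValueError("empty integration interval")
    g = nx.DiGraph()
    if isinstance(erc, GroupERCResult):
        tsel = (erc.times >= t0) & (erc.times <= t1)
        if not tsel.any():
            raise ValueError(f"interval {interval} outside the time grid")
        for (src, tgt), cc in erc.classes.items():
            vals = cc.mean[tsel][cc.mask[tsel]]
            g.add_edge(src, tgt, weight=float(vals.mean()) if vals.size else 0.0)
        return g
    tsel = (erc.times >= t0) & (erc.times <= t1)
    if not tsel.any():
        raise ValueError(f"interval {interval} outside the time grid")
    fsel = (erc.freqs >= band[0]) & (erc.freqs <= band[1])
    for i, (k, l) in enumerate(erc.pairs):
        sub_d = erc.delta[i][np.ix_(fsel, tsel)]
        sub_m = erc.mask[i][np.ix_(fsel, tsel)]
        src = erc.channels[l] if erc.channels else l
        tgt = erc.channels[k] if erc.channels else k
        vals = sub_d[sub_m]
        g.add_edge(src, tgt, weight=float(vals.mean()) if vals.size else 0.0)
    return g
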