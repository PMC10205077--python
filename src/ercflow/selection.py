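"""High-gamma activation screen for channel selection.

Channels enter the causality analysis only if they show statistically
significant event-related power augmentation at 60-180 Hz: each
post-stimulus time-frequency power point is compared across trials to the
same trial's baseline mean at that frequency (two-sided paired t test),
with BH-FDR over each channel's (frequency, time) family.  Only increases
select a channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .preprocess import EpochSet, HIGH_GAMMA_BAND

__all__ = [
    "PowerTensor",
    "ChannelSelection",
    "timefreq_power",
    "activation_screen",
    "selection_summary",
    "summary_from_counts",
]


@dataclass(frozen=True)
class PowerTensor:
    """Per-trial spectrogram power ``values[trial, channel, freq, time]``."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # s relative to the alignment event
    channels: tuple = ()

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("power must be nonnegative")
        for name in ("freqs", "times"):
            g = np.asarray(getattr(self, name))
            if g.size > 1 and np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} grid must be strictly increasing")


def timefreq_power(
    ep: EpochSet,
    win_s: float = 0.1,
    step_s: float = 0.01,
    freqs: np.ndarray | None = None,
) -> PowerTensor:
    """Short-time Fourier power per trial and channel.

    Hann windows of ``win_s`` shifted by ``step_s``; power is ``|STFT|^2``.
    If ``freqs`` is given, the nearest FFT bins are returned (all must be
    below Nyquist).
    """
    fs = ep.sampling_rate
    nper = int(round(win_s * fs))
    hop = max(1, int(round(step_s * fs)))
    if nper > ep.n_samples:
        raise ValueError("epoch shorter than one spectral window")
    fgrid = np.fft.rfftfreq(nper, 1.0 / fs)
    if freqs is not None:
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs > fs / 2):
            raise ValueError("requested frequency above Nyquist")
        bin_idx = np.unique([int(np.argmin(np.abs(fgrid - f))) for f in freqs])
    else:
        bin_idx = np.arange(len(fgrid))
    win = scipy.signal.get_window("hann", nper)
    starts = np.arange(0, ep.n_samples - nper + 1, hop)
    # frames: (trials, channels, n_frames, nper)
    idx = starts[:, None] + np.arange(nper)[None, :]
    frames = ep.data[:, :, idx] * win[None, None, None, :]
    spec = np.fft.rfft(frames, axis=-1)
    power = np.abs(spec[..., bin_idx]) ** 2  # (nt, K, T, F)
    power = power.transpose(0, 1, 3, 2)
    times = ep.window[0] + (starts + nper / 2) / fs
    channels = tuple(ch.id for ch in ep.channels) if ep.channels else ()
    return PowerTensor(values=power, freqs=fgrid[bin_idx], times=times, channels=channels)


@dataclass(frozen=True)
class ChannelSelection:
    """Per-channel screen outcome: selected flag and smallest q-value."""

    table: pd.DataFrame  # channel, region, selected, min_q
    alpha: float
    band: tuple[float, float] = HIGH_GAMMA_BAND

    @property
    def selected_channels(self) -> list:
        return list(self.table.loc[self.table["selected"], "channel"])

    def __len__(self) -> int:
        return len(self.table)


def activation_screen(
    task: PowerTensor,
    baseline: PowerTensor,
    alpha: float = 0.05,
    band: tuple[float, float] = HIGH_GAMMA_BAND,
    regions: dict | None = None,
) -> ChannelSelection:
    """Screen channels for significant post-stimulus power increases.

    For each (channel, frequency, task time point), the task power is
    compared across trials to the trial's baseline mean at the same
    frequency (two-sided paired t test).  P-values are BH-FDR corrected
    within each channel over all in-band (f, t) points; a channel is
    selected iff any point is significant with a positive mean change.
    """
    if task.values.shape[1] != baseline.values.shape[1]:
        raise ValueError("task and baseline channel counts differ")
    if not np.allclose(task.freqs, baseline.freqs):
        raise ValueError("task and baseline frequency grids differ")
    nt = task.values.shape[0]
    if nt < 2 or baseline.values.shape[0] != nt:
        raise ValueError("need >= 2 paired trials in task and baseline")
    fsel = (task.freqs >= band[0]) & (task.freqs <= band[1])
    if not fsel.any():
        raise ValueError(f"no frequencies inside band {band}")
    base_mean = baseline.values[:, :, fsel, :].mean(axis=3)  # (nt, K, Fb)
    diffs = task.values[:, :, fsel, :] - base_mean[:, :, :, None]  # (nt,K,Fb,T)
    t, p = scipy.stats.ttest_1samp(diffs, 0.0, axis=0)
    mean_diff = diffs.mean(axis=0)
    K = diffs.shape[1]
    rows = []
    for k in range(K):
        pk = p[k].ravel()
        rej, q, _, _ = multipletests(pk, alpha=alpha, method="fdr_bh")
        sig_increase = rej & (mean_diff[k].ravel() > 0)
        ch = task.channels[k] if task.channels else k
        rows.append(
            {
                "channel": ch,
                "region": (regions or {}).get(ch, ""),
                "selected": bool(sig_increase.any()),
                "min_q": float(np.min(q)) if len(q) else 1.0,
            }
        )
    return ChannelSelection(table=pd.DataFrame(rows), alpha=alpha, band=band)


def summary_from_counts(selected: dict, implanted: dict) -> pd.DataFrame:
    """Selection summary from raw counts per region/group.

    Percentages are rounded to one decimal, e.g. 53 of 124 -> 42.7.
    """
    rows = []
    for region, n_impl in implanted.items():
        n_sel = int(selected.get(region, 0))
        if n_impl < n_sel:
            raise ValueError(
                f"{region}: implanted count {n_impl} < selected count {n_sel}"
            )
        rows.append(
            {
                "region": region,
                "selected": n_sel,
                "implanted": n_impl,
                "percent": round(100.0 * n_sel / n_impl, 1) if n_impl else 0.0,
            }
        )
    return pd.DataFrame(rows)


def selection_summary(sel: ChannelSelection, implanted: dict) -> pd.DataFrame:
    """Counts and percentages of selected channels per region."""
    counts = (
        sel.table[sel.table["selected"]].groupby("region")["channel"].count().to_dict()
    )
    return summary_from_counts(counts, implanted)
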