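"""Continuous recordings to analysis-ready epochs.

Resampling, event-aligned epoching, amplitude-based artifact rejection,
common average referencing, and zero-phase FIR band-pass filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "Channel",
    "SessionRecording",
    "EpochSet",
    "RejectionReport",
    "AllTrialsRejectedError",
    "ANALYSIS_RATE",
    "HIGH_GAMMA_BAND",
    "BASELINE_WINDOW",
    "RESPONSE_WINDOW",
    "resample",
    "epoch",
    "reject_artifacts",
    "common_average_reference",
    "bandpass_zero_phase",
    "design_bandpass_fir",
]

#: Analysis sampling rate: 140 ms windows = 175 samples, 5.6 ms steps = 7.
ANALYSIS_RATE = 1250.0
#: High-gamma band in Hz.
HIGH_GAMMA_BAND = (60.0, 180.0)
#: Cue-aligned pre-stimulus baseline epoch (s).
BASELINE_WINDOW = (-0.52, 0.0)
#: Speech-onset-aligned 1 s response epoch (s).
RESPONSE_WINDOW = (-0.6, 0.4)

_ALIGNMENT_COLUMNS = {
    "cue": "cue_onset_s",
    "stimulus": "stimulus_onset_s",
    "speech_onset": "speech_onset_s",
}


class Channel(NamedTuple):
    id: str
    region: str


class AllTrialsRejectedError(RuntimeError):
    pass


@dataclass
class SessionRecording:
    """Continuous multichannel signals plus channel labels and trial events."""

    signals: np.ndarray  # (K, N)
    sampling_rate: float
    channels: tuple[Channel, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be (channels, samples)")
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError("channel labels do not match signal rows")
        if np.isnan(self.signals).any():
            raise ValueError("signals contain NaNs")
        self.channels = tuple(Channel(*c) for c in self.channels)

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.id == channel_id:
                return i
        raise KeyError(channel_id)


@dataclass
class EpochSet:
    """Trial-aligned segments ``data[trial, channel, sample]``.

    ``window`` is half-open in seconds relative to the alignment event;
    rejected trials are excluded from ``data`` but listed in ``trials``.
    """

    data: np.ndarray  # (n_kept, K, Ns)
    alignment: str
    window: tuple[float, float]
    sampling_rate: float
    channels: tuple[Channel, ...]
    trials: pd.DataFrame  # trial_id, condition, kept, reject_reason
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    @property
    def conditions(self) -> np.ndarray:
        kept = self.trials[self.trials["kept"]]
        return kept["condition"].to_numpy()

    def select_condition(self, condition: str) -> "EpochSet":
        """Sub-epoch set containing only kept trials of one condition."""
        kept = self.trials[self.trials["kept"]].reset_index(drop=True)
        idx = np.nonzero((kept["condition"] == condition).to_numpy())[0]
        trials = self.trials[
            (self.trials["condition"] == condition) | ~self.trials["kept"]
        ].reset_index(drop=True)
        return replace(self, data=self.data[idx], trials=trials)

    def select_channels(self, channel_ids: Sequence[str]) -> "EpochSet":
        index = {ch.id: i for i, ch in enumerate(self.channels)}
        idx = [index[c] for c in channel_ids]
        return replace(
            self,
            data=self.data[:, idx, :],
            channels=tuple(self.channels[i] for i in idx),
        )


def resample(rec: SessionRecording, target_rate: float) -> SessionRecording:
    """Anti-alias filter and resample to ``target_rate``.

    Event times live in seconds and are unchanged.  ``target_rate`` must
    exceed twice the top of the high-gamma band (360 Hz).
    """
    if target_rate <= 2 * HIGH_GAMMA_BAND[1]:
        raise ValueError(
            f"target rate {target_rate} Hz violates Nyquist for the "
            f"{HIGH_GAMMA_BAND[1]} Hz band top"
        )
    if abs(target_rate - rec.sampling_rate) < 1e-9:
        return replace(rec, signals=rec.signals.copy())
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # anti-alias FIR at the upsampled rate: pass edge at 0.8x the output
    # Nyquist, >= 40 dB stopband by the output Nyquist
    fs_up = rec.sampling_rate * up
    nyq_out = min(rec.sampling_rate, target_rate) / 2.0
    transition = 0.2 * nyq_out
    numtaps = int(np.ceil(3.3 * fs_up / transition)) | 1
    h = scipy.signal.firwin(numtaps, 0.9 * nyq_out, fs=fs_up, window="hamming")
    out = scipy.signal.resample_poly(rec.signals, up, down, axis=1, window=h * up)
    return replace(rec, signals=out, sampling_rate=target_rate)


def epoch(
    rec: SessionRecording,
    alignment: str,
    window: tuple[float, float],
) -> EpochSet:
    """Cut event-aligned epochs ``[start, end)`` around each trial's event.

    ``alignment`` is one of ``cue``, ``stimulus``, ``speech_onset``.  Trials
    whose window falls outside the recording are flagged rejected (reason
    ``out_of_bounds``) rather than silently dropped.
    """
    if alignment not in _ALIGNMENT_COLUMNS:
        raise ValueError(f"unknown alignment {alignment!r}")
    col = _ALIGNMENT_COLUMNS[alignment]
    start_s, end_s = window
    if not start_s < end_s:
        raise ValueError("window start must be < end")
    fs = rec.sampling_rate
    n_samp_f = (end_s - start_s) * fs
    if abs(n_samp_f - round(n_samp_f)) > 1e-6:
        raise ValueError(
            f"window length {end_s - start_s}s is not an integer sample count at {fs} Hz"
        )
    n_samp = int(round(n_samp_f))
    rows = []
    segments = []
    for _, ev in rec.events.iterrows():
        t_ev = float(ev[col])
        i0 = int(round(t_ev * fs)) + int(round(start_s * fs))
        trial_id = ev.get("trial_id", len(rows))
        cond = ev.get("condition", "")
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            rows.append((trial_id, cond, False, "out_of_bounds"))
            continue
        segments.append(rec.signals[:, i0 : i0 + n_samp])
        rows.append((trial_id, cond, True, ""))
    trials = pd.DataFrame(rows, columns=["trial_id", "condition", "kept", "reject_reason"])
    data = (
        np.stack(segments, axis=0)
        if segments
        else np.empty((0, rec.n_channels, n_samp))
    )
    return EpochSet(
        data=data,
        alignment=alignment,
        window=window,
        sampling_rate=fs,
        channels=rec.channels,
        trials=trials,
    )


@dataclass(frozen=True)
class RejectionReport:
    """Artifact-rejection summary: counts, percentage and per-trial reasons."""

    n_total: int
    n_rejected: int
    rows: pd.DataFrame  # trial_id, channel, reason

    @property
    def percentage(self) -> float:
        """Rejected share of recorded trials, in percent (two decimals)."""
        return round(100.0 * self.n_rejected / self.n_total, 2)

    @classmethod
    def from_counts(cls, n_rejected: int, n_total: int) -> "RejectionReport":
        return cls(
            n_total=n_total,
            n_rejected=n_rejected,
            rows=pd.DataFrame(columns=["trial_id", "channel", "reason"]),
        )


def reject_artifacts(
    ep: EpochSet, amplitude_sd_threshold: float = 8.0
) -> tuple[EpochSet, RejectionReport]:
    """Flag trials whose peak amplitude exceeds a robust-SD multiple.

    The robust SD per channel is ``1.4826 * MAD`` over all kept epochs; a
    trial is rejected when any channel's peak absolute deviation exceeds
    ``amplitude_sd_threshold`` times that channel's robust SD.  Surrogate
    for manual inspection.
    """
    if ep.n_trials < 1:
        raise ValueError("need at least one trial")
    x = ep.data
    med = np.median(x, axis=(0, 2))  # per channel
    dev = np.abs(x - med[None, :, None])
    robust_sd = 1.4826 * np.median(dev, axis=(0, 2))
    robust_sd = np.where(robust_sd > 0, robust_sd, np.inf)
    peaks = dev.max(axis=2)  # (trials, channels)
    flagged = peaks > amplitude_sd_threshold * robust_sd[None, :]
    bad_trials = np.nonzero(flagged.any(axis=1))[0]
    kept_ids = ep.trials[ep.trials["kept"]].reset_index(drop=True)
    rows = []
    for t in bad_trials:
        for c in np.nonzero(flagged[t])[0]:
            rows.append(
                (
                    kept_ids.loc[t, "trial_id"],
                    ep.channels[c].id,
                    f"amplitude > {amplitude_sd_threshold} robust SD",
                )
            )
    report = RejectionReport(
        n_total=len(ep.trials),
        n_rejected=int(len(bad_trials)) + int((~ep.trials["kept"]).sum()),
        rows=pd.DataFrame(rows, columns=["trial_id", "channel", "reason"]),
    )
    if len(bad_trials) == ep.n_trials:
        raise AllTrialsRejectedError(
            f"all {ep.n_trials} trials exceeded {amplitude_sd_threshold} robust SDs"
        )
    keep_mask = np.ones(ep.n_trials, dtype=bool)
    keep_mask[bad_trials] = False
    trials = ep.trials.copy()
    kept_positions = np.nonzero(trials["kept"].to_numpy())[0]
    for t in bad_trials:
        pos = kept_positions[t]
        trials.loc[pos, "kept"] = False
        trials.loc[pos, "reject_reason"] = "artifact"
    out = replace(ep, data=ep.data[keep_mask], trials=trials)
    return out, report


def common_average_reference(
    ep: EpochSet, group: Sequence[str] | None = None
) -> EpochSet:
    """Subtract the instantaneous mean of ``group`` channels from each of them.

    ``group`` defaults to all channels; singleton groups are rejected.
    Idempotent.
    """
    ids = [ch.id for ch in ep.channels]
    if group is None:
        group = ids
    idx = [ids.index(g) for g in group]
    if len(idx) < 2:
        raise ValueError("CAR group must contain at least 2 channels")
    data = ep.data.copy()
    ref = data[:, idx, :].mean(axis=1, keepdims=True)
    data[:, idx, :] -= ref
    meta = dict(ep.meta, car_group=tuple(group))
    return replace(ep, data=data, meta=meta)


def design_bandpass_fir(
    band: tuple[float, float],
    sampling_rate: float,
    transition_hz: float = 10.0,
) -> np.ndarray:
    """Windowed-sinc band-pass FIR with >= 40 dB stopband at ``transition_hz``."""
    low, high = band
    nyq = sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    numtaps = int(np.ceil(3.3 * sampling_rate / transition_hz))
    numtaps += 1 - numtaps % 2  # odd
    return scipy.signal.firwin(
        numtaps, [low, high], pass_zero=False, fs=sampling_rate, window="hamming"
    )


def bandpass_zero_phase(obj, band: tuple[float, float] = HIGH_GAMMA_BAND):
    """Forward-backward (zero-phase) FIR band-pass.

    Accepts an :class:`EpochSet` or :class:`SessionRecording`; filtering is
    applied along the sample axis.  Edge effects are confined to one filter
    length, recorded in ``meta['filter_edge_samples']`` for epoch sets.
    """
    taps = design_bandpass_fir(band, obj.sampling_rate)
    n = obj.signals.shape[1] if isinstance(obj, SessionRecording) else obj.data.shape[2]
    padlen = min(3 * (len(taps) - 1), n - 1)
    if isinstance(obj, SessionRecording):
        out = scipy.signal.filtfilt(taps, [1.0], obj.signals, axis=1, padlen=padlen)
        return replace(obj, signals=out)
    out = scipy.signal.filtfilt(taps, [1.0], obj.data, axis=2, padlen=padlen)
    meta = dict(obj.meta, filter_edge_samples=len(taps), band=band)
    return replace(obj, data=out, meta=meta)
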