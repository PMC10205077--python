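"""Simulated cohorts with known, time-localized, condition-dependent couplings.

Sessions are realized from stable MVAR networks whose base dynamics are
independent band-limited (high-gamma) AR carriers per channel.  Directed
couplings are time-varying lag coefficients switched on inside windows
defined relative to each trial's speech onset, with a 10 ms cosine taper
at the edges.  Per-channel noise-gain events model task-evoked power
augmentation so the activation screen has ground truth too.

All randomness flows through explicit integer seeds; identical inputs give
bit-identical signals and event tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .mvar import MVARModel, UnstableModelError
from .preprocess import Channel, SessionRecording, ANALYSIS_RATE

__all__ = [
    "CouplingEvent",
    "ActivationEvent",
    "NetworkSpec",
    "TrialTiming",
    "BehaviorParams",
    "SimulatedSession",
    "EpochCollisionError",
    "mvar_generate",
    "sample_behavior",
    "simulate_session",
    "build_default_cohort",
    "band_limited_ar2",
    "independent_network",
]

REGIONS = ("STN", "PreCG", "PoCG", "STG")
CONDITIONS = ("word", "pseudoword")

#: Cosine taper length for switching couplings/activations on and off.
TAPER_S = 0.010
#: Samples discarded before the first usable output of the recursion.
DEFAULT_BURN_IN = 1000


class EpochCollisionError(RuntimeError):
    pass


@dataclass(frozen=True)
class CouplingEvent:
    """A directed lag coupling active in a window relative to speech onset.

    ``window`` is half-open ``(start_s, end_s)`` relative to the alignment
    event (speech onset); ``condition`` restricts the coupling to word or
    pseudoword trials (``both`` = always active).
    """

    source: str
    target: str
    gain: float
    lag: int
    window: tuple[float, float]
    condition: str = "both"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("coupling source must differ from target")
        if not self.window[0] < self.window[1]:
            raise ValueError("coupling window start must be < end")
        if not math.isfinite(self.gain):
            raise ValueError("coupling gain must be finite")
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        if self.condition not in CONDITIONS + ("both",):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class ActivationEvent:
    """Noise-gain multiplier for one channel inside a speech-aligned window.

    Models event-related power augmentation (the quantity the channel
    screen tests for); ``gain`` multiplies the channel's innovation SD.
    """

    channel: str
    gain: float
    window: tuple[float, float]
    condition: str = "both"

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("activation window start must be < end")
        if self.gain <= 0:
            raise ValueError("activation gain must be > 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth network: base model, couplings and activations."""

    channels: tuple[Channel, ...]
    base_model: MVARModel
    couplings: tuple[CouplingEvent, ...] = ()
    activations: tuple[ActivationEvent, ...] = ()
    noise_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(Channel(*c) for c in self.channels))
        if self.base_model.n_channels != len(self.channels):
            raise ValueError("base_model size does not match channel list")
        ids = [c.id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate channel ids")
        for cp in self.couplings:
            if cp.source not in ids or cp.target not in ids:
                raise ValueError(f"coupling references unknown channel: {cp}")
            if cp.lag > self.effective_order:
                raise ValueError(
                    f"coupling lag {cp.lag} exceeds model order {self.effective_order}"
                )
        for ac in self.activations:
            if ac.channel not in ids:
                raise ValueError(f"activation references unknown channel: {ac}")
        if self.noise_sd is not None:
            sd = np.asarray(self.noise_sd, dtype=float)
            if sd.shape != (len(ids),) or np.any(sd < 0):
                raise ValueError("noise_sd must be a nonnegative per-channel vector")
            object.__setattr__(self, "noise_sd", sd)
        self.require_stable()

    @property
    def effective_order(self) -> int:
        return self.base_model.order

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(channel_id)

    def _model_with(self, couplings: Sequence[CouplingEvent]) -> MVARModel:
        coeffs = self.base_model.coeffs.copy()
        for cp in couplings:
            coeffs[cp.lag - 1, self.channel_index(cp.target), self.channel_index(cp.source)] += cp.gain
        return MVARModel(coeffs, self.base_model.noise_cov, self.base_model.sampling_rate)

    def _concurrent_sets(self) -> list[tuple[CouplingEvent, ...]]:
        """Coupling sets that can be active simultaneously in some condition."""
        sets: list[tuple[CouplingEvent, ...]] = []
        for cond in CONDITIONS:
            cps = [c for c in self.couplings if c.condition in ("both", cond)]
            times = sorted({t for c in cps for t in c.window})
            for t0 in times:
                active = tuple(c for c in cps if c.window[0] <= t0 < c.window[1])
                if active and active not in sets:
                    sets.append(active)
        return sets

    def require_stable(self) -> None:
        """Stability with no coupling, each coupling alone, and every set of
        couplings that can be simultaneously active."""
        checks: list[tuple[str, tuple[CouplingEvent, ...]]] = [("base model", ())]
        checks += [(f"coupling {cp.source}->{cp.target}", (cp,)) for cp in self.couplings]
        checks += [
            (
                "concurrent couplings " + ", ".join(f"{c.source}->{c.target}" for c in cps),
                cps,
            )
            for cps in self._concurrent_sets()
        ]
        for label, cps in checks:
            model = self._model_with(cps)
            rho = model.spectral_radius()
            if rho >= 1.0:
                raise UnstableModelError(
                    f"{label}: companion spectral radius {rho:.4f} >= 1"
                )


@dataclass(frozen=True)
class TrialTiming:
    """Event times (absolute seconds) and phoneme durations for one trial."""

    condition: str
    cue_onset_s: float
    stimulus_onset_s: float
    speech_onset_s: float
    c1_dur_s: float
    v_dur_s: float
    c2_dur_s: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not self.cue_onset_s < self.stimulus_onset_s < self.speech_onset_s:
            raise ValueError("require cue < stimulus < speech onset")
        if min(self.c1_dur_s, self.v_dur_s, self.c2_dur_s) <= 0:
            raise ValueError("phoneme durations must be > 0")

    @property
    def latency_s(self) -> float:
        return self.speech_onset_s - self.stimulus_onset_s

    @property
    def response_dur_s(self) -> float:
        return self.c1_dur_s + self.v_dur_s + self.c2_dur_s


@dataclass(frozen=True)
class BehaviorParams:
    """Trial-timing distributions (seconds).

    Latency and duration means follow the reported task behavior (word
    latency 736 ms, pseudoword 818 ms; condition-specific C1/V/C2 means).
    Trial-level SDs are a modelling choice: reported SEMs reflect mostly
    between-session spread, which enters separately as a session offset
    in the cohort builder.
    """

    latency_mean: dict = field(
        default_factory=lambda: {"word": 0.736, "pseudoword": 0.818}
    )
    latency_sd: dict = field(
        default_factory=lambda: {"word": 0.150, "pseudoword": 0.150}
    )
    c1_mean: dict = field(default_factory=lambda: {"word": 0.093, "pseudoword": 0.105})
    v_mean: dict = field(default_factory=lambda: {"word": 0.217, "pseudoword": 0.203})
    c2_mean: dict = field(default_factory=lambda: {"word": 0.170, "pseudoword": 0.187})
    c1_sd: dict = field(default_factory=lambda: {"word": 0.020, "pseudoword": 0.025})
    v_sd: dict = field(default_factory=lambda: {"word": 0.030, "pseudoword": 0.028})
    c2_sd: dict = field(default_factory=lambda: {"word": 0.030, "pseudoword": 0.032})
    isi_range: tuple[float, float] = (0.5, 1.0)
    cue_duration: float = 0.25
    intertrial_gap: float = 1.3

    def __post_init__(self) -> None:
        for name in ("latency_mean", "c1_mean", "v_mean", "c2_mean"):
            for cond, m in getattr(self, name).items():
                if m <= 0:
                    raise ValueError(f"{name}[{cond!r}] must be > 0, got {m}")
        for name in ("latency_sd", "c1_sd", "v_sd", "c2_sd"):
            for cond, s in getattr(self, name).items():
                if s < 0:
                    raise ValueError(f"{name}[{cond!r}] must be >= 0")
        if not self.isi_range[0] <= self.isi_range[1]:
            raise ValueError("isi range low must be <= high")

    def shifted(self, latency_offset_s: float) -> "BehaviorParams":
        """Same distributions with both condition latency means offset."""
        new_means = {
            c: max(0.2, m + latency_offset_s) for c, m in self.latency_mean.items()
        }
        return replace(self, latency_mean=new_means)


@dataclass
class SimulatedSession:
    """A simulated recording with its generating truth."""

    recording: SessionRecording
    truth: NetworkSpec
    trials: list[TrialTiming]
    seed: int
    subject: str = "S1"
    session: int = 1


def _draw_truncnorm(rng, mean, sd, size):
    """Normal(mean, sd) truncated at zero; degenerate when sd == 0."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return scipy.stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def mvar_generate(
    model: MVARModel,
    n_samples: int,
    seed: int,
    burn_in: int = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Stationary realization of a stable MVAR model, shape ``(K, n_samples)``.

    The recursion ``x(t) = sum_j B_j x(t-j) + e(t)`` is run for
    ``burn_in + n_samples`` steps from zero initial conditions and the
    burn-in is discarded.  Deterministic for a fixed seed.
    """
    model.require_stable()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p, K = model.order, model.n_channels
    total = n_samples + burn_in
    L = np.linalg.cholesky(model.noise_cov + 1e-15 * np.eye(K))
    e = rng.standard_normal((total, K)) @ L.T
    if not model.coeffs.any():
        return e[burn_in:].T.copy()
    # Stacked coefficients act on [x(t-1); ...; x(t-p)].
    Bstack = np.concatenate(list(model.coeffs), axis=1)  # (K, K*p)
    x = np.zeros((total + p, K))
    for t in range(p, total + p):
        past = x[t - p : t][::-1].reshape(-1)  # x(t-1) first
        x[t] = Bstack @ past + e[t - p]
    return x[p + burn_in :].T.copy()


def sample_behavior(
    params: BehaviorParams,
    n_trials: int,
    seed: int,
    first_condition: str = "word",
    t_start: float = 2.0,
) -> list[TrialTiming]:
    """Sample a strictly alternating word/pseudoword trial schedule.

    Latencies and phoneme durations are drawn from zero-truncated normal
    distributions; cue onsets are scheduled sequentially with the
    configured cue duration, uniform ISI, and intertrial gap.
    """
    if n_trials % 2 != 0:
        raise ValueError("n_trials must be even for strict alternation")
    if first_condition not in CONDITIONS:
        raise ValueError(f"unknown condition {first_condition!r}")
    rng = np.random.default_rng(seed)
    other = "pseudoword" if first_condition == "word" else "word"
    conditions = [first_condition if i % 2 == 0 else other for i in range(n_trials)]
    trials: list[TrialTiming] = []
    cursor = t_start
    for cond in conditions:
        isi = rng.uniform(*params.isi_range)
        latency = float(_draw_truncnorm(rng, params.latency_mean[cond], params.latency_sd[cond], 1)[0])
        c1 = float(_draw_truncnorm(rng, params.c1_mean[cond], params.c1_sd[cond], 1)[0])
        v = float(_draw_truncnorm(rng, params.v_mean[cond], params.v_sd[cond], 1)[0])
        c2 = float(_draw_truncnorm(rng, params.c2_mean[cond], params.c2_sd[cond], 1)[0])
        cue = cursor
        stim = cue + params.cue_duration + isi
        speech = stim + latency
        trials.append(
            TrialTiming(
                condition=cond,
                cue_onset_s=cue,
                stimulus_onset_s=stim,
                speech_onset_s=speech,
                c1_dur_s=c1,
                v_dur_s=v,
                c2_dur_s=c2,
            )
        )
        cursor = speech + c1 + v + c2 + params.intertrial_gap
    return trials


def _tapered_envelope(n: int, start: int, stop: int, fs: float) -> np.ndarray:
    """0/1 envelope over ``[start, stop)`` with 10 ms raised-cosine edges."""
    env = np.zeros(n)
    start = max(start, 0)
    stop = min(stop, n)
    if stop <= start:
        return env
    env[start:stop] = 1.0
    taper = min(int(round(TAPER_S * fs)), (stop - start) // 2)
    if taper > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(taper) + 0.5) / taper))
        env[start : start + taper] = ramp
        env[stop - taper : stop] = ramp[::-1]
    return env


def events_table(trials: Sequence[TrialTiming]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "condition": [t.condition for t in trials],
            "cue_onset_s": [t.cue_onset_s for t in trials],
            "stimulus_onset_s": [t.stimulus_onset_s for t in trials],
            "speech_onset_s": [t.speech_onset_s for t in trials],
            "c1_dur_s": [t.c1_dur_s for t in trials],
            "v_dur_s": [t.v_dur_s for t in trials],
            "c2_dur_s": [t.c2_dur_s for t in trials],
        }
    )


def _check_epoch_collisions(trials: Sequence[TrialTiming], span_s: float = 0.65) -> None:
    """Trials must be far enough apart that analysis epochs cannot overlap."""
    colliding = []
    for i in range(len(trials) - 1):
        this_end = trials[i].speech_onset_s + 0.45
        next_start = trials[i + 1].cue_onset_s - span_s
        if this_end > next_start:
            colliding.append((i, i + 1))
    if colliding:
        raise EpochCollisionError(f"overlapping trial epochs: {colliding}")


def simulate_session(
    net: NetworkSpec,
    params: BehaviorParams | None = None,
    n_trials: int = 60,
    seed: int = 0,
    sampling_rate: float = ANALYSIS_RATE,
    subject: str = "S1",
    session: int = 1,
    first_condition: str = "word",
) -> SimulatedSession:
    """Simulate one task session from a ground-truth network.

    Couplings and activations are switched on inside their speech-aligned
    windows (cosine-tapered) on trials matching their condition; the rest
    of the recording follows the base model.
    """
    if params is None:
        params = BehaviorParams()
    rng = np.random.default_rng(seed)
    behavior_seed, noise_seed = rng.integers(0, 2**31 - 1, size=2)
    trials = sample_behavior(params, n_trials, int(behavior_seed), first_condition)
    _check_epoch_collisions(trials)

    fs = sampling_rate
    model = net.base_model
    if abs(model.sampling_rate - fs) > 1e-9:
        model = MVARModel(model.coeffs, model.noise_cov, fs)
    p, K = model.order, model.n_channels
    duration = trials[-1].speech_onset_s + trials[-1].response_dur_s + 2.0
    n = int(math.ceil(duration * fs))

    # Per-sample coupling envelopes, grouped by (target, source, lag).
    coupling_ramps: list[tuple[int, int, int, np.ndarray]] = []
    for cp in net.couplings:
        env = np.zeros(n)
        for tr in trials:
            if cp.condition != "both" and tr.condition != cp.condition:
                continue
            s0 = int(round((tr.speech_onset_s + cp.window[0]) * fs))
            s1 = int(round((tr.speech_onset_s + cp.window[1]) * fs))
            env += _tapered_envelope(n, s0, s1, fs)
        np.clip(env, 0.0, 1.0, out=env)
        coupling_ramps.append(
            (net.channel_index(cp.target), net.channel_index(cp.source), cp.lag, env * cp.gain)
        )

    # Per-sample noise-gain envelopes.
    noise_gain = np.ones((n, K))
    for ac in net.activations:
        env = np.zeros(n)
        for tr in trials:
            if ac.condition != "both" and tr.condition != ac.condition:
                continue
            s0 = int(round((tr.speech_onset_s + ac.window[0]) * fs))
            s1 = int(round((tr.speech_onset_s + ac.window[1]) * fs))
            env += _tapered_envelope(n, s0, s1, fs)
        np.clip(env, 0.0, 1.0, out=env)
        noise_gain[:, net.channel_index(ac.channel)] *= 1.0 + (ac.gain - 1.0) * env

    nrng = np.random.default_rng(int(noise_seed))
    sd = net.noise_sd if net.noise_sd is not None else np.sqrt(np.diag(model.noise_cov))
    e = nrng.standard_normal((n + DEFAULT_BURN_IN, K)) * sd
    e[DEFAULT_BURN_IN:] *= noise_gain

    Bstack = np.concatenate(list(model.coeffs), axis=1)
    total = n + DEFAULT_BURN_IN
    x = np.zeros((total + p, K))
    active = np.zeros(total, dtype=bool)
    for tgt, src, lag, ramp in coupling_ramps:
        nz = ramp != 0
        active[DEFAULT_BURN_IN:][nz] = True
    ramp_list = [
        (tgt, src, lag, np.concatenate([np.zeros(DEFAULT_BURN_IN), ramp]))
        for tgt, src, lag, ramp in coupling_ramps
    ]
    for t in range(p, total + p):
        past = x[t - p : t][::-1].reshape(-1)
        xt = Bstack @ past + e[t - p]
        ti = t - p
        if active[ti] if ti < total else False:
            for tgt, src, lag, ramp in ramp_list:
                g = ramp[ti]
                if g != 0.0:
                    xt[tgt] += g * x[t - lag, src]
        x[t] = xt
    signals = x[p + DEFAULT_BURN_IN :].T.copy()

    rec = SessionRecording(
        signals=signals,
        sampling_rate=fs,
        channels=net.channels,
        events=events_table(trials),
    )
    return SimulatedSession(
        recording=rec, truth=net, trials=trials, seed=seed,
        subject=subject, session=session,
    )


# ---------------------------------------------------------------------------
# Default cohort
# ---------------------------------------------------------------------------

def band_limited_ar2(
    center_hz: float, sampling_rate: float = ANALYSIS_RATE, r: float = 0.75
) -> np.ndarray:
    """AR(2) coefficients resonant at ``center_hz`` (high-gamma carrier)."""
    w = 2 * np.pi * center_hz / sampling_rate
    return np.array([2 * r * np.cos(w), -(r**2)])


def independent_network(
    channels: Sequence[tuple[str, str]],
    centers_hz: Sequence[float] | None = None,
    sampling_rate: float = ANALYSIS_RATE,
    r: float = 0.75,
) -> NetworkSpec:
    """Network of mutually independent band-limited AR(2) channels."""
    channels = [Channel(*c) for c in channels]
    K = len(channels)
    if centers_hz is None:
        centers_hz = [100 + 15 * (i % 5) for i in range(K)]
    coeffs = np.zeros((2, K, K))
    for i, f0 in enumerate(centers_hz):
        a = band_limited_ar2(f0, sampling_rate, r)
        coeffs[0, i, i] = a[0]
        coeffs[1, i, i] = a[1]
    model = MVARModel(coeffs, np.eye(K), sampling_rate)
    return NetworkSpec(channels=tuple(channels), base_model=model)


#: Ground-truth coupling windows (s, relative to speech onset).
STG_BURST_WINDOW = (-0.45, -0.40)
LEXICALITY_WINDOW = (-0.208, -0.117)

DEFAULT_COHORT_SUBJECTS = ("S1", "S1", "S1", "S2", "S2", "S2", "S3", "S3", "S4", "S4")


def default_session_network(
    seed: int = 0,
    word_gain: float = 0.40,
    pseudoword_gain: float = 0.20,
    jitter: float = 0.05,
) -> NetworkSpec:
    """The shared cohort motif with per-session gain jitter.

    Channels: 3 STN sites plus 7 cortical sites, of which STN1, PreCG1,
    PoCG1 and STG1 carry task-evoked power augmentation (so the screen
    selects them).  Couplings: an STG1->STN1 pre-speech burst at
    (-450, -400) ms (both conditions), a lexicality-dependent STG1->STN1
    coupling at (-208, -117) ms with word gain > pseudoword gain,
    reciprocal STN1<->PoCG1, and PreCG1->STN1.
    """
    rng = np.random.default_rng(seed)
    channels = [
        ("STN1", "STN"), ("STN2", "STN"), ("STN3", "STN"),
        ("PreCG1", "PreCG"), ("PoCG1", "PoCG"), ("STG1", "STG"),
        ("PreCG2", "PreCG"), ("PoCG2", "PoCG"), ("STG2", "STG"),
        ("PoCG3", "PoCG"),
    ]
    centers = [105, 95, 140, 120, 110, 130, 100, 125, 115, 135]

    def j(g: float) -> float:
        return float(g * (1.0 + jitter * rng.standard_normal()))

    net = independent_network(channels, centers)
    couplings = (
        CouplingEvent("STG1", "STN1", j(0.40), 1, STG_BURST_WINDOW, "both"),
        CouplingEvent("STG1", "STN1", j(word_gain), 1, LEXICALITY_WINDOW, "word"),
        CouplingEvent("STG1", "STN1", j(pseudoword_gain), 1, LEXICALITY_WINDOW, "pseudoword"),
        CouplingEvent("STN1", "PoCG1", j(0.25), 1, (-0.30, -0.10), "both"),
        CouplingEvent("PoCG1", "STN1", j(0.25), 2, (-0.10, 0.10), "both"),
        CouplingEvent("PreCG1", "STN1", j(0.25), 1, (-0.25, 0.0), "both"),
    )
    activations = tuple(
        ActivationEvent(ch, 1.6, (-0.5, 0.3)) for ch in ("STN1", "PreCG1", "PoCG1", "STG1")
    )
    return replace(net, couplings=couplings, activations=activations)


def build_default_cohort(
    seed: int,
    n_sessions: int = 10,
    n_trials: int = 60,
    session_latency_sd: float = 0.10,
) -> list[SimulatedSession]:
    """Ten-session cohort (four subjects) sharing the default network motif.

    Each session carries jittered coupling gains (word STG->STN gain kept
    strictly above the pseudoword gain) and a shared per-session latency
    offset applied to both conditions, emulating between-session behavioral
    spread.
    """
    root = np.random.default_rng(seed)
    sessions = []
    per_subject_counter: dict[str, int] = {}
    for i in range(n_sessions):
        subj = DEFAULT_COHORT_SUBJECTS[i % len(DEFAULT_COHORT_SUBJECTS)]
        per_subject_counter[subj] = per_subject_counter.get(subj, 0) + 1
        net_seed, sess_seed = root.integers(0, 2**31 - 1, size=2)
        net = default_session_network(int(net_seed))
        # invariant of the motif: word gain strictly above pseudoword gain
        wg = next(c.gain for c in net.couplings if c.condition == "word")
        pg = next(c.gain for c in net.couplings if c.condition == "pseudoword")
        if wg <= pg:  # jitter safeguard; regenerate deterministically
            net = default_session_network(int(net_seed) + 1)
        offset = float(root.normal(0.0, session_latency_sd))
        params = BehaviorParams().shifted(offset)
        sessions.append(
            simulate_session(
                net,
                params=params,
                n_trials=n_trials,
                seed=int(sess_seed),
                subject=subj,
                session=per_subject_counter[subj],
                first_condition="word" if i % 2 == 0 else "pseudoword",
            )
        )
    return sessions
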