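"""End-to-end orchestration: session runs, group pooling, reporting.

``run_session`` composes preprocessing -> activation screen -> sliding
SdDTF -> session ERC; ``run_group`` pools sessions into region-pair class
statistics, condition contrasts and integrated flow graphs.  Figures
mirror the study's output styles (flow diagrams with the smallest edges
trimmed; group time courses with phoneme-epoch shading).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import behavior as bh
from . import io as ercio
from . import mvar, preprocess as pp, selection as sel, stats as st
from .synthetic import SimulatedSession

__all__ = [
    "PipelineConfig",
    "SessionResult",
    "GroupResult",
    "run_session",
    "run_group",
    "render_flow_diagram",
    "render_timecourse",
]

logger = logging.getLogger(__name__)

#: Pooled phoneme-duration means (s) used for timecourse shading.
DEFAULT_PHONEME_MEANS = (0.097, 0.207, 0.177)


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis parameters in one declarative object."""

    analysis_rate: float = pp.ANALYSIS_RATE
    band: tuple[float, float] = pp.HIGH_GAMMA_BAND
    baseline_window: tuple[float, float] = pp.BASELINE_WINDOW
    response_window: tuple[float, float] = pp.RESPONSE_WINDOW
    window_len_s: float = mvar.WINDOW_LEN_S
    step_s: float = mvar.WINDOW_STEP_S
    order: int | None = None  # None -> AIC selection
    p_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    freq_step: float = 4.0
    artifact_threshold: float = 8.0
    screen_alpha: float = 0.05
    stats: st.StatsConfig = field(default_factory=st.StatsConfig)
    min_sessions: int = 2

    def __post_init__(self) -> None:
        for name, w in (("baseline", self.baseline_window), ("response", self.response_window)):
            ns = (w[1] - w[0]) * self.analysis_rate
            if abs(ns - round(ns)) > 1e-6:
                raise ValueError(f"{name} window is not an integer sample count")
        if not (0 < self.band[0] < self.band[1] < self.analysis_rate / 2):
            raise ValueError("band must lie inside (0, rate/2)")

    @property
    def freqs(self) -> np.ndarray:
        return mvar.default_freq_grid(self.band[0], self.band[1], self.freq_step)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    """Everything produced by one session run."""

    session_id: str
    selection: sel.ChannelSelection
    flows: dict  # condition -> (task FlowTensor, baseline FlowTensor)
    erc: dict  # condition -> ERCResult
    behavior_table: pd.DataFrame
    behavior_summary: pd.DataFrame
    rejection: pp.RejectionReport
    order: int
    sufficiency: mvar.SufficiencyResult
    regions: tuple
    provenance: dict = field(default_factory=dict)


def _load(session) -> tuple[pp.SessionRecording, str]:
    if isinstance(session, SimulatedSession):
        return session.recording, f"{session.subject}-s{session.session}"
    if isinstance(session, pp.SessionRecording):
        return session, "session"
    rec = ercio.read_session(session)
    return rec, Path(session).name


def run_session(session, cfg: PipelineConfig | None = None) -> SessionResult:
    """Run the full single-session analysis.

    Steps: resample to the analysis rate, zero-phase band-pass, epoch
    (cue-aligned baseline, speech-aligned response), artifact rejection,
    common average reference, activation screen, sliding SdDTF and
    session-level ERC for pooled trials and per condition.
    """
    cfg = cfg or PipelineConfig()
    rec, session_id = _load(session)
    if abs(rec.sampling_rate - cfg.analysis_rate) > 1e-9:
        rec = pp.resample(rec, cfg.analysis_rate)
    rec = pp.bandpass_zero_phase(rec, cfg.band)

    base_ep = pp.epoch(rec, "cue", cfg.baseline_window)
    resp_ep = pp.epoch(rec, "speech_onset", cfg.response_window)
    resp_ep, rejection = pp.reject_artifacts(resp_ep, cfg.artifact_threshold)
    # keep only trials retained in both epochings, so task and baseline match
    resp_kept = resp_ep.trials["kept"].to_numpy()
    base_kept = base_ep.trials["kept"].to_numpy()
    combined = resp_kept & base_kept
    idx = np.nonzero(combined)[0]
    resp_ep.data = resp_ep.data[(np.cumsum(resp_kept) - 1)[idx]]
    base_ep.data = base_ep.data[(np.cumsum(base_kept) - 1)[idx]]
    trials = resp_ep.trials.copy()
    trials["kept"] = combined
    resp_ep.trials = trials
    base_ep.trials = trials.copy()

    resp_ep = pp.common_average_reference(resp_ep)
    base_ep = pp.common_average_reference(base_ep)

    regions_map = {ch.id: ch.region for ch in rec.channels}
    task_power = sel.timefreq_power(resp_ep)
    base_power = sel.timefreq_power(base_ep)
    selection = sel.activation_screen(
        task_power, base_power, alpha=cfg.screen_alpha, band=cfg.band, regions=regions_map
    )
    chosen = selection.selected_channels
    if len(chosen) < 2:
        raise RuntimeError(
            f"{session_id}: only {len(chosen)} channel(s) passed the activation screen"
        )
    resp_sel = resp_ep.select_channels(chosen)
    base_sel = base_ep.select_channels(chosen)

    grid = mvar.WindowGrid(
        n_epoch_samples=resp_sel.n_samples,
        sampling_rate=cfg.analysis_rate,
        window_len_s=cfg.window_len_s,
        step_s=cfg.step_s,
    )
    nt, K = resp_sel.n_trials, resp_sel.n_channels
    if cfg.order is None:
        p_ok = [p for p in cfg.p_range if mvar.check_sufficiency(K, p, grid.Ns, nt).passed]
        if not p_ok:
            worst = mvar.check_sufficiency(K, min(cfg.p_range), grid.Ns, nt)
            raise RuntimeError(
                f"{session_id}: no candidate order satisfies the sufficiency "
                f"inequality (ratio {worst.ratio:.4f} >= {worst.threshold})"
            )
        order = mvar.select_order_aic(resp_sel, p_ok, grid=grid)
    else:
        order = cfg.order
    suff = mvar.check_sufficiency(K, order, grid.Ns, nt)
    logger.info("%s: order %d, sufficiency ratio %.4f", session_id, order, suff.ratio)
    if not suff.passed:
        raise RuntimeError(
            f"{session_id}: sufficiency check failed, K(p+1)/(Ns*nt) = "
            f"{suff.ratio:.4f} >= {suff.threshold}"
        )

    base_grid = mvar.WindowGrid(
        n_epoch_samples=base_sel.n_samples,
        sampling_rate=cfg.analysis_rate,
        window_len_s=cfg.window_len_s,
        step_s=cfg.step_s,
    )
    sel_regions = tuple(regions_map[c] for c in chosen)
    flows: dict = {}
    erc: dict = {}
    for cond in ("pooled", "word", "pseudoword"):
        t_ep = resp_sel if cond == "pooled" else resp_sel.select_condition(cond)
        b_ep = base_sel if cond == "pooled" else base_sel.select_condition(cond)
        task_flow = mvar.sliding_sddtf(t_ep, order, cfg.freqs, grid)
        base_flow = mvar.sliding_sddtf(b_ep, order, cfg.freqs, base_grid)
        flows[cond] = (task_flow, base_flow)
        erc[cond] = st.erc_session(
            task_flow, base_flow, cfg.stats, regions=sel_regions, session_id=session_id
        )

    trials = ercio.read_trials(session) if isinstance(session, (str, Path)) else (
        session.trials if isinstance(session, SimulatedSession) else None
    )
    if trials is not None:
        btable, _ = bh.response_metrics(trials)
        bsummary = bh.condition_summary(btable)
    else:
        btable = pd.DataFrame()
        bsummary = pd.DataFrame()

    return SessionResult(
        session_id=session_id,
        selection=selection,
        flows=flows,
        erc=erc,
        behavior_table=btable,
        behavior_summary=bsummary,
        rejection=rejection,
        order=order,
        sufficiency=suff,
        regions=sel_regions,
        provenance={"config_hash": cfg.config_hash()},
    )


@dataclass
class GroupResult:
    group: dict  # condition -> GroupERCResult
    contrast: dict  # class -> signed mask / q / mean_diff
    graphs: dict  # (condition, preset) -> nx.DiGraph
    behavior_table: pd.DataFrame
    session_ids: tuple
    provenance: dict = field(default_factory=dict)


def run_group(
    sessions: Sequence, cfg: PipelineConfig | None = None
) -> GroupResult:
    """Pool >= 2 session runs into group statistics and flow graphs.

    Accepts session inputs (paths / simulated sessions) or precomputed
    :class:`SessionResult` objects.
    """
    cfg = cfg or PipelineConfig()
    if len(sessions) < cfg.min_sessions:
        raise ValueError(f"need >= {cfg.min_sessions} sessions, got {len(sessions)}")
    results = [
        s if isinstance(s, SessionResult) else run_session(s, cfg) for s in sessions
    ]
    rates = {r.erc["pooled"].meta.get("rate", cfg.analysis_rate) for r in results}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates across sessions: {sorted(rates)}")
    group = {
        cond: st.erc_group(
            [r.erc[cond] for r in results], cfg.stats, band=cfg.band,
            min_sessions=cfg.min_sessions,
        )
        for cond in ("pooled", "word", "pseudoword")
    }
    contrast = st.condition_contrast(group["word"], group["pseudoword"], cfg.stats)
    graphs = {
        (cond, name): st.integrate_flows(group[cond], interval, band=cfg.band)
        for name, interval in st.INTEGRATION_PRESETS.items()
        for cond in ("pooled", "word", "pseudoword")
    }
    btable = pd.concat(
        [r.behavior_table.assign(session=r.session_id) for r in results],
        ignore_index=True,
    )
    return GroupResult(
        group=group,
        contrast=contrast,
        graphs=graphs,
        behavior_table=btable,
        session_ids=tuple(r.session_id for r in results),
        provenance={"config_hash": cfg.config_hash()},
    )


def render_flow_diagram(graph, trim_fraction: float = 0.15, path: str | None = None):
    """Directed flow diagram with the smallest edges trimmed.

    The smallest ``floor(trim_fraction * n_nonzero)`` nonzero edges are
    dropped (rounding down); arrow width and color are monotone in edge
    weight.  Returns ``(figure, kept edge list)``.
    """
    import networkx as nx

    if not 0 <= trim_fraction < 1:
        raise ValueError("trim_fraction must be in [0, 1)")
    edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
    if any(w < 0 for *_, w in edges):
        raise ValueError("graph weights must be >= 0")
    nonzero = sorted((e for e in edges if e[2] > 0), key=lambda e: e[2])
    n_drop = math.floor(trim_fraction * len(nonzero))
    kept = nonzero[n_drop:]
    fig, ax = plt.subplots(figsize=(5, 5))
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for u, v, w in kept:
        g.add_edge(u, v, weight=w)
    pos = nx.circular_layout(g)
    wmax = max((w for *_, w in kept), default=1.0)
    widths = [0.5 + 4.0 * w / wmax for *_, w in kept]
    colors = [w / wmax for *_, w in kept]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="lightgray", node_size=900)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    if kept:
        nx.draw_networkx_edges(
            g, pos, ax=ax, width=widths, edge_color=colors, edge_cmap=plt.cm.viridis,
            connectionstyle="arc3,rad=0.15",
        )
    ax.set_axis_off()
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig, kept


def render_timecourse(
    group: st.GroupERCResult,
    phoneme_means: tuple[float, float, float] = DEFAULT_PHONEME_MEANS,
    classes: Sequence[tuple[str, str]] | None = None,
    path: str | None = None,
):
    """Group flow-change time courses with significance markers.

    One panel per region-pair class: mean +/- SEM across sessions,
    asterisks at significant time points, and shaded C1/V/C2 epochs from
    the pooled phoneme-duration means.  Time zero is speech onset.
    """
    keys = list(classes) if classes is not None else sorted(group.classes)
    keys = [k for k in keys if k in group.classes]
    n = max(len(keys), 1)
    fig, axes = plt.subplots(n, 1, figsize=(7, 2.2 * n), squeeze=False, sharex=True)
    c1, v, c2 = phoneme_means
    spans = [(0.0, c1, "C1"), (c1, c1 + v, "V"), (c1 + v, c1 + v + c2, "C2")]
    for ax, cls in zip(axes[:, 0], keys):
        cc = group.classes[cls]
        t = group.times
        ax.fill_between(t, cc.mean - cc.sem, cc.mean + cc.sem, alpha=0.3)
        ax.plot(t, cc.mean, lw=1.2)
        if cc.mask.any():
            ymax = (cc.mean + cc.sem).max()
            ax.plot(t[cc.mask], np.full(cc.mask.sum(), ymax * 1.05), "*", ms=4)
        for s0, s1, label in spans:
            ax.axvspan(s0, s1, alpha=0.12, color="gray")
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_ylabel(f"{cls[0]}→{cls[1]}", fontsize=8)
    axes[-1, 0].set_xlabel("time re speech onset (s)")
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig
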