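"""Session directory I/O.

A session directory holds:

* ``signals.h5`` — dataset ``signals`` (channels x samples, float) with
  attrs ``sampling_rate_hz``, ``channel_ids``, ``channel_regions``;
* ``events.csv`` — one row per trial (trial_id, condition, onsets, phoneme
  durations);
* ``truth.json`` — the generating network (simulated sessions only);
* ``meta.json`` — subject, session number, seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mvar import MVARModel
from .preprocess import Channel, SessionRecording
from .synthetic import (
    ActivationEvent,
    CouplingEvent,
    NetworkSpec,
    SimulatedSession,
    TrialTiming,
)

__all__ = [
    "write_session",
    "read_session",
    "read_truth",
    "read_trials",
    "save_flow_tensor",
    "load_flow_tensor",
    "save_erc_result",
    "load_erc_result",
]

_EVENT_COLUMNS = [
    "trial_id", "condition", "cue_onset_s", "stimulus_onset_s",
    "speech_onset_s", "c1_dur_s", "v_dur_s", "c2_dur_s",
]


def _network_to_json(net: NetworkSpec) -> dict:
    return {
        "channels": [[c.id, c.region] for c in net.channels],
        "base_model": {
            "coeffs": net.base_model.coeffs.tolist(),
            "noise_cov": net.base_model.noise_cov.tolist(),
            "sampling_rate": net.base_model.sampling_rate,
        },
        "couplings": [
            {
                "source": cp.source, "target": cp.target, "gain": cp.gain,
                "lag": cp.lag, "window": list(cp.window), "condition": cp.condition,
            }
            for cp in net.couplings
        ],
        "activations": [
            {
                "channel": ac.channel, "gain": ac.gain,
                "window": list(ac.window), "condition": ac.condition,
            }
            for ac in net.activations
        ],
        "noise_sd": None if net.noise_sd is None else net.noise_sd.tolist(),
    }


def _network_from_json(d: dict) -> NetworkSpec:
    bm = d["base_model"]
    model = MVARModel(
        np.asarray(bm["coeffs"]), np.asarray(bm["noise_cov"]), bm["sampling_rate"]
    )
    return NetworkSpec(
        channels=tuple(Channel(*c) for c in d["channels"]),
        base_model=model,
        couplings=tuple(
            CouplingEvent(
                cp["source"], cp["target"], cp["gain"], cp["lag"],
                tuple(cp["window"]), cp["condition"],
            )
            for cp in d["couplings"]
        ),
        activations=tuple(
            ActivationEvent(
                ac["channel"], ac["gain"], tuple(ac["window"]), ac["condition"]
            )
            for ac in d.get("activations", [])
        ),
        noise_sd=None if d.get("noise_sd") is None else np.asarray(d["noise_sd"]),
    )


def write_session(path: str | Path, sim: SimulatedSession) -> Path:
    """Write a simulated session to a session directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rec = sim.recording
    with h5py.File(path / "signals.h5", "w") as f:
        ds = f.create_dataset("signals", data=rec.signals)
        ds.attrs["sampling_rate_hz"] = rec.sampling_rate
        ds.attrs["channel_ids"] = [c.id for c in rec.channels]
        ds.attrs["channel_regions"] = [c.region for c in rec.channels]
    rec.events[_EVENT_COLUMNS].to_csv(path / "events.csv", index=False)
    (path / "truth.json").write_text(json.dumps(_network_to_json(sim.truth), indent=1))
    (path / "meta.json").write_text(
        json.dumps({"subject": sim.subject, "session": sim.session, "seed": sim.seed})
    )
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Load a session directory into a :class:`SessionRecording`."""
    path = Path(path)
    with h5py.File(path / "signals.h5", "r") as f:
        ds = f["signals"]
        signals = ds[()]
        fs = float(ds.attrs["sampling_rate_hz"])
        ids = [s if isinstance(s, str) else s.decode() for s in ds.attrs["channel_ids"]]
        regions = [
            s if isinstance(s, str) else s.decode() for s in ds.attrs["channel_regions"]
        ]
    events = pd.read_csv(path / "events.csv")
    channels = tuple(Channel(i, r) for i, r in zip(ids, regions))
    return SessionRecording(
        signals=signals, sampling_rate=fs, channels=channels, events=events
    )


def read_truth(path: str | Path) -> NetworkSpec | None:
    p = Path(path) / "truth.json"
    if not p.exists():
        return None
    return _network_from_json(json.loads(p.read_text()))


def read_trials(path: str | Path) -> list[TrialTiming]:
    events = pd.read_csv(Path(path) / "events.csv")
    return [
        TrialTiming(
            condition=row.condition,
            cue_onset_s=row.cue_onset_s,
            stimulus_onset_s=row.stimulus_onset_s,
            speech_onset_s=row.speech_onset_s,
            c1_dur_s=row.c1_dur_s,
            v_dur_s=row.v_dur_s,
            c2_dur_s=row.c2_dur_s,
        )
        for row in events.itertuples()
    ]


def save_flow_tensor(path: str | Path, ft) -> Path:
    """Serialize a FlowTensor to HDF5 with axis metadata and provenance."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("z", data=ft.z)
        f.create_dataset("freqs", data=ft.freqs)
        f.create_dataset("times", data=ft.times)
        ds.attrs["axes"] = ["target", "source", "freq", "time"]
        ds.attrs["channels"] = list(ft.channels)
        for key, val in ft.meta.items():
            ds.attrs[key] = val
    return path


def load_flow_tensor(path: str | Path):
    from .mvar import FlowTensor

    with h5py.File(path, "r") as f:
        ds = f["z"]
        channels = tuple(
            c if isinstance(c, str) else c.decode() for c in ds.attrs["channels"]
        )
        meta = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in ds.attrs.items()
            if k not in ("axes", "channels")
        }
        return FlowTensor(
            z=ds[()],
            freqs=f["freqs"][()],
            times=f["times"][()],
            channels=channels,
            meta=meta,
        )


def save_erc_result(path: str | Path, erc) -> Path:
    """Serialize an ERCResult (deltas, q-values, masks) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("delta", data=erc.delta)
        f.create_dataset("q", data=erc.q)
        f.create_dataset("mask", data=erc.mask)
        f.create_dataset("baseline_mean", data=erc.baseline_mean)
        f.create_dataset("freqs", data=erc.freqs)
        f.create_dataset("times", data=erc.times)
        f.create_dataset("pairs", data=np.asarray(erc.pairs))
        f.attrs["channels"] = list(erc.channels)
        f.attrs["regions"] = list(erc.regions)
        f.attrs["session_id"] = erc.session_id
    return path


def load_erc_result(path: str | Path):
    from .stats import ERCResult

    with h5py.File(path, "r") as f:
        def _dec(xs):
            return tuple(x if isinstance(x, str) else x.decode() for x in xs)

        return ERCResult(
            delta=f["delta"][()],
            q=f["q"][()],
            mask=f["mask"][()].astype(bool),
            baseline_mean=f["baseline_mean"][()],
            pairs=tuple(map(tuple, f["pairs"][()].tolist())),
            freqs=f["freqs"][()],
            times=f["times"][()],
            channels=_dec(f.attrs["channels"]),
            regions=_dec(f.attrs["regions"]),
            session_id=str(f.attrs["session_id"]),
        )
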