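"""Session directory format and validation.

A session directory holds one locomotor condition:

    config.yaml        session configuration echo
    events.csv         limb, event {contact, liftoff}, time_s, x_m
    stims.csv          time_s, nerve, limb
    emg.h5             dataset 'emg' (channels x samples), attrs rate_hz,
                       muscles, limbs
    ground_truth.json  hidden generator parameters (synthetic sessions only)

A study directory is a directory of sessions (one per condition) with a
manifest carrying the seed and a hash of the configuration, so re-running
with the same hash reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import LIMBS, MuscleSpec, NoiseSpec, SessionConfig, StimSpec
from .kinematics import GaitEventSeries
from .synthetic import (
    EmgRecording,
    ReflexGroundTruth,
    ResponseSpec,
    SessionBundle,
)


def config_hash(config: SessionConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_session(directory: str | Path, bundle: SessionBundle) -> Path:
    """Write a session bundle to ``directory`` (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    cfg = dataclasses.asdict(bundle.config)
    cfg["config_hash"] = config_hash(bundle.config)
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    rows = []
    for limb, ev in bundle.gait_events.items():
        for i, t in enumerate(ev.contact_times):
            rows.append((limb, "contact", t, ev.contact_x[i] if ev.contact_x is not None else np.nan))
        for i, t in enumerate(ev.liftoff_times):
            rows.append((limb, "liftoff", t, ev.liftoff_x[i] if ev.liftoff_x is not None else np.nan))
    events = pd.DataFrame(rows, columns=["limb", "event", "time_s", "x_m"])
    events.sort_values(["limb", "time_s"], inplace=True)
    events.to_csv(d / "events.csv", index=False)

    stims = pd.DataFrame(
        {
            "time_s": bundle.emg.stim_times,
            "nerve": bundle.emg.nerve,
            "limb": bundle.emg.stim_limb,
        }
    )
    stims.to_csv(d / "stims.csv", index=False)

    with h5py.File(d / "emg.h5", "w") as fh:
        ds = fh.create_dataset("emg", data=bundle.emg.data.astype(np.float64))
        ds.attrs["rate_hz"] = bundle.emg.rate
        ds.attrs["muscles"] = [m for m, _ in bundle.emg.channels]
        ds.attrs["limbs"] = [l for _, l in bundle.emg.channels]

    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        payload = {
            "responses": [dataclasses.asdict(r) for r in gt.responses],
            "phase_targets": gt.phase_targets,
            "gap_targets": gt.gap_targets,
            "reference_onsets": np.asarray(gt.reference_onsets).tolist(),
            "stim_bins": np.asarray(gt.stim_bins).tolist(),
            "truncated_stims": list(gt.truncated_stims),
        }
        with open(d / "ground_truth.json", "w") as fh:
            json.dump(payload, fh, indent=1)
    return d


def _events_from_frame(df: pd.DataFrame, limb: str, belt_speed: float) -> GaitEventSeries:
    sub = df[df.limb == limb].sort_values("time_s")
    contacts = sub[sub.event == "contact"]
    liftoffs = sub[sub.event == "liftoff"]
    if contacts.empty:
        raise ValueError(f"events.csv: no contact events for limb {limb}")
    try:
        return GaitEventSeries(
            limb=limb,
            contact_times=contacts.time_s.to_numpy(),
            liftoff_times=liftoffs.time_s.to_numpy(),
            contact_x=contacts.x_m.to_numpy(),
            liftoff_x=liftoffs.x_m.to_numpy(),
            belt_speed=belt_speed,
        )
    except ValueError as err:
        raise ValueError(f"events.csv: {err}") from err


def read_session(directory: str | Path) -> SessionBundle:
    """Read and validate a session directory; schema violations raise
    descriptive errors naming the file."""
    d = Path(directory)
    for name in ("config.yaml", "events.csv", "stims.csv", "emg.h5"):
        if not (d / name).exists():
            raise FileNotFoundError(f"session {d}: missing {name}")

    with open(d / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw.pop("config_hash", None)
    raw["muscles"] = tuple(MuscleSpec(**{**m, "window": tuple(m["window"])}) for m in raw["muscles"])
    raw["stim"] = StimSpec(**{**raw["stim"], "gap_cycles": tuple(raw["stim"]["gap_cycles"])})
    raw["noise"] = NoiseSpec(**raw["noise"])
    for key in ("cycle_duration_model", "stance_fraction_model"):
        raw[key] = tuple(raw[key])
    for key in ("phase_targets", "gap_targets"):
        raw[key] = {k: tuple(v) for k, v in raw[key].items()}
    config = SessionConfig(**raw)

    events = pd.read_csv(d / "events.csv", float_precision="round_trip")
    gait = {
        limb: _events_from_frame(events, limb, config.belt_speed(limb)) for limb in LIMBS
    }

    stims = pd.read_csv(d / "stims.csv", float_precision="round_trip")
    with h5py.File(d / "emg.h5", "r") as fh:
        if "emg" not in fh:
            raise ValueError(f"{d / 'emg.h5'}: missing dataset 'emg'")
        ds = fh["emg"]
        data = ds[()].astype(float)
        rate = float(ds.attrs["rate_hz"])
        muscles = [str(m) for m in ds.attrs["muscles"]]
        limbs = [str(l) for l in ds.attrs["limbs"]]
    if rate < 1000.0:
        raise ValueError(f"{d / 'emg.h5'}: rate {rate} Hz < 1000 Hz")
    if len(muscles) != data.shape[0]:
        raise ValueError(
            f"{d / 'emg.h5'}: {data.shape[0]} channels but {len(muscles)} muscle labels"
        )
    if not np.all(np.isfinite(data)):
        bad = int(np.argmax(~np.all(np.isfinite(data), axis=1)))
        raise ValueError(f"{d / 'emg.h5'}: non-finite samples in channel {muscles[bad]}")

    emg = EmgRecording(
        data=data,
        rate=rate,
        channels=tuple(zip(muscles, limbs)),
        stim_times=stims.time_s.to_numpy(dtype=float),
        nerve=str(stims.nerve.iloc[0]) if len(stims) else config.stim.nerve,
        stim_limb=str(stims.limb.iloc[0]) if len(stims) else config.stim.limb,
    )

    truth = None
    gt_path = d / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            payload = json.load(fh)
        truth = ReflexGroundTruth(
            responses=tuple(
                ResponseSpec(**{**r, "profile": tuple(r["profile"])})
                for r in payload["responses"]
            ),
            phase_targets={k: tuple(v) for k, v in payload["phase_targets"].items()},
            gap_targets={k: tuple(v) for k, v in payload["gap_targets"].items()},
            reference_onsets=np.asarray(payload["reference_onsets"]),
            stim_bins=np.asarray(payload["stim_bins"], dtype=int),
            truncated_stims=tuple(payload["truncated_stims"]),
        )

    bundle = SessionBundle(config=config, gait_events=gait, emg=emg, ground_truth=truth)
    bundle.validate()
    return bundle
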