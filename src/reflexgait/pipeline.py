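"""End-to-end orchestration: session -> kinematics, coordination, reflex
tables; study (four conditions) -> cross-condition normalization,
modulation indexes, circular condition comparisons, manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    AnalysisConfig,
    CONDITIONS,
    COUPLINGS,
    GAP_COUPLINGS,
)
from .coordination import coupling_angles, coupling_summary, symmetry_index
from .kinematics import cycles_table
from .reflex import (
    ReflexAnalysis,
    analyze_session_reflexes,
    modulation_index,
    normalize_responses,
    phase_profiles,
)
from .session_io import config_hash
from .synthetic import SessionBundle


def reference_onsets(bundle: SessionBundle, cfg: AnalysisConfig) -> np.ndarray:
    """Cycle onsets for the reflex analysis: contact events of the
    reference limb (the limb carrying the configured reference muscle)."""
    return bundle.gait_events[cfg.reference_limb].contact_times


def run_pipeline(bundle: SessionBundle, cfg: AnalysisConfig | None = None) -> dict:
    """Analyze one session.  Reflex stages are skipped (with a note in the
    manifest) when the session carries no stimuli; kinematics and
    coordination are always computed."""
    cfg = cfg or AnalysisConfig()
    condition = bundle.config.condition
    report: dict = {"condition": condition}

    try:
        kin = cycles_table(bundle.gait_events, bundle.emg.stim_times)
    except Exception as err:
        raise RuntimeError(f"kinematics stage failed: {err}") from err
    report["kinematics"] = kin

    try:
        rows = []
        angles = {}
        for pair in COUPLINGS:
            a = coupling_angles(bundle.gait_events, pair, "phase")
            angles[(pair, "phase")] = a
            rows += [
                {"pair": pair, "kind": "phase", "cycle": i, "angle_deg": v}
                for i, v in enumerate(a)
            ]
        for pair in GAP_COUPLINGS:
            a = coupling_angles(bundle.gait_events, pair, "gap")
            angles[(pair, "gap")] = a
            rows += [
                {"pair": pair, "kind": "gap", "cycle": i, "angle_deg": v}
                for i, v in enumerate(a)
            ]
        coord = pd.DataFrame(rows)
        coord["symmetry_index_pct"] = [
            symmetry_index(v) if r["pair"] in GAP_COUPLINGS else np.nan
            for r, v in zip(rows, coord.angle_deg)
        ]
    except Exception as err:
        raise RuntimeError(f"coordination stage failed: {err}") from err
    report["coordination"] = coord
    report["coupling_angles"] = angles

    if bundle.emg.stim_times.size == 0:
        report["reflex"] = None
        report["profiles"] = pd.DataFrame()
        report["notes"] = ["no stimuli: reflex stages skipped"]
    else:
        try:
            analysis = analyze_session_reflexes(
                bundle.emg, reference_onsets(bundle, cfg), cfg, condition
            )
        except Exception as err:
            raise RuntimeError(f"reflex stage failed: {err}") from err
        report["reflex"] = analysis
        report["profiles"] = phase_profiles(analysis, cfg)
        report["notes"] = []

    report["manifest"] = {
        "package_version": __version__,
        "condition": condition,
        "seed": bundle.config.seed,
        "config_hash": config_hash(bundle.config),
        "n_stimuli": int(bundle.emg.stim_times.size),
    }
    return report


def run_study(
    bundles: dict[str, SessionBundle], cfg: AnalysisConfig | None = None
) -> dict:
    """Analyze a study (one session per condition) and assemble the
    cross-condition quantities: per-muscle normalized reflex profiles,
    modulation indexes, and circular condition comparisons."""
    cfg = cfg or AnalysisConfig()
    sessions = {cond: run_pipeline(b, cfg) for cond, b in bundles.items()}

    profiles = pd.concat(
        [r["profiles"] for r in sessions.values() if len(r["profiles"])],
        ignore_index=True,
    ) if any(len(r["profiles"]) for r in sessions.values()) else pd.DataFrame()

    norm_rows, index_rows = [], []
    if len(profiles):
        for (muscle, limb, family), sub in profiles.groupby(["muscle", "limb", "family"]):
            normed = sub.copy()
            normed["normalized_pct"] = normalize_responses(
                sub.net_value.to_numpy(), cfg.normalization
            )
            norm_rows.append(normed)
            for cond, csub in normed.groupby("condition"):
                index_rows.append(
                    {
                        "muscle": muscle,
                        "limb": limb,
                        "relation": csub.relation.iloc[0],
                        "family": family,
                        "condition": cond,
                        "modulation_index_pct": modulation_index(
                            csub.normalized_pct.to_numpy()
                        ),
                    }
                )
    normalized = (
        pd.concat(norm_rows, ignore_index=True) if norm_rows else pd.DataFrame()
    )
    indexes = pd.DataFrame(index_rows)

    coordination = {}
    for pair in COUPLINGS:
        by_cond = {
            cond: r["coupling_angles"][(pair, "phase")] for cond, r in sessions.items()
        }
        coordination[f"{pair}_phase"] = coupling_summary(by_cond)
    for pair in GAP_COUPLINGS:
        by_cond = {
            cond: r["coupling_angles"][(pair, "gap")] for cond, r in sessions.items()
        }
        coordination[f"{pair}_gap"] = coupling_summary(by_cond)

    return {
        "sessions": sessions,
        "profiles": profiles,
        "normalized": normalized,
        "modulation_indexes": indexes,
        "coordination": coordination,
        "manifest": {
            "package_version": __version__,
            "conditions": list(bundles),
            "session_manifests": {c: r["manifest"] for c, r in sessions.items()},
        },
    }


def write_report(outdir: str | Path, study: dict) -> Path:
    """Write study tables (CSV) and summaries (JSON) under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, rep in study["sessions"].items():
        rep["kinematics"].to_csv(out / f"kinematics_{cond}.csv", index=False)
        rep["coordination"].to_csv(out / f"coordination_{cond}.csv", index=False)
        analysis = rep["reflex"]
        if isinstance(analysis, ReflexAnalysis) and len(analysis.responses):
            analysis.responses.to_csv(out / f"responses_{cond}.csv", index=False)
    if len(study["normalized"]):
        study["normalized"].to_csv(out / "normalized_responses.csv", index=False)
    if len(study["modulation_indexes"]):
        study["modulation_indexes"].to_csv(out / "modulation_indexes.csv", index=False)
    with open(out / "coordination_summary.json", "w") as fh:
        json.dump(study["coordination"], fh, indent=1, default=float)
    with open(out / "manifest.json", "w") as fh:
        json.dump(study["manifest"], fh, indent=1, default=str)
    return out
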