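"""Report figures: 10-phase reflex panels with the blEMG overlay, polar
coupling plots, and modulation-index bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def phase_panel(analysis, muscle: str, limb: str, path: Path) -> None:
    """One column of 10 phase bins: stimulated average (black) over the
    phase-matched control band (gray), per bin."""
    fig, axes = plt.subplots(10, 1, figsize=(4, 12), sharex=True)
    for b, ax in enumerate(axes):
        tr = analysis.traces.get((muscle, limb, b))
        ax.set_ylabel(f"bin {b}", fontsize=7)
        if tr is None:
            ax.set_yticks([])
            continue
        ax.fill_between(
            tr.time_ms,
            tr.ctrl_mean - tr.halfwidth,
            tr.ctrl_mean + tr.halfwidth,
            color="0.8",
        )
        ax.plot(tr.time_ms, tr.ctrl_mean, color="0.5", lw=0.8)
        ax.plot(tr.time_ms, tr.stim_mean, color="k", lw=0.8)
    axes[-1].set_xlabel("time after stimulus (ms)")
    fig.suptitle(f"{muscle}/{limb} ({analysis.condition})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def polar_coupling(summary: dict, title: str, path: Path) -> None:
    """Mean direction and r per condition on a polar axis."""
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    for cond, s in summary["conditions"].items():
        if np.isfinite(s["mean_direction_deg"]):
            th = np.deg2rad(s["mean_direction_deg"])
            ax.plot([th, th], [0, s["r"]], label=cond)
    ax.set_rmax(1.0)
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=6, loc="lower left", bbox_to_anchor=(1.0, 0.0))
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def index_bars(indexes, path: Path) -> None:
    """Modulation index per condition, grouped by muscle/family."""
    if not len(indexes):
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = indexes.apply(lambda r: f"{r.muscle}/{r.limb} {r.family}", axis=1)
    x = np.arange(len(indexes))
    ax.bar(x, indexes.modulation_index_pct, tick_label=labels + " " + indexes.condition)
    ax.set_ylabel("modulation index (%)")
    ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def study_figures(study: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, summary in study["coordination"].items():
        polar_coupling(summary, name, outdir / f"coupling_{name}.png")
    index_bars(study["modulation_indexes"], outdir / "modulation_indexes.png")
    for cond, rep in study["sessions"].items():
        analysis = rep["reflex"]
        if analysis is None:
            continue
        for muscle, limb in analysis.blemg:
            if any(k[:2] == (muscle, limb) for k in analysis.traces):
                phase_panel(
                    analysis, muscle, limb, outdir / f"phases_{cond}_{limb}_{muscle}.png"
                )
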