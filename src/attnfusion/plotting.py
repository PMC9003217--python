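"""Matplotlib hooks for the window-size sweep and attention-behavior curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fusion import SessionReport


def plot_ws_table(table: list[dict], path: str | Path) -> None:
    """Attention gains of both sources against candidate window sizes."""
    ws = [row["ws"] for row in table]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ws, [row["ag_fe"] for row in table], "o-", label="facial AG")
    ax.plot(ws, [row["ag_p"] for row in table], "s-", label="physio AG")
    ax.set_xlabel("window size (samples)")
    ax.set_ylabel("attention gain (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_attention_behavior(report: SessionReport, path: str | Path) -> None:
    """Per-source attention-behavior curves over the session."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for ab, name in ((report.ab_facial, "facial"), (report.ab_physio, "physio")):
        if ab:
            ax.plot(ab["t_s"], ab["values"], label=f"{name} AB")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("attention behavior")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
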