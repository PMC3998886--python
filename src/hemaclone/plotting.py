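"""Figure-style panels for trajectories and sweep grids (matplotlib)."""
from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .competition import OutcomeGrid
from .observables import trajectory_summary
from .simulate import Trajectory

__all__ = ["plot_trajectory_panels", "plot_sweep_heatmap"]

_OUTCOME_LEVEL = {"no_takeover": 0, "marginal": 1, "takeover": 2, "error": np.nan}


def plot_trajectory_panels(traj: Trajectory, out_dir: str, prefix: str = "trajectory"):
    """Write the standard disease-course panels as PNG files.

    Panels: compartment counts (log scale), normal mature decline, marrow
    composition stack, feedback signals, apoptotic percentage.  Returns the
    list of files written.
    """
    os.makedirs(out_dir, exist_ok=True)
    frame = trajectory_summary(traj)
    years = traj.times_years
    written = []

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for lin, name in traj.params.labels():
        series = traj.series(lin, name)
        style = "-" if lin == "normal" else "--"
        ax.semilogy(years, np.where(series > 0, series, np.nan), style,
                    label=f"{lin}:{name}")
    ax.set(xlabel="time (years)", ylabel="cells", title="Compartment counts")
    ax.legend(fontsize=6, ncol=2)
    path = os.path.join(out_dir, f"{prefix}_counts.png")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(2, 2, figsize=(9, 6.5))
    normal = traj.params.lineage("normal")
    mature = traj.series("normal", normal.compartments[-1].name)
    axes[0, 0].plot(years, mature / mature[0] if mature[0] > 0 else mature)
    axes[0, 0].set(xlabel="years", ylabel="fraction of baseline",
                   title="Normal mature cells (PB)")
    t_m = traj.events.get("manifestation_years")
    if t_m is not None:
        axes[0, 0].axvline(t_m, color="r", ls=":", label=f"manifestation {t_m:.1f} y")
        axes[0, 0].legend(fontsize=8)

    bm_cols = [c for c in frame.columns if c.startswith("bm_pct:")]
    axes[0, 1].stackplot(years, [frame[c] for c in bm_cols],
                         labels=[c.split(":", 1)[1] for c in bm_cols])
    axes[0, 1].set(xlabel="years", ylabel="% of bone marrow",
                   title="Marrow composition")
    axes[0, 1].legend(fontsize=5, loc="center left")

    axes[1, 0].plot(years, traj.s_a, label="self-renewal signal $s_a$")
    axes[1, 0].plot(years, traj.s_p, label="proliferation signal $s_p$")
    axes[1, 0].set(xlabel="years", ylabel="signal intensity", ylim=(0, 1.05),
                   title="Feedback signals")
    axes[1, 0].legend(fontsize=8)

    axes[1, 1].plot(years, frame["apoptotic_pct"])
    axes[1, 1].set(xlabel="years", ylabel="% apoptotic in BM",
                   title="Apoptotic cells")
    fig.tight_layout()
    path = os.path.join(out_dir, f"{prefix}_panels.png")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written


def plot_sweep_heatmap(grid: OutcomeGrid, path: str):
    """Outcome heatmap over (a_max,MDS x p-scale)."""
    frame = grid.frame
    a_vals = sorted(frame.a_max_mds.unique())
    p_vals = sorted(frame.p_scale.unique())
    z = np.full((len(p_vals), len(a_vals)), np.nan)
    for _, row in frame.iterrows():
        i = p_vals.index(row.p_scale)
        j = a_vals.index(row.a_max_mds)
        z[i, j] = _OUTCOME_LEVEL.get(row.label, np.nan)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(z, origin="lower", aspect="auto", cmap="RdYlBu_r",
                   vmin=0, vmax=2)
    ax.set_xticks(range(len(a_vals)), [f"{a:g}" for a in a_vals])
    ax.set_yticks(range(len(p_vals)), [f"{p:g}" for p in p_vals])
    ax.set(xlabel="MDS stem maximal self-renewal $a_{max}$",
           ylabel="MDS proliferation scaling",
           title="Competition outcome")
    cbar = fig.colorbar(im, ticks=[0, 1, 2])
    cbar.ax.set_yticklabels(["no takeover", "marginal", "takeover"])
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
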