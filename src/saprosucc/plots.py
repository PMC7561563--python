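"""Figure helpers: trajectory panels, ordination triplot, Venn diagram.

Every figure is drawn from tabular outputs the pipeline also writes to
disk, so no number exists only inside an image.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_ENV_STYLE = {
    "exposed": dict(color="white", edgecolor="black"),
    "shaded": dict(color="0.6", edgecolor="black"),
}


def plot_trajectory(fit, path, title: str = "") -> None:
    """Predicted cell means with 95% CIs over observed per-trap values."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    times = fit.design.factors["time"]
    xpos = {t: i for i, t in enumerate(times)}
    for env, off in (("exposed", -0.12), ("shaded", 0.12)):
        obs = fit.data[fit.data["environment"] == env]
        ax.scatter(
            obs["time"].map(xpos) + off + np.random.default_rng(0).uniform(
                -0.04, 0.04, len(obs)
            ),
            obs["y"], s=6, alpha=0.35, zorder=1,
            facecolor=_ENV_STYLE[env]["color"], edgecolor="gray", linewidth=0.3,
        )
        pred = fit.predictions[fit.predictions["environment"] == env]
        x = pred["time"].map(xpos) + off
        ax.errorbar(
            x, pred["predicted"],
            yerr=[pred["predicted"] - pred["ci_lo"],
                  pred["ci_hi"] - pred["predicted"]],
            fmt="o", ms=8, capsize=3, zorder=3,
            markerfacecolor=_ENV_STYLE[env]["color"], color="black",
            label=env,
        )
    ax.set_xticks(range(len(times)), [str(t) for t in times])
    ax.set_xlabel("time")
    ax.set_ylabel(fit.spec.response)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_triplot(scores: pd.DataFrame, path, label_threshold: float = 0.2) -> None:
    """Two-panel triplot: site + centroid scores, and species scores."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2))
    sites = scores[scores["type"] == "site"]
    cents = scores[scores["type"] == "centroid"]
    spp = scores[scores["type"] == "species"]
    axes[0].scatter(sites["axis1"], sites["axis2"], s=8, alpha=0.4, c="0.5")
    axes[0].scatter(cents["axis1"], cents["axis2"], marker="s", c="black", s=25)
    for _, row in cents.iterrows():
        axes[0].annotate(row["entity"], (row["axis1"], row["axis2"]),
                         fontsize=6, xytext=(2, 2), textcoords="offset points")
    axes[0].set_title("sites and centroids")
    axes[1].scatter(spp["axis1"], spp["axis2"], s=8, alpha=0.5, c="0.4")
    for _, row in spp[spp["flagged"]].iterrows():
        axes[1].annotate(row["entity"], (row["axis1"], row["axis2"]),
                         fontsize=6, xytext=(2, 2), textcoords="offset points")
    axes[1].set_title(f"species (|score| > {label_threshold} labelled)")
    for ax in axes:
        ax.axhline(0, lw=0.5, c="0.8")
        ax.axvline(0, lw=0.5, c="0.8")
        ax.set_xlabel("RDA axis 1")
        ax.set_ylabel("RDA axis 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_venn(result, path) -> None:
    """Three-circle Venn of unique/shared adjusted-R^2 fractions.

    Negative fractions are truncated at zero for display only.
    """
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    centers = {"E": (-0.5, 0.3), "Y": (0.5, 0.3), "F": (0.0, -0.55)}
    for k, (x, y) in centers.items():
        ax.add_patch(plt.Circle((x, y), 0.85, fill=False, lw=1.2))
        ax.text(x * 1.9, y * 1.9, k, fontsize=12, ha="center")
    pct = result.as_percent()
    shown = {
        (-0.85, 0.45): pct["unique_E"],
        (0.85, 0.45): pct["unique_Y"],
        (0.0, -0.95): pct["unique_F"],
        (0.0, 0.55): pct["shared_EY"],
        (-0.55, -0.25): pct["shared_EF"],
        (0.55, -0.25): pct["shared_YF"],
        (0.0, 0.0): pct["shared_EYF"],
    }
    for (x, y), v in shown.items():
        ax.text(x, y, f"{max(v, 0)}%", ha="center", fontsize=9)
    ax.text(0, -1.85, f"residual {pct['residual']}%", ha="center", fontsize=9)
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2.1, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
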