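"""Plot helpers for cervical stress profiles and wear trends."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def plot_cervical_profiles(results_list, path: str | Path | None = None, ax=None):
    """sigma1 vs buccal-cervix arc position, one line per wear state."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for res in results_list:
        ax.plot(
            res.cervical.arc_positions,
            res.cervical.sigma1,
            marker="o",
            label=f"wear {res.params.wear_depth:.2f} mm (stage {res.stage.stage})",
        )
    ax.set_xlabel("arc position along buccal cervix (mesial -> distal)")
    ax.set_ylabel(r"$\sigma_1$ (MPa)")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.legend(fontsize=8)
    ax.set_title("Buccal cervical tensile stress by wear state")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_wear_trends(trends, path: str | Path | None = None):
    """Contact area, load obliquity and cervical sigma1 vs wear depth."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    x = trends["wear_depth_mm"]
    axes[0].plot(x, trends["contact_area_mm2"], "o-")
    axes[0].set_ylabel("total contact area (mm$^2$)")
    axes[1].plot(x, trends["load_obliquity_deg"], "o-")
    axes[1].set_ylabel("load obliquity (deg)")
    axes[2].plot(x, trends["mean_cervical_sigma1_mpa"], "o-")
    axes[2].set_ylabel(r"mean cervical $\sigma_1$ (MPa)")
    for ax in axes:
        ax.set_xlabel("wear depth (mm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
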