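"""Optional matplotlib figures for the evaluation outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_threshold_tradeoff(sweep: pd.DataFrame, path) -> None:
    """Threshold trade-off: 1 - macro F1 (left axis) vs mean delay (right)."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(sweep["threshold"], sweep["one_minus_macro_f1"], "o-", color="tab:blue")
    ax1.set_xlabel("squared Mahalanobis distance threshold")
    ax1.set_ylabel("1 - macro F1", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(sweep["threshold"], sweep["mean_delay"], "s--", color="tab:red")
    ax2.set_ylabel("mean time delay (s)", color="tab:red")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_convergence(curve: pd.DataFrame, path, dof: int = 4) -> None:
    """Mean squared distance vs training duration, with the chi2 mean line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["duration"], curve["mean_squared_md"], "o-")
    ax.axhline(dof, color="red", linestyle="--", label=f"chi-squared mean ({dof})")
    ax.set_xlabel("training data used (s)")
    ax.set_ylabel("mean filtered squared MD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_md_vs_speed(table: pd.DataFrame, fits: dict, path) -> None:
    """Mean squared distance vs speed offset with per-side linear fits."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["speed_offset"], table["mean_squared_md"], "ko")
    for name, style in (("negative", "b--"), ("positive", "r--")):
        fit = fits.get(name)
        if fit:
            dv = table["speed_offset"]
            mask = dv <= 0 if name == "negative" else dv >= 0
            xs = dv[mask]
            ax.plot(xs, fit["slope"] * xs + fit["intercept"], style,
                    label=f"{name}: R2={fit['r2']:.3f}")
    ax.set_xlabel("speed offset from baseline (m/s)")
    ax.set_ylabel("mean filtered squared MD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
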