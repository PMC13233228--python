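"""Bland-Altman and correlation plots for cohort reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import AgreementStats

__all__ = ["plot_agreement"]


def plot_agreement(
    x_native, y_generic, stats: AgreementStats, label: str, out_path
) -> Path:
    """Side-by-side correlation and Bland-Altman plot for one parameter."""
    x = np.asarray(x_native, dtype=float)
    y = np.asarray(y_generic, dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.2))

    ax1.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax1.plot(lims, lims, "k:", lw=0.8, label="identity")
    xs = np.linspace(*lims, 2)
    ax1.plot(xs, stats.slope * xs + stats.intercept, "k-", lw=1.2, label="fit")
    ax1.set_xlabel(f"native {label}")
    ax1.set_ylabel(f"generic {label}")
    ax1.set_title(f"PCC {stats.pcc:.3f}, NRMSE {100 * stats.nrmse:.2f}%")
    ax1.legend(frameon=False, fontsize=8)

    mean = 0.5 * (x + y)
    diff = y - x
    ax2.scatter(mean, diff, s=12, alpha=0.6, edgecolors="none")
    ax2.axhline(stats.bias, color="k", lw=1.2)
    ax2.axhspan(*stats.ci95_bias, color="k", alpha=0.15, lw=0)
    for v in stats.loa:
        ax2.axhline(v, color="k", ls="--", lw=0.9)
    ax2.set_xlabel(f"mean of methods ({label})")
    ax2.set_ylabel(f"generic - native ({label})")
    ax2.set_title(f"bias {stats.bias:.3g}, LOA [{stats.loa[0]:.3g}, {stats.loa[1]:.3g}]")

    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
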