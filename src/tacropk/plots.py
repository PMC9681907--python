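"""Optional plotting helpers (goodness-of-fit panels and VPC ribbons).

Thin matplotlib layers over the diagnostic summaries; everything they
draw is available as numbers from the corresponding diagnostics objects.
"""

from __future__ import annotations

import numpy as np

from .datamodel import FlatData
from .diagnostics import VpcSummary
from .estimation import FitResult
from .models import predict, residual_variance


def gof_panels(fit: FitResult, data: FlatData, path: str) -> None:
    """Four-panel goodness-of-fit figure: OBS vs PRED, OBS vs IPRED,
    CWRES-style weighted residuals vs PRED and vs postoperative day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = fit.spec
    y = data.col(spec.dv_column)
    pred = predict(spec, data, np.zeros((data.n_subjects, spec.n_eta)) if spec.n_eta else None)
    ipred = predict(spec, data, fit.eta_modes if spec.n_eta else None)
    wres = (y - ipred) / np.sqrt(residual_variance(ipred, spec.residual))
    pod = data.col("pod")

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x, yy, labels in (
        (axes[0, 0], pred, y, ("population prediction", "observation")),
        (axes[0, 1], ipred, y, ("individual prediction", "observation")),
    ):
        ax.plot(x, yy, ".", ms=3, alpha=0.5)
        lim = [0, max(np.max(x), np.max(yy)) * 1.05]
        ax.plot(lim, lim, "k-", lw=0.8)
        ax.set_xlabel(labels[0])
        ax.set_ylabel(labels[1])
    for ax, x, xlabel in (
        (axes[1, 0], pred, "population prediction"),
        (axes[1, 1], pod, "postoperative day"),
    ):
        ax.plot(x, wres, ".", ms=3, alpha=0.5)
        ax.axhline(0, color="k", lw=0.8)
        for ref in (-1.96, 1.96):
            ax.axhline(ref, color="k", lw=0.8, ls="--")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("weighted residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(vpc: VpcSummary, path: str, ylabel: str = "corrected observation") -> None:
    """Percentile ribbons of a prediction/variability-corrected VPC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = ("tab:blue", "tab:red", "tab:blue")
    for j, pct in enumerate(vpc.percentiles):
        ax.fill_between(
            vpc.bin_mid, vpc.sim_ci[:, j, 0], vpc.sim_ci[:, j, 1],
            color=colors[j], alpha=0.25, lw=0,
        )
        style = "-" if pct == 50 else "--"
        ax.plot(vpc.bin_mid, vpc.obs_percentiles[:, j], style, color="k", lw=1.2,
                label=f"observed {pct:g}th")
    ax.set_xlabel("postoperative day")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
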