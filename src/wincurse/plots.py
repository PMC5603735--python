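"""Plotting helpers for simulation-study reports."""

from __future__ import annotations

import numpy as np

from .evaluate import EvaluationReport

__all__ = ["plot_naive_vs_adjusted", "plot_bias_vs_power"]


def plot_naive_vs_adjusted(report: EvaluationReport, path=None):
    """Histogram panels of naive vs. adjusted statistics per variant.

    One panel per variant, overlaying the naive (red) and adjusted
    (blue) distributions over Step-1-significant replicates, with the
    expected value as a dashed line.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.naive_matrix is None or report.naive_matrix.size == 0:
        raise ValueError("report holds no significant replicates to plot")
    m = report.naive_matrix.shape[1]
    ncol = min(5, m)
    nrow = int(np.ceil(m / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    expected = report.truth.expected(report.statistic_family)
    for j in range(m):
        ax = axes[j // ncol][j % ncol]
        ax.hist(report.naive_matrix[:, j], bins=30, alpha=0.5, color="lightcoral", label="naive")
        if report.adjusted_available:
            ax.hist(
                report.adjusted_matrix[:, j], bins=30, alpha=0.5, color="steelblue", label="adjusted"
            )
        ax.axvline(expected[j], color="black", linestyle="--", linewidth=1)
        ax.set_title(f"SNP {j + 1}", fontsize=9)
        ax.tick_params(labelsize=7)
    axes[0][0].legend(fontsize=7)
    fig.suptitle(
        f"{report.setting_id}: {report.statistic_family} after {report.test_family}, "
        f"alpha={report.alpha:g}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_bias_vs_power(reports, path=None):
    """Funnel plot: per-variant |bias| against Step-1 power, naive vs.
    adjusted, across a collection of study reports."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for rep in reports:
        if rep.n_significant_replicates == 0:
            continue
        pv = rep.per_variant
        maf = rep.truth.setting.maf
        axes[0].scatter(
            np.full(len(pv), rep.step1_power), pv["bias_naive"].abs(), c=np.log10(maf), s=12
        )
        if rep.adjusted_available:
            axes[1].scatter(
                np.full(len(pv), rep.step1_power), pv["bias_adjusted"].abs(), c=np.log10(maf), s=12
            )
    axes[0].set_title("naive")
    axes[1].set_title("adjusted")
    for ax in axes:
        ax.set_xlabel("Step 1 power")
    axes[0].set_ylabel("|bias|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
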