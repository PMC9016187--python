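"""Optional rendering of the standard MR diagnostic figures.

All plots are written straight to file (SVG/PNG by extension) using the
non-interactive matplotlib backend; nothing here is required by the
analysis itself.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def forest_plot(forest: pd.DataFrame, results: pd.DataFrame, path) -> None:
    """Per-SNP Wald ratios with CIs, plus the combined estimates below."""
    n = len(forest)
    fig, ax = plt.subplots(figsize=(6, 0.28 * (n + len(results)) + 1.5))
    y = range(n)
    ax.errorbar(forest["theta"], y,
                xerr=[forest["theta"] - forest["ci_low"],
                      forest["ci_high"] - forest["theta"]],
                fmt="o", ms=3, color="0.3", ecolor="0.6", capsize=2)
    ax.set_yticks(list(y), forest["SNP"], fontsize=7)
    for k, row in results.reset_index(drop=True).iterrows():
        yy = n + 1 + k
        ax.plot(row["beta"], yy, "D", color="firebrick", ms=4)
        ax.text(ax.get_xlim()[1], yy, f' {row["method"]}', fontsize=7,
                va="center")
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("per-SNP causal estimate (log-odds)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def funnel_plot(funnel: pd.DataFrame, ivw_beta: float, path) -> None:
    """Instrument precision against causal estimate; asymmetry suggests
    directional pleiotropy."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(funnel["theta"], funnel["precision"], "o", ms=4, color="0.3")
    ax.axvline(ivw_beta, color="firebrick", lw=1,
               label="IVW estimate")
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def loo_plot(loo: pd.DataFrame, full, path) -> None:
    """Leave-one-out IVW estimates against the full-set estimate."""
    n = len(loo)
    fig, ax = plt.subplots(figsize=(6, 0.28 * n + 1.5))
    y = range(n)
    ax.errorbar(loo["beta"], y,
                xerr=[loo["beta"] - loo["ci_low"],
                      loo["ci_high"] - loo["beta"]],
                fmt="o", ms=3, color="0.3", ecolor="0.6", capsize=2)
    ax.set_yticks(list(y), loo["SNP"], fontsize=7)
    ax.axvline(full.beta, color="firebrick", lw=1, label="all SNPs")
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("IVW estimate excluding the labelled SNP")
    ax.invert_yaxis()
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
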