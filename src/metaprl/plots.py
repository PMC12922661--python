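"""Figure helpers for the analysis bundle (moderation curves, probability
contrast bars, recovery scatter, belief-behavior mapping curves)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import MappingResult, RecoveryReport
from .inference import ContrastResult, GLMFit, predicted_wsr

__all__ = [
    "plot_moderation_curves",
    "plot_contrast_bars",
    "plot_recovery_scatter",
    "plot_mapping_curves",
]


def plot_moderation_curves(fit: GLMFit, path) -> None:
    """Predicted WSR across z(μ₃⁰) at low (−1 SD) and high (+1 SD) M̄."""
    grid = np.linspace(-2, 2, 81)
    fig, ax = plt.subplots(figsize=(5, 4))
    for mp_z, label, color in ((-1.0, "low MP (−1 SD)", "tab:orange"), (1.0, "high MP (+1 SD)", "tab:blue")):
        ax.plot(grid, [predicted_wsr(fit, g, mp_z) for g in grid], label=label, color=color)
    ax.set_xlabel("z(μ₃⁰)")
    ax.set_ylabel("predicted win-switch rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_contrast_bars(contrast: ContrastResult, path) -> None:
    """pp change in predicted WSR for μ₃⁰ −1→+1 SD, at low vs high MP."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(["low MP", "high MP"], [contrast.pp_low, contrast.pp_high], color=["tab:orange", "tab:blue"])
    ax.set_ylabel("Δ predicted WSR (percentage points)")
    ax.set_title(f"Δ = {contrast.delta:+.1f} pp  [95% CI {contrast.ci_low:+.1f}, {contrast.ci_high:+.1f}]")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_recovery_scatter(report: RecoveryReport, param: str, path) -> None:
    ok = report.table[report.table["converged"]]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ok[f"true_{param}"], ok[f"recovered_{param}"], s=12, alpha=0.6)
    lims = [
        min(ok[f"true_{param}"].min(), ok[f"recovered_{param}"].min()),
        max(ok[f"true_{param}"].max(), ok[f"recovered_{param}"].max()),
    ]
    ax.plot(lims, lims, "k--", lw=0.8)
    r, p = report.correlations.get(param, (float("nan"), float("nan")))
    ax.set_xlabel(f"true {param}")
    ax.set_ylabel(f"recovered {param}")
    ax.set_title(f"r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mapping_curves(result: MappingResult, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result.grid, result.population_curve, "k-", label="all participants")
    ax.plot(result.grid, result.low_curve, color="tab:orange", label=f"low MP (n={result.n_low})")
    ax.plot(result.grid, result.high_curve, color="tab:blue", label=f"high MP (n={result.n_high})")
    ax.set_xlabel("μ₃⁰")
    ax.set_ylabel("expected win-switch rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
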