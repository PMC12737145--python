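"""Report figures: predictions vs index, prediction scatter, error
histograms, PSO convergence, and explanation bar charts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bench import BenchResult

__all__ = ["plot_benchmark", "plot_convergence", "plot_explanation"]


def plot_benchmark(result: BenchResult, out_dir: str | Path) -> list[Path]:
    """Prediction-vs-index, y=x scatter and error histogram per model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    y = result.y_test
    paths = []
    rows = [r for r in result.rows if not r.failed]

    fig, axes = plt.subplots(len(rows), 3, figsize=(13, 3 * len(rows)), squeeze=False)
    for ax_row, r in zip(axes, rows):
        pred = r.predictions
        ax_row[0].plot(y, label="actual", lw=1)
        ax_row[0].plot(pred, label="predicted", lw=1)
        ax_row[0].set_title(f"{r.name}: actual vs predicted")
        ax_row[0].set_xlabel("test sample")
        ax_row[0].set_ylabel("IR (mGy)")
        ax_row[0].legend(fontsize=8)
        ax_row[1].scatter(y, pred, s=8, alpha=0.6)
        lim = [min(y.min(), pred.min()), max(y.max(), pred.max())]
        ax_row[1].plot(lim, lim, "r--", lw=1)
        ax_row[1].set_xlabel("actual IR (mGy)")
        ax_row[1].set_ylabel("predicted IR (mGy)")
        ax_row[2].hist(y - pred, bins=30)
        ax_row[2].set_xlabel("error (mGy)")
        ax_row[2].set_ylabel("count")
    fig.tight_layout()
    p = out / "benchmark.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    paths.append(p)
    return paths


def plot_convergence(result: BenchResult, out_dir: str | Path) -> Path:
    """Per-particle p_best and swarm g_best MSE across PSO iterations."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [r for r in result.rows if not r.failed and r.trace is not None]
    fig, axes = plt.subplots(1, len(rows), figsize=(4 * len(rows), 3.2), squeeze=False)
    for ax, r in zip(axes[0], rows):
        p_best = np.array(r.trace.p_best)
        for j in range(p_best.shape[1]):
            ax.plot(p_best[:, j], lw=0.7, alpha=0.5)
        ax.plot(r.trace.g_best, "k-", lw=2, label="g_best")
        ax.set_title(r.name, fontsize=9)
        ax.set_xlabel("iteration")
        ax.set_ylabel("CV MSE")
        ax.legend(fontsize=7)
    fig.tight_layout()
    p = out / "pso_convergence.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    return p


def plot_explanation(explanation: dict, out_path: str | Path) -> Path:
    """Horizontal signed-contribution bars for one explained instance."""
    contribs = explanation["contributions"]
    labels = [f"{c['condition']}\n(value {c['value']:.2f})" for c in contribs][::-1]
    vals = [c["contribution"] for c in contribs][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.7 * len(vals) + 1.2))
    colors = ["tab:green" if v >= 0 else "tab:red" for v in vals]
    ax.barh(range(len(vals)), vals, color=colors)
    ax.set_yticks(range(len(vals)), labels, fontsize=8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("contribution to predicted IR (mGy)")
    ax.set_title(f"instance {explanation['instance_id']}", fontsize=10)
    fig.tight_layout()
    out = Path(out_path)
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
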