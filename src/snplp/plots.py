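"""Optional matplotlib figures for evaluation reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_retrieval(reports: dict[str, "EvaluationReport"], out_path) -> None:
    """PR and ROC retrieval curves, one line per ranking method."""
    fig, (ax_pr, ax_roc) = plt.subplots(1, 2, figsize=(10, 4))
    for name, rep in reports.items():
        if rep.pr_points:
            ax_pr.plot(*zip(*rep.pr_points), label=name)
        if rep.roc_points:
            ax_roc.plot(*zip(*rep.roc_points), label=name)
    ax_pr.set(xlabel="recall", ylabel="precision", title="Causal-SNP retrieval")
    ax_roc.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax_roc.set(xlabel="false positive rate", ylabel="true positive rate", title="ROC")
    ax_roc.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_auc_vs_panel(reports: dict[str, "EvaluationReport"], out_path) -> None:
    """Cross-validated AUC against panel size, with 95% CIs."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, rep in reports.items():
        ns = [n for n in rep.panel_sizes if rep.auc_by_n.get(n) is not None]
        aucs = [rep.auc_by_n[n][0] for n in ns]
        los = [rep.auc_by_n[n][1] for n in ns]
        his = [rep.auc_by_n[n][2] for n in ns]
        ax.errorbar(ns, aucs,
                    yerr=[[a - l for a, l in zip(aucs, los)],
                          [h - a for a, h in zip(aucs, his)]],
                    marker="o", capsize=3, label=name)
    ax.set(xscale="log", xlabel="top-n SNPs in panel", ylabel="AUC",
           title="kNN cross-validated AUC")
    ax.axhline(0.5, color="k", ls="--", lw=0.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_reproducibility(curves: dict[str, dict[int, float]], n_universe: int,
                         out_path) -> None:
    """Top-n overlap fraction against depth; diagonal = random expectation."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, by_depth in curves.items():
        depths = sorted(by_depth)
        ax.plot(depths, [by_depth[d] for d in depths], marker="o", label=name)
    depths = sorted(next(iter(curves.values()))) if curves else []
    if depths:
        ax.plot(depths, [d / n_universe for d in depths], "k--", lw=0.8,
                label="random")
    ax.set(xscale="log", xlabel="list depth n", ylabel="overlap fraction",
           title="Top-n ranking reproducibility", ylim=(0, 1.05))
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
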