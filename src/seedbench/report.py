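"""Summary tables and optional figures from experiment result tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .experiments import split_summary

__all__ = ["write_report"]


def write_report(results: pd.DataFrame, out_dir, plots: bool = True) -> Path:
    """Write a condition-level summary CSV (mean and SE across replications)
    and, when matplotlib is available, accuracy plots per experiment kind.
    Returns the summary CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = split_summary(results)
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)
    if plots:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:
            return summary_path
        for experiment, g in summary.groupby("experiment"):
            acc = g[g["metric"] == "accuracy"]
            if acc.empty:
                continue
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for split, gs in acc.groupby("split"):
                gs = gs.sort_values("condition", key=_cond_key)
                x = range(len(gs))
                ax.errorbar(x, gs["mean"], yerr=gs["se"], marker="o",
                            capsize=3, label=split)
                ax.set_xticks(list(x))
                ax.set_xticklabels([str(c) for c in gs["condition"]],
                                   rotation=45, ha="right", fontsize=8)
            ax.set_xlabel("condition")
            ax.set_ylabel("accuracy")
            ax.set_title(f"{experiment} experiment")
            ax.legend()
            fig.tight_layout()
            fig.savefig(out / f"{experiment}_accuracy.png", dpi=120)
            plt.close(fig)
    return summary_path


def _cond_key(s: pd.Series) -> pd.Series:
    def key(c):
        try:
            return float(str(c).split(":")[-1])
        except ValueError:
            return float("inf")
    return s.map(key)
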