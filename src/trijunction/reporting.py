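"""Plots, tables and text summaries of sweep and null-model results."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .inference import NullModelResult

__all__ = [
    "plot_radius_sweep",
    "plot_observed_vs_expected",
    "results_to_json",
    "results_to_csv",
    "text_summary",
    "write_report",
]

_COLORS = {"TRI": "0.45", "BI": "tab:blue", "BODY": "tab:red"}
_LABELS = {"TRI": "tricellular", "BI": "bicellular", "BODY": "transcellular"}


def plot_radius_sweep(sweep: pd.DataFrame, path: str | Path) -> None:
    """Null category frequency versus dilation radius."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for key, col in (("TRI", "p_tri"), ("BI", "p_bi"), ("BODY", "p_body")):
        ax.plot(sweep["radius_um"], sweep[col], marker="o", ms=3,
                color=_COLORS[key], label=_LABELS[key])
    ax.set_xlabel("junction radius (µm)")
    ax.set_ylabel("null pixel frequency")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_observed_vs_expected(results: list[NullModelResult],
                              path: str | Path) -> None:
    """Stacked observed vs expected category composition per radius."""
    if not results:
        raise ValueError("no results to plot")
    fig, ax = plt.subplots(figsize=(max(4, 1.2 * len(results)), 3.5))
    width = 0.38
    for i, res in enumerate(results):
        n = max(res.n_events, 1)
        bottoms = [0.0, 0.0]
        for key in ("BODY", "BI", "TRI"):
            obs = res.observed[key] / n
            exp = res.expected_probs[key]
            ax.bar(i - width / 2, obs, width, bottom=bottoms[0],
                   color=_COLORS[key],
                   label=_LABELS[key] if i == 0 else None)
            ax.bar(i + width / 2, exp, width, bottom=bottoms[1],
                   color=_COLORS[key], alpha=0.45)
            bottoms[0] += obs
            bottoms[1] += exp
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels([f"{r.radius:g}" for r in results])
    ax.set_xlabel("radius (µm)  [left: observed, right: null]")
    ax.set_ylabel("fraction of events")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def results_to_json(results: list[NullModelResult], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in results],
                                     indent=2))


def results_to_csv(results: list[NullModelResult], path: str | Path) -> None:
    pd.DataFrame([r.summary_row() for r in results]).to_csv(path, index=False)


def text_summary(results: list[NullModelResult], alpha: float = 0.05) -> str:
    """Plain-text verdict per radius, naming enriched categories."""
    if not results:
        raise ValueError("no results to summarize")
    lines = []
    for res in results:
        flags = [
            f"{_LABELS[c.category]} enriched {c.enrichment:.2f}x "
            f"(adj p={c.adjusted_p:.3g})"
            for c in res.per_category
            if c.adjusted_p < alpha and c.enrichment > 1
        ]
        verdict = "; ".join(flags) if flags else "consistent with random location"
        lines.append(
            f"radius {res.radius:g} µm: n={res.n_events} "
            f"(TRI {res.observed['TRI']}, BI {res.observed['BI']}, "
            f"BODY {res.observed['BODY']}), global p={res.global_p:.4g} -> "
            f"{verdict}")
    return "\n".join(lines)


def write_report(results: list[NullModelResult], sweep: pd.DataFrame | None,
                 out_dir: str | Path, alpha: float = 0.05) -> dict[str, Path]:
    """Write the full report bundle (plots, JSON, CSV, text summary)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if sweep is not None and len(sweep):
        paths["sweep_plot"] = out_dir / "frequency_vs_radius.png"
        plot_radius_sweep(sweep, paths["sweep_plot"])
    paths["bars_plot"] = out_dir / "observed_vs_expected.png"
    plot_observed_vs_expected(results, paths["bars_plot"])
    paths["results_json"] = out_dir / "null_results.json"
    results_to_json(results, paths["results_json"])
    paths["results_csv"] = out_dir / "null_results_summary.csv"
    results_to_csv(results, paths["results_csv"])
    paths["summary_txt"] = out_dir / "summary.txt"
    paths["summary_txt"].write_text(text_summary(results, alpha=alpha) + "\n")
    return paths
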