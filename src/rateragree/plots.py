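"""Figures: rank-order accuracy, extended Bland-Altman, agreement panel, items.

Plotting is a pure view layer: every function draws from already-computed
result objects (or their JSON-parsed dicts) and never recomputes statistics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bland_altman import BlandAltmanResult
from .ranking import ItemSummary, ParticipantRank


def rank_plot(ranks: Sequence[ParticipantRank], path: str | Path) -> Path:
    """Mean accuracy per participant in rank order, with across-rater SD bars."""
    path = Path(path)
    ranks = sorted(ranks, key=lambda r: r.rank)
    x = [r.rank for r in ranks]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    ax1.errorbar(x, [r.mean_accuracy for r in ranks],
                 yerr=[r.sd_accuracy for r in ranks],
                 fmt="o", ms=3, lw=0.8, capsize=2, color="tab:blue")
    ax1.set_xlabel("participant rank")
    ax1.set_ylabel("accuracy score (%)")
    ax1.set_title("mean ± across-evaluator SD")
    k = len(ranks[0].per_evaluator_means) if ranks else 0
    for r_idx in range(k):
        ax2.plot(x, [r.per_evaluator_means[r_idx] for r in ranks],
                 ".", ms=3, label=f"evaluator {r_idx + 1}")
    ax2.set_xlabel("participant rank")
    ax2.set_title("per-evaluator means")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def ba_plot(result: BlandAltmanResult, path: str | Path) -> Path:
    """Extended Bland-Altman: mean vs intra-subject SD with the LOA line."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(result.means, result.intra_subject_sds, s=14, alpha=0.7)
    ax.axhline(result.loa, color="red", lw=1.2,
               label=f"95% LOA = {result.loa:.1f}")
    if result.bootstrap_ci is not None:
        ax.axhspan(result.bootstrap_ci[0], result.bootstrap_ci[1],
                   color="red", alpha=0.12,
                   label=(f"bootstrap BC 95% CI "
                          f"({result.bootstrap_ci[0]:.1f}–"
                          f"{result.bootstrap_ci[1]:.1f})"))
    # per-evaluator mean tick marks on the right margin
    xmax = ax.get_xlim()[1]
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for r_idx, m in enumerate(result.evaluator_means):
        ax.plot([xmax], [0], alpha=0)  # keep limits
        ax.annotate("", xy=(1.0, 0), xycoords=("axes fraction", "data"))
        ax.plot(1.005, m, marker="<", color=colors[r_idx % len(colors)],
                transform=ax.get_yaxis_transform(), clip_on=False, ms=6)
    ax.set_xlabel("participant mean accuracy (%)")
    ax.set_ylabel("intra-subject SD across evaluators (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def agreement_panel(bundle: Mapping[str, Any], path: str | Path) -> Path:
    """Two-panel agreement view: Pearson heatmap and ICC forest plot."""
    path = Path(path)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    r = np.asarray(bundle["pearson"]["r"], dtype=float)
    ids = bundle["pearson"]["evaluator_ids"]
    im = ax1.imshow(r, vmin=0, vmax=1, cmap="viridis")
    ax1.set_xticks(range(len(ids)), ids)
    ax1.set_yticks(range(len(ids)), ids)
    for i in range(len(ids)):
        for j in range(len(ids)):
            ax1.text(j, i, f"{r[i, j]:.2f}", ha="center", va="center",
                     color="w", fontsize=8)
    fig.colorbar(im, ax=ax1, shrink=0.8)
    ax1.set_title("pairwise Pearson r")
    iccs = bundle["icc"]
    y = np.arange(len(iccs))
    vals = [e["value"] for e in iccs]
    lo = [e["value"] - e["ci_low"] for e in iccs]
    hi = [e["ci_high"] - e["value"] for e in iccs]
    ax2.errorbar(vals, y, xerr=[lo, hi], fmt="o", capsize=3)
    ax2.set_yticks(y, [e["form"] for e in iccs])
    ax2.axvline(0.40, color="grey", ls=":", lw=0.8)
    ax2.axvline(0.75, color="grey", ls=":", lw=0.8)
    ax2.set_xlim(0, 1)
    ax2.invert_yaxis()
    ax2.set_title("ICC (95% CI); dotted: Fleiss bands")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def items_plot(items: Sequence[ItemSummary], path: str | Path) -> Path:
    """Mean accuracy per item with across-evaluator SD bars."""
    path = Path(path)
    items = sorted(items, key=lambda s: -s.mean_accuracy)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.3 * len(items))))
    y = np.arange(len(items))
    ax.barh(y, [s.mean_accuracy for s in items],
            xerr=[s.sd_across_evaluators for s in items],
            color="tab:blue", alpha=0.8, capsize=2)
    ax.set_yticks(y, [s.label for s in items], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("mean accuracy (%) ± across-evaluator SD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
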