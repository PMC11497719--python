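"""Clinician-facing interpretation graphics.

Two coordinated views per clinical question: an UpSet plot of the
2^k normal/abnormal marker flag patterns (matrix of dots below stacked
bars, one column per pattern) showing how common each pattern is and which
diagnosis dominates it, and a probability density plot of the aggregated
logistic score per class with the three probability threshold lines. A
single patient is overlaid as a highlighted UpSet column and a vertical
line in the density plot; the combined one-page report adds a
value-versus-threshold table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MarkerPanel
from .models import QuestionModel, classify_patient

__all__ = [
    "UpSetSummary",
    "upset_summarize",
    "render_upset",
    "render_density",
    "render_patient_report",
    "reflected_kde",
]


@dataclass
class UpSetSummary:
    """Counts and composition of every normal/abnormal flag pattern.

    ``combos`` holds one entry per pattern (tuple of booleans in marker
    order, True = abnormal), including empty patterns with count 0, ordered
    by descending count with ties broken by the pattern's binary value.
    """

    question_id: str
    markers: tuple[str, ...]
    combos: list[dict]
    n_total: int
    positive_label: str

    def combo(self, pattern) -> dict:
        pattern = tuple(bool(p) for p in pattern)
        for c in self.combos:
            if c["pattern"] == pattern:
                return c
        raise KeyError(f"pattern {pattern} not a valid combo")


def _flag_patterns(subset: pd.DataFrame, model: QuestionModel) -> pd.Series:
    flags = {}
    for m in model.markers:
        t = model.marker_thresholds[m]
        v = subset[m].to_numpy(float)
        flags[m] = v < t["cutoff"] if t["direction"] == "lower_abnormal" else v > t["cutoff"]
    mat = np.column_stack([flags[m] for m in model.markers])
    return pd.Series([tuple(bool(b) for b in row) for row in mat], index=subset.index)


def upset_summarize(subset: pd.DataFrame, model: QuestionModel) -> UpSetSummary:
    """Group a question subset by its marker flag pattern.

    Each subject is flagged normal/abnormal per marker using the model's
    Youden cutoffs, then patterns are tallied: count, fraction of the
    subset, and composition by outcome class within the pattern.
    """
    markers = list(model.markers)
    cc = subset.dropna(subset=markers)
    if len(cc) == 0:
        raise ValueError("empty subset")
    patterns = _flag_patterns(cc, model)
    y = cc["outcome"].to_numpy(int)
    n_total = len(cc)
    combos = []
    for pattern in product([False, True], repeat=len(markers)):
        sel = (patterns == pattern).to_numpy()
        count = int(sel.sum())
        if count:
            pos = float(y[sel].mean())
            composition = {"positive": pos, "negative": 1.0 - pos}
        else:
            composition = {"positive": 0.0, "negative": 0.0}
        combos.append(
            {
                "pattern": pattern,
                "count": count,
                "fraction": count / n_total,
                "composition": composition,
            }
        )
    combos.sort(
        key=lambda c: (-c["count"], sum(b << i for i, b in enumerate(c["pattern"])))
    )
    return UpSetSummary(
        question_id=model.question_id,
        markers=tuple(markers),
        combos=combos,
        n_total=n_total,
        positive_label=model.positive_label or "positive",
    )


def render_upset(
    summary: UpSetSummary,
    highlight=None,
    path=None,
    ax_pair=None,
):
    """Matrix-dot UpSet figure: stacked bars over a dot matrix.

    Dark dots mark abnormal markers, light dots normal ones; bars are
    stacked by outcome class. ``highlight`` draws a box around the column
    of one flag pattern (the patient's). Returns the matplotlib Figure.
    """
    if highlight is not None:
        highlight = tuple(bool(b) for b in highlight)
        summary.combo(highlight)  # raises KeyError if invalid
    k = len(summary.markers)
    ncols = len(summary.combos)
    if ax_pair is None:
        fig, (ax_bar, ax_dot) = plt.subplots(
            2, 1, figsize=(max(6, 0.8 * ncols), 5),
            gridspec_kw={"height_ratios": [3, 1], "hspace": 0.05},
            sharex=True,
        )
    else:
        ax_bar, ax_dot = ax_pair
        fig = ax_bar.figure

    xs = np.arange(ncols)
    pos_frac = np.array([c["composition"]["positive"] for c in summary.combos])
    counts = np.array([c["count"] for c in summary.combos], dtype=float)
    pos_h = counts * pos_frac
    neg_h = counts - pos_h
    ax_bar.bar(xs, pos_h, color="#b2182b", label=summary.positive_label)
    ax_bar.bar(xs, neg_h, bottom=pos_h, color="#2166ac", label="other")
    for x, c in zip(xs, summary.combos):
        ax_bar.text(x, c["count"], f"{100 * c['fraction']:.0f}%",
                    ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel("subjects")
    ax_bar.legend(frameon=False, fontsize=8)

    for x, c in zip(xs, summary.combos):
        for row, abnormal in enumerate(c["pattern"]):
            ax_dot.scatter(
                x, row,
                s=60,
                color="#1a1a1a" if abnormal else "#cccccc",
                zorder=3,
            )
    ax_dot.set_yticks(range(k))
    ax_dot.set_yticklabels(summary.markers, fontsize=8)
    ax_dot.set_ylim(-0.7, k - 0.3)
    ax_dot.invert_yaxis()
    ax_dot.set_xticks(xs)
    ax_dot.set_xticklabels([])

    if highlight is not None:
        col = next(i for i, c in enumerate(summary.combos) if c["pattern"] == highlight)
        for ax, (y0, y1) in ((ax_bar, ax_bar.get_ylim()), (ax_dot, ax_dot.get_ylim())):
            ax.add_patch(
                plt.Rectangle(
                    (col - 0.45, min(y0, y1)), 0.9, abs(y1 - y0),
                    fill=False, edgecolor="#ff7f00", linewidth=2, zorder=4,
                )
            )

    if path is not None:
        _save(fig, path)
    return fig


def reflected_kde(samples, grid, bw_method="silverman"):
    """Gaussian KDE on [0, 1] with boundary reflection at both ends."""
    samples = np.asarray(samples, dtype=float)
    if np.ptp(samples) == 0:
        # degenerate: a narrow Gaussian bump at the single value
        width = 0.01
        d = stats.norm.pdf(grid, loc=samples[0], scale=width)
        d += stats.norm.pdf(-np.asarray(grid), loc=samples[0], scale=width)
        d += stats.norm.pdf(2 - np.asarray(grid), loc=samples[0], scale=width)
        return d
    kde = stats.gaussian_kde(samples, bw_method=bw_method)
    g = np.asarray(grid, dtype=float)
    return kde(g) + kde(-g) + kde(2.0 - g)


def render_density(
    probs_by_class: dict,
    model: QuestionModel,
    patient_probability: float | None = None,
    path=None,
    ax=None,
    grid_points: int = 512,
):
    """Per-class smoothed probability densities with threshold lines.

    ``probs_by_class`` maps a class label to that class's development
    probabilities. Classes with fewer than 5 points fall back to a rug
    plot with a warning. Threshold lines are drawn vertically at the
    Youden, 90%-sensitivity, and 90%-specificity probability cutoffs.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    grid = np.linspace(0.0, 1.0, grid_points)
    palette = ["#2166ac", "#b2182b", "#4daf4a", "#984ea3"]
    for color, (label, probs) in zip(palette, probs_by_class.items()):
        probs = np.asarray(probs, dtype=float)
        if len(probs) < 5:
            warnings.warn(
                f"class {label!r} has {len(probs)} < 5 probabilities; "
                "drawing a rug instead of a density", stacklevel=2,
            )
            ax.plot(probs, np.zeros_like(probs), "|", color=color,
                    markersize=15, label=label)
            continue
        dens = reflected_kde(probs, grid)
        ax.plot(grid, dens, color=color, label=label)
        ax.fill_between(grid, dens, alpha=0.2, color=color)
    th = model.prob_thresholds
    for key, style in (("youden", "-"), ("sens90", "--"), ("spec90", ":")):
        ax.axvline(th[key], color="#555555", linestyle=style, linewidth=1,
                   label=f"{key} = {th[key]:.2f}")
    if patient_probability is not None:
        ax.axvline(patient_probability, color="#ff7f00", linewidth=2,
                   label=f"patient = {patient_probability:.2f}")
    ax.set_xlim(0, 1)
    ax.set_xlabel(f"probability of {model.positive_label or 'positive class'}")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=7)
    if path is not None:
        _save(fig, path)
    return fig


def render_patient_report(
    panel: MarkerPanel,
    age: float,
    model: QuestionModel,
    development_summary: UpSetSummary,
    probs_by_class: dict,
    path=None,
):
    """One-page report: value/threshold table, UpSet with the patient's
    column boxed, density with the patient's probability line, and the
    likelihood-zone statement. The clinical question is the caller's
    choice; the report is specific to the supplied model."""
    result = classify_patient(panel, age, model)
    pattern = tuple(result.flags[m] for m in model.markers)

    fig = plt.figure(figsize=(11, 8))
    gs = fig.add_gridspec(
        2, 2, height_ratios=[3, 1.2], width_ratios=[1.2, 1], hspace=0.3
    )
    ax_bar = fig.add_subplot(gs[0, 0])
    ax_dot = fig.add_subplot(gs[1, 0], sharex=ax_bar)
    ax_den = fig.add_subplot(gs[0, 1])
    ax_tab = fig.add_subplot(gs[1, 1])
    ax_tab.axis("off")

    render_upset(development_summary, highlight=pattern, ax_pair=(ax_bar, ax_dot))
    render_density(probs_by_class, model,
                   patient_probability=result.probability, ax=ax_den)

    rows = []
    for m in model.markers:
        t = model.marker_thresholds[m]
        rel = "<" if t["direction"] == "lower_abnormal" else ">"
        rows.append([
            m,
            f"{result.marker_values[m]:.2f}",
            f"abnormal {rel} {t['cutoff']:.2f}",
            "abnormal" if result.flags[m] else "normal",
        ])
    table = ax_tab.table(
        cellText=rows,
        colLabels=["marker", "value", "threshold", "flag"],
        loc="center",
    )
    table.auto_set_font_size(False)
    table.set_fontsize(8)

    fig.suptitle(
        f"{model.question_id}: probability {result.probability:.2f} "
        f"({result.zone} likelihood of {model.positive_label})",
        fontsize=11,
    )
    if path is not None:
        _save(fig, path)
    return fig


def _save(fig, path) -> None:
    """Write SVG and 300-dpi PNG siblings for a figure path."""
    from pathlib import Path

    p = Path(path)
    if p.suffix:
        fig.savefig(p, dpi=300, bbox_inches="tight")
    else:
        fig.savefig(p.with_suffix(".svg"), bbox_inches="tight")
        fig.savefig(p.with_suffix(".png"), dpi=300, bbox_inches="tight")
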