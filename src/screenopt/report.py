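"""Plot suite and self-contained HTML report.

The report summarizes one optimization run: a histogram of the criterion
across all tested models with the significance threshold marked; the
linear-log ROC of the best model; per-parameter boxplots of the criterion;
pairwise heatmaps (each cell holding the *maximum* criterion achieved at
that parameter-value combination); split violins of score by class grouped
by net molecular charge (exposing charge bias); and a ridgeline of the
energy terms by class.  Every figure is rebuilt from results.csv and the
persisted per-molecule score tables alone, so regenerating the report
needs no recompute.
"""

from __future__ import annotations

import base64
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from screenopt.enrichment import DEFAULT_LAMBDA, ScoredClasses, roc_curve

__all__ = [
    "plot_histogram_with_threshold",
    "plot_roc",
    "plot_boxplot",
    "plot_heatmap",
    "plot_violin_by_charge",
    "plot_energy_ridgeline",
    "render_report",
]

_NON_PARAM_COLUMNS = {
    "id", "step", "sphere_provenance", "criterion", "criterion_value", "status",
    "mean_score_pos", "mean_score_neg",
}


def parameter_columns(results: pd.DataFrame) -> list[str]:
    return [c for c in results.columns if c not in _NON_PARAM_COLUMNS]


def plot_histogram_with_threshold(results: pd.DataFrame, threshold: float | None):
    """Histogram of criterion values across tested models + threshold line.

    Returns (figure, counts): bin counts sum to the number of models with
    a successful evaluation.
    """
    values = results.loc[results["status"] == "ok", "criterion_value"].astype(float)
    if values.empty:
        raise ValueError("no successfully evaluated models to plot")
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, _, _ = ax.hist(values, bins=min(40, max(1, values.nunique())), color="#4878d0")
    if threshold is not None:
        ax.axvline(threshold, color="crimson", linestyle="--",
                   label=f"significance threshold = {threshold:.3f}")
        ax.legend()
    ax.set_xlabel("criterion value")
    ax.set_ylabel("tested models")
    ax.set_title(f"Performance of {values.size} tested docking models")
    return fig, counts


def plot_roc(scores: pd.DataFrame, lam: float = DEFAULT_LAMBDA):
    """Linear-log ROC of positives vs negatives for one model's score table."""
    scored = ScoredClasses(
        scores_pos=scores.loc[scores["label"] == "positive", "total_score"].to_numpy(),
        scores_neg=scores.loc[scores["label"] == "negative", "total_score"].to_numpy(),
    )
    curve = roc_curve(scored, lam)
    pts = curve.points.copy()
    pts[:, 0] = np.clip(pts[:, 0], lam, 1.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(pts[:, 0], pts[:, 1], drawstyle="default", color="#4878d0", label="best model")
    xs = np.logspace(np.log10(lam), 0, 100)
    ax.plot(xs, xs, linestyle=":", color="gray", label="random")
    ax.set_xscale("log")
    ax.set_xlim(lam, 1.0)
    ax.set_ylim(0, 1.02)
    ax.set_xlabel("false positive rate (log scale)")
    ax.set_ylabel("true positive rate")
    ax.legend()
    ax.set_title("Enrichment of positives over negatives")
    return fig


def plot_boxplot(results: pd.DataFrame, param: str):
    """Criterion distribution per tested value of one parameter."""
    ok = results[results["status"] == "ok"]
    if param not in results.columns:
        raise KeyError(f"unknown parameter column {param!r}")
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = ok.groupby(param, dropna=True)["criterion_value"]
    labels = [f"{k:.3g}" if isinstance(k, float) else str(k) for k in groups.groups]
    ax.boxplot([g.to_numpy(dtype=float) for _, g in groups], tick_labels=labels)
    ax.set_xlabel(param)
    ax.set_ylabel("criterion value")
    fig.autofmt_xdate(rotation=30)
    return fig


def plot_heatmap(results: pd.DataFrame, param_x: str, param_y: str):
    """Max-criterion heatmap over a parameter pair.

    Each cell holds the maximum criterion value across all
    parameterizations that used that (x, y) value combination; cells never
    visited are missing.  Both parameters must be multivalued in the
    results — for a single-valued parameter use :func:`plot_boxplot`.
    """
    ok = results[results["status"] == "ok"]
    for p in (param_x, param_y):
        if p not in results.columns:
            raise KeyError(f"unknown parameter column {p!r}")
        if ok[p].nunique(dropna=True) < 2:
            raise ValueError(
                f"parameter {p!r} is single-valued in these results; use a boxplot instead"
            )
    matrix = (
        ok.groupby([param_y, param_x])["criterion_value"].max().unstack(param_x)
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    sns.heatmap(matrix, ax=ax, cmap="viridis",
                cbar_kws={"label": "max criterion value"})
    ax.set_xlabel(param_x)
    ax.set_ylabel(param_y)
    ax.set_xticklabels([f"{float(t.get_text()):.3g}" if _is_float(t.get_text()) else t.get_text()
                        for t in ax.get_xticklabels()], rotation=30)
    ax.set_yticklabels([f"{float(t.get_text()):.3g}" if _is_float(t.get_text()) else t.get_text()
                        for t in ax.get_yticklabels()], rotation=0)
    return matrix, fig


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def plot_violin_by_charge(scores: pd.DataFrame):
    """Split violins of total score by class, grouped by net molecular charge."""
    df = scores.copy()
    df["net_charge"] = df["net_charge"].astype(int)
    fig, ax = plt.subplots(figsize=(6, 4))
    split = df["label"].nunique() == 2
    sns.violinplot(data=df, x="net_charge", y="total_score", hue="label",
                   split=split, inner="quart", ax=ax, cut=0, density_norm="width")
    ax.set_xlabel("net charge (e)")
    ax.set_ylabel("total score")
    ax.set_title("Score by class, grouped by charge")
    return fig


ENERGY_TERMS = ("electrostatic", "vdw", "ligand_desolvation")


def plot_energy_ridgeline(scores: pd.DataFrame):
    """Ridgeline (stacked densities) of each energy term, split by class."""
    fig, axes = plt.subplots(len(ENERGY_TERMS), 1, figsize=(6, 1.8 * len(ENERGY_TERMS)),
                             sharex=True)
    palette = {"positive": "#4878d0", "negative": "#ee854a"}
    for ax, term in zip(np.atleast_1d(axes), ENERGY_TERMS):
        for label, group in scores.groupby("label"):
            vals = group[term].to_numpy(dtype=float)
            if np.ptp(vals) > 0:
                sns.kdeplot(vals, ax=ax, fill=True, alpha=0.5,
                            color=palette.get(label), label=label)
            else:
                ax.axvline(vals[0], color=palette.get(label), alpha=0.7, label=label)
        ax.set_ylabel(term, rotation=0, ha="right", fontsize=8)
        ax.set_yticks([])
    np.atleast_1d(axes)[0].legend(fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("energy (score units)")
    fig.suptitle("Energy terms by class")
    fig.tight_layout()
    return fig


def _embed(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def _section(title: str, body: str) -> str:
    return f"<section><h2>{title}</h2>\n{body}\n</section>\n"


def _figure_or_note(title: str, builder) -> str:
    """Render a plot section, or an explicit 'not available' note on failure."""
    try:
        out = builder()
        fig = out[-1] if isinstance(out, tuple) else out
        return _section(title, f'<img src="data:image/png;base64,{_embed(fig)}"/>')
    except Exception as exc:  # noqa: BLE001 — report sections degrade, never vanish
        return _section(title, f"<p><em>not available: {exc}</em></p>")


def render_report(
    path: str | Path,
    results: pd.DataFrame,
    best_scores: pd.DataFrame | None,
    threshold: float | None,
    criterion_name: str = "normalized_logauc",
) -> Path:
    """Write the self-contained HTML report; returns the output path.

    ``results`` is the results.csv table; ``best_scores`` the per-molecule
    score table of the top-ranked model (may be None, in which case the
    score-based sections carry an explicit note instead of a figure).
    """
    params = parameter_columns(results)
    multi = [p for p in params
             if results.loc[results["status"] == "ok", p].nunique(dropna=True) >= 2]

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>screenopt report</title>"
        "<style>body{font-family:sans-serif;max-width:900px;margin:2em auto;}"
        "h2{border-bottom:1px solid #ccc;}</style></head><body>",
        f"<h1>Docking-model optimization report</h1>"
        f"<p>{int((results['status'] == 'ok').sum())} models evaluated; criterion: "
        f"{criterion_name}.</p>",
        _figure_or_note(
            "Model performance histogram with significance threshold",
            lambda: plot_histogram_with_threshold(results, threshold),
        ),
    ]
    if best_scores is not None:
        parts.append(_figure_or_note("Linear-log ROC (best model)",
                                     lambda: plot_roc(best_scores)))
        parts.append(_figure_or_note("Score by class, grouped by net charge",
                                     lambda: plot_violin_by_charge(best_scores)))
        parts.append(_figure_or_note("Energy terms by class",
                                     lambda: plot_energy_ridgeline(best_scores)))
    else:
        for title in ("Linear-log ROC (best model)",
                      "Score by class, grouped by net charge",
                      "Energy terms by class"):
            parts.append(_section(title, "<p><em>not available: no score table</em></p>"))
    for p in multi:
        parts.append(_figure_or_note(f"Criterion by {p}",
                                     lambda p=p: plot_boxplot(results, p)))
    if len(multi) >= 2:
        for i in range(len(multi)):
            for j in range(i + 1, len(multi)):
                parts.append(
                    _figure_or_note(
                        f"Max criterion heatmap: {multi[i]} vs {multi[j]}",
                        lambda a=multi[i], b=multi[j]: plot_heatmap(results, a, b),
                    )
                )
    else:
        parts.append(_section("Parameter heatmaps",
                              "<p><em>not available: fewer than two multivalued "
                              "parameters</em></p>"))
    parts.append("</body></html>")
    path = Path(path)
    path.write_text("\n".join(parts))
    return path
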