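"""Figure outputs: Lasso coefficient paths, concentration curve,
decomposition contributions, and the score distribution by consumption
quartile."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .scores import quantile_group  # noqa: E402


def coefficient_path(lasso_fit, ax=None, max_labels: int = 8):
    """Standardized coefficients against log(lambda); selected lambda marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = lasso_fit.lambda_grid
    path = lasso_fit.coef_path
    show = [c for c in path.columns if not c.startswith(("city_", "comm_"))]
    for c in show:
        ax.plot(np.log(grid), path[c], lw=1,
                label=c if len(show) <= max_labels else None)
    ax.axvline(np.log(lasso_fit.selected_lambda), color="k", ls="--", lw=0.8)
    ax.set_xlabel("log(lambda)")
    ax.set_ylabel("standardized coefficient")
    ax.set_title("Lasso coefficient paths")
    if len(show) <= max_labels:
        ax.legend(fontsize=7)
    return ax


def concentration_curve_plot(result, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    p, L = result.curve[:, 0], result.curve[:, 1]
    ax.plot(p, L, label=f"curve (CI={result.ci:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="equality")
    ax.set_xlabel(f"cumulative population share (ranked by {result.ranking_name})")
    ax.set_ylabel("cumulative outcome share")
    ax.legend()
    return ax


def contribution_bars(grouped, residual_pct: float, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = list(grouped["group"]) + ["residual"]
    vals = list(grouped["pct_contribution"]) + [residual_pct]
    ax.barh(labels[::-1], vals[::-1])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("% contribution to CI")
    ax.set_title("Decomposition of inequality")
    return ax


def score_by_quartile(df, outcome: str = "he_total",
                      ranking: str = "consumption", ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    q = quantile_group(df[ranking].to_numpy(), 4)
    data = [df.loc[q == g, outcome] for g in (1, 2, 3, 4)]
    ax.boxplot(data, tick_labels=["Q1", "Q2", "Q3", "Q4"])
    ax.set_xlabel(f"{ranking} quartile")
    ax.set_ylabel(outcome)
    return ax


def save_all(outdir, df, fit, ineq) -> None:
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    if fit is not None and fit["post_double"].step1 is not None:
        ax = coefficient_path(fit["post_double"].step1)
        ax.figure.savefig(figdir / "lasso_path.png", dpi=120,
                          bbox_inches="tight")
        plt.close(ax.figure)
    ax = concentration_curve_plot(ineq["concentration"])
    ax.figure.savefig(figdir / "concentration_curve.png", dpi=120,
                      bbox_inches="tight")
    plt.close(ax.figure)
    ax = contribution_bars(ineq["grouped"], ineq["decomposition"].residual_pct)
    ax.figure.savefig(figdir / "contributions.png", dpi=120,
                      bbox_inches="tight")
    plt.close(ax.figure)
    ax = score_by_quartile(df)
    ax.figure.savefig(figdir / "score_by_quartile.png", dpi=120,
                      bbox_inches="tight")
    plt.close(ax.figure)
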