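"""Accuracy metrics, coefficient interpretation, and figures.

Model accuracy for the binary report is the misclassification percentage
of the fitted conditional probabilities at the 0.5 threshold; VAS
accuracy is reported as mean absolute error plus the fitted-vs-real
scatter.  Every figure has a TSV twin so all reported numbers are
recomputable from the exports alone.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "binary_error_percent",
    "vas_mae",
    "coefficient_to_percent",
    "tstat_heatmap",
    "fitted_vs_real_scatter",
    "accuracy_table",
]


def binary_error_percent(fit) -> float:
    """Misclassification percentage of the binomial window model.

    Predicted class is fitted conditional probability >= 0.5; the error
    is 100 x (mispredicted trials) / (total trials); lower is more
    accurate.
    """
    if fit.model.family != "binomial":
        raise ValueError("binary_error_percent requires a binomial fit")
    fitted = np.asarray(fit.fitted_conditional)
    if fitted.size == 0:
        raise ValueError("empty feature set")
    pred = (fitted >= 0.5).astype(int)
    real = np.asarray(fit.response, dtype=int)
    return float(100.0 * np.mean(pred != real))


def vas_mae(fit) -> float:
    """Mean absolute error of the fitted conditional VAS responses."""
    if fit.model.family != "gaussian":
        raise ValueError("vas_mae requires a gaussian fit")
    fitted = np.asarray(fit.fitted_conditional)
    if fitted.size == 0:
        raise ValueError("empty feature set")
    return float(np.mean(np.abs(fitted - fit.response)))


def coefficient_to_percent(beta: float) -> float:
    """Read a binomial-model coefficient as the percent change in the
    proportion of "yes" responses per unit HFA.

    This is the linear reading ``100 * beta``; strictly the logit slope
    implies a probability change of ``beta * p * (1 - p)`` per z unit,
    so the linear reading is an approximation most accurate near
    p = 0.5.
    """
    return 100.0 * float(beta)


def _window_label(start, end):
    return f"{start:g}:{end:g} ms"


def tstat_heatmap(results: pd.DataFrame, out_tsv=None, out_fig=None,
                  title: str = ""):
    """Region x window heatmap of real t-statistics.

    ``results`` needs columns region, window_start, window_end, t_real,
    significant.  Significant cells are outlined; missing cells render
    neutral (NaN).  Returns ``(fig, matrix)`` where ``matrix`` is the
    region x window DataFrame (also written to ``out_tsv``).
    """
    res = results.copy()
    res["window"] = [
        _window_label(s, e)
        for s, e in zip(res["window_start"], res["window_end"])
    ]
    order = (
        res[["window", "window_start"]]
        .drop_duplicates()
        .sort_values("window_start")["window"]
        .tolist()
    )
    matrix = res.pivot_table(index="region", columns="window",
                             values="t_real", aggfunc="first")
    matrix = matrix.reindex(columns=order)
    sig = res.pivot_table(index="region", columns="window",
                          values="significant", aggfunc="first")
    sig = sig.reindex(index=matrix.index, columns=order).fillna(False)

    fig, ax = plt.subplots(
        figsize=(1.0 + 0.9 * matrix.shape[1], 0.6 + 0.35 * matrix.shape[0])
    )
    vmax = np.nanmax(np.abs(matrix.to_numpy())) if matrix.size else 1.0
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                  edgecolor="black", linewidth=1.5)
                )
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45,
                  ha="right", fontsize=8)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=8)
    # dotted marker at the event boundary (window start crossing 0)
    zero_cols = [j for j, w in enumerate(order)
                 if float(w.split(":")[0]) == 0.0]
    for j in zero_cols:
        ax.axvline(j - 0.5, color="k", linestyle=":", linewidth=1)
    fig.colorbar(im, ax=ax, label="t statistic")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_tsv is not None:
        matrix.to_csv(out_tsv, sep="\t")
    if out_fig is not None:
        fig.savefig(out_fig, dpi=150)
    return fig, matrix


def fitted_vs_real_scatter(fit, out_tsv=None, out_fig=None, title: str = ""):
    """Fitted conditional vs real VAS responses with rank correlation.

    Returns ``(fig, pairs, rho)`` where ``pairs`` is the (real, fitted)
    DataFrame and ``rho`` the Spearman correlation.
    """
    real = np.asarray(fit.response, dtype=float)
    fitted = np.asarray(fit.fitted_conditional, dtype=float)
    pairs = pd.DataFrame({"real": real, "fitted": fitted})
    if real.size >= 2 and np.std(real) > 0 and np.std(fitted) > 0:
        rho = float(spearmanr(real, fitted).statistic)
    else:
        rho = np.nan
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(real, fitted, s=12, alpha=0.6)
    lim = [min(real.min(), fitted.min()) - 0.5,
           max(real.max(), fitted.max()) + 0.5]
    ax.plot(lim, lim, "k--", linewidth=0.8)
    ax.set_xlabel("real VAS response")
    ax.set_ylabel("fitted conditional response")
    ax.set_title(title or f"Spearman rho = {rho:.2f}")
    fig.tight_layout()
    if out_tsv is not None:
        pairs.to_csv(out_tsv, sep="\t", index=False)
    if out_fig is not None:
        fig.savefig(out_fig, dpi=150)
    return fig, pairs, rho


def accuracy_table(results: pd.DataFrame, fits: dict) -> pd.DataFrame:
    """Accuracy metrics for the significant windows only.

    ``fits`` maps (region, event, (start, end), family) to the fitted
    :class:`~painhfa.modeling.PainGlmeResults`.  Binomial rows get the
    misclassification percentage, gaussian rows the VAS MAE.
    """
    rows = []
    for _, r in results.iterrows():
        if not r["significant"]:
            continue
        key = (r["region"], r["event"],
               (r["window_start"], r["window_end"]), r["family"])
        fit = fits.get(key)
        if fit is None:
            continue
        row = dict(region=r["region"], event=r["event"],
                   window_start=r["window_start"],
                   window_end=r["window_end"], family=r["family"],
                   n_trials=len(fit.response))
        if r["family"] == "binomial":
            row["error_percent"] = binary_error_percent(fit)
        else:
            row["mae_vas"] = vas_mae(fit)
        rows.append(row)
    return pd.DataFrame(rows)
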