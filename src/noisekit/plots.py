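"""Publication-style figures for the evaluation layer.

Each function draws onto (and returns) a matplotlib Axes so figures compose;
the CLI saves them as SVG/PNG.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .statseval import RocResult, records_to_frame  # noqa: E402


def scatter_identity(auto, manual, variable="noise", ax=None):
    """Automatic vs manual values with the identity line."""
    ax = ax or plt.subplots()[1]
    ax.scatter(manual, auto, s=14, alpha=0.7)
    lo = min(np.min(auto), np.min(manual))
    hi = max(np.max(auto), np.max(manual))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel(f"manual {variable}")
    ax.set_ylabel(f"automatic {variable}")
    return ax


def bland_altman_plot(auto, manual, variable="noise", ax=None):
    """Difference vs mean with bias and 1.96-SD limits of agreement."""
    ax = ax or plt.subplots()[1]
    auto = np.asarray(auto, float)
    manual = np.asarray(manual, float)
    d = auto - manual
    m = (auto + manual) / 2
    bias = d.mean()
    sd = d.std(ddof=1)
    ax.scatter(m, d, s=14, alpha=0.7)
    for y, style in ((bias, "-"), (bias - 1.96 * sd, "--"), (bias + 1.96 * sd, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel(f"mean of methods ({variable})")
    ax.set_ylabel("automatic - manual")
    return ax


def group_boxplot(records_or_df, variable="snr", ax=None):
    """Box plot of a measurement across the three quality groups."""
    ax = ax or plt.subplots()[1]
    df = records_to_frame(records_or_df)
    df = df[df["status"] == "ok"] if "status" in df else df
    order = ["fully_diagnostic", "excluded_parts", "non_diagnostic"]
    groups = [df.loc[df["quality_label"] == g, variable].dropna() for g in order]
    ax.boxplot(groups, tick_labels=[g.replace("_", "\n") for g in order])
    ax.set_ylabel(variable)
    return ax


def roc_plot(result: RocResult, label: str = "", ax=None):
    """ROC curve with the chance diagonal and AUC in the legend."""
    ax = ax or plt.subplots()[1]
    ax.plot(result.fpr, result.tpr,
            label=f"{label} AUC {result.auc:.2f} "
                  f"({result.auc_ci[0]:.2f}-{result.auc_ci[1]:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
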