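"""Figure helpers for the main result objects (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_positions(positions: pd.DataFrame, ax=None):
    """Forest plot of mean gradient position B with 95% CrI per species,
    ordered by mean B (the display order of the abundance figure)."""
    ax = ax or plt.gca()
    df = positions.sort_values("mean_B").reset_index(drop=True)
    y = np.arange(len(df))
    ax.hlines(y, df["lo95"], df["hi95"], color="0.5")
    ax.plot(df["mean_B"], y, "o", color="saddlebrown")
    ax.set_yticks(y, df["species"])
    ax.set_xlabel("mean position along browning gradient (BPC1)")
    return ax


def plot_variance_partition(varpart: pd.DataFrame, ax=None):
    """Stacked bars of browning vs spatial variance share per species."""
    ax = ax or plt.gca()
    df = varpart.sort_values("browning_prop", ascending=False)
    x = np.arange(len(df))
    ax.bar(x, df["browning_prop"], color="saddlebrown", label="browning")
    ax.bar(x, df["spatial_prop"], bottom=df["browning_prop"],
           color="steelblue", label="spatial")
    ax.set_xticks(x, df["species"], rotation=90, fontsize=6)
    ax.set_ylabel("variance proportion")
    ax.legend(loc="upper right", fontsize=7)
    return ax


def plot_nomogram(nomogram: pd.DataFrame, ax=None):
    """BPC1 score against back-transformed raw metric values (log y-axes
    per metric, since the metrics live on very different scales)."""
    ax = ax or plt.gca()
    for m, colour in (("doc", "saddlebrown"), ("secchi", "steelblue"),
                      ("colour", "darkgoldenrod")):
        ax.plot(nomogram["bpc1"], nomogram[m], label=m, color=colour)
    ax.set_yscale("log")
    ax.set_xlabel("BPC1 (browner →)")
    ax.set_ylabel("back-transformed metric value")
    ax.legend()
    return ax
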