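"""Minimal plotting helpers (accuracy distributions and size effects)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_accuracy_by_method(records_frame: pd.DataFrame, ax=None):
    """Box plot of leave-one-out Bray-Curtis accuracy per method, ordered by
    mean accuracy, with the mean marked per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    df = records_frame[~records_frame["failed"]]
    order = (
        df.groupby("method")["bc_similarity"].mean().sort_values(ascending=False)
    )
    data = [df.loc[df["method"] == m, "bc_similarity"].to_numpy() for m in order.index]
    ax.boxplot(data, tick_labels=list(order.index), showmeans=True)
    ax.set_ylabel("Bray-Curtis similarity")
    ax.set_xlabel("method")
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_sample_size_effect(subsample_frame: pd.DataFrame, ax=None):
    """Mean accuracy (with s.e. bars) against subsampled sample size."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    g = subsample_frame.groupby("sample_size")["bc_similarity"]
    mean, sem = g.mean(), g.std() / np.sqrt(g.size())
    ax.errorbar(mean.index, mean, yerr=sem, marker="o")
    ax.set_xlabel("sample size")
    ax.set_ylabel("mean Bray-Curtis similarity")
    return ax
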