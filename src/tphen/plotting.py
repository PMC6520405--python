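"""Plot helpers: Kaplan–Meier step curves and accuracy box plots."""

from __future__ import annotations

import numpy as np


def km_plot(curves: dict, ax=None, title: str | None = None):
    """Step plot of one or more :class:`~tphen.survival_eval.KMCurve`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{label} (n={curve.n})")
    ax.set_xlabel("time [months]")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def accuracy_boxplot(results: dict, ax=None):
    """Box plot of per-run MCCV accuracies for several methods."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(results) + 2, 4))
    names = list(results)
    ax.boxplot([results[n].accuracies for n in names], tick_labels=names)
    ax.set_ylabel("aggregated test-fold accuracy")
    ax.tick_params(axis="x", rotation=30)
    return ax
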