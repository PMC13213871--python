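"""Plain static plots: force traces and Q-Q normality checks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sps

from .errors import DataError
from .hdf import ForceTrace

__all__ = ["plot_force_trace", "qq_plot"]


def plot_force_trace(trace: ForceTrace, path, title: str = "") -> None:
    """Reference-cycle force components vs cycle fraction, systole shaded."""
    if trace.reference is None:
        raise DataError("plot requires a reference-cycle trace; resample first")
    ref = trace.reference
    frac = np.arange(ref.shape[0]) / ref.shape[0]
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, label in enumerate(trace.labels):
        ax.plot(frac, ref[:, i], label=label.replace("_", "-"))
    ax.axvspan(0.0, trace.es_fraction, alpha=0.1, color="gray", label="systole")
    ax.axhline(0.0, lw=0.5, color="black")
    ax.set_xlabel("cardiac cycle fraction")
    ax.set_ylabel("force (N)")
    ax.set_title(title or (trace.ventricle or ""))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(values, path, title: str = "") -> None:
    """Static normal Q-Q plot of a sample."""
    arr = np.asarray(values, float).ravel()
    if arr.size < 3:
        raise DataError("Q-Q plot needs n >= 3")
    fig, ax = plt.subplots(figsize=(4, 4))
    sps.probplot(arr, dist="norm", plot=ax)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
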