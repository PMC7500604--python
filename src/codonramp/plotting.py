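"""Simple matplotlib views of LOR profiles and grouped expression curves."""

from __future__ import annotations

from .periodicity import LorProfile
from .reporter import GroupedExpressionHistogram


def plot_lor_profile(profile: LorProfile, ax=None, bases: str = "ACGT"):
    """Line plot of per-position LOR values, one line per base."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for b in bases:
        ax.plot(list(profile.positions), profile.lor[b], label=b, lw=1)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("position (anchor = 1)")
    ax.set_ylabel(r"$\log_2$(obs / background)")
    ax.legend(ncol=4, fontsize=8)
    return ax


def plot_group_cumulative(hist: GroupedExpressionHistogram, ax=None):
    """Cumulative expression-frequency curves, one per G1+C2 group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = range(len(hist.scheme.labels))
    for g in hist.nonempty_groups():
        ax.plot(x, hist.cumfreq.loc[g], marker="o", ms=3, label=f"{g}")
    ax.set_xticks(list(x))
    ax.set_xticklabels(hist.scheme.labels)
    ax.set_xlabel("expression bin")
    ax.set_ylabel("cumulative frequency")
    ax.legend(title="G1+C2", fontsize=8)
    return ax
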