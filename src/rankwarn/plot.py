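"""Minimal plotting: ranking score against time with the threshold line."""

from __future__ import annotations

__all__ = ["plot_score_series"]


def plot_score_series(series_list, threshold=None, ax=None, title=None):
    """Plot one or many ranking-score traces; returns the axes.

    Parameters
    ----------
    series_list
        A ScoreSeries or an iterable of them.
    threshold
        Optional Threshold (or number) drawn as a horizontal line.
    """
    import matplotlib.pyplot as plt

    from .containers import ScoreSeries
    from .detection import Threshold

    if isinstance(series_list, ScoreSeries):
        series_list = [series_list]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for s in series_list:
        ax.plot(range(s.n_timepoints), s.ranking_scores, marker="o",
                label=s.subject_id)
    if threshold is not None:
        theta = threshold.theta if isinstance(threshold, Threshold) else float(threshold)
        ax.axhline(theta, color="crimson", linestyle="--",
                   label=f"threshold {theta:.3g}")
    first = next(iter(series_list))
    ax.set_xticks(range(first.n_timepoints))
    ax.set_xticklabels(first.time_labels, rotation=45, ha="right")
    ax.set_xlabel("time point")
    ax.set_ylabel("ranking score ΔS")
    if title:
        ax.set_title(title)
    ax.legend(fontsize="small")
    return ax
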