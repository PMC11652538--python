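"""Threshold calibration and pre-disease state calling.

Two modes mirror the two study designs the scoring statistic is used in:

* time-course mode — a threshold theta is calibrated from the pooled
  ranking scores of designated normal subjects (z-scored, standard-normal
  upper-alpha quantile, mapped back to the original scale); a subject's
  earliest strict exceedance of theta is the early-warning call.
* stage mode — cancer datasets averaged to one pseudo-sample per stage
  have too few reference samples for a trustworthy threshold, so the
  call is a heuristic: a drastic, continued increase of the ranking
  score after the first stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .containers import ScoreSeries

__all__ = [
    "Threshold",
    "WarningCall",
    "StageCall",
    "compute_threshold",
    "detect_warning",
    "detect_stage_transition",
]


@dataclass(frozen=True)
class Threshold:
    """Early-warning threshold on the ranking-score scale.

    ``theta = mean_normal + z_(1-alpha) * sd_normal``: the ranking score
    whose z-score (under the normal-sample score distribution) sits at
    the upper-alpha standard-normal quantile.
    """

    theta: float
    alpha: float
    n_normal_scores: int
    mean_normal: float
    sd_normal: float

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sd_normal <= 0:
            raise ValueError("sd_normal must be positive")


@dataclass(frozen=True)
class WarningCall:
    """Earliest time point whose ranking score strictly exceeds theta."""

    subject_id: str
    signal_time: object  # time label, or None when never exceeded
    signal_index: int | None
    exceeded_scores: tuple  # all (time, deltaS) pairs above theta

    @property
    def detected(self) -> bool:
        return self.signal_index is not None


@dataclass(frozen=True)
class StageCall:
    """Stage-mode call: earliest stage of a sustained drastic increase."""

    dataset_id: str
    stage_labels: tuple
    ranking_scores: np.ndarray
    called_stage: object  # stage label or None
    called_index: int | None
    rule_params: dict

    @property
    def detected(self) -> bool:
        return self.called_index is not None


def compute_threshold(normal_scores, alpha: float = 0.05) -> Threshold:
    """Calibrate theta from the ranking scores of normal samples.

    The normal scores are z-scored with their own mean and sample
    standard deviation; assuming the z-scores are standard normal, the
    value whose z-score equals the upper-alpha quantile is the
    threshold, i.e. ``theta = mean + norm.ppf(1 - alpha) * sd``.

    Parameters
    ----------
    normal_scores
        Pooled ranking scores (dS values) of all time points of all
        designated normal subjects.
    alpha
        Upper-tail mass treated as warning territory; 0.05 by default.
    """
    scores = np.asarray(normal_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("threshold calibration needs at least 2 normal scores")
    if np.isnan(scores).any():
        raise ValueError("normal scores contain NaN")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("normal scores are degenerate (zero standard deviation)")
    theta = mean + float(norm.ppf(1 - alpha)) * sd
    return Threshold(theta=theta, alpha=alpha, n_normal_scores=scores.size,
                     mean_normal=mean, sd_normal=sd)


def detect_warning(series: ScoreSeries, threshold) -> WarningCall:
    """Call the earliest time point whose ranking score exceeds theta.

    Exceedance is strict (dS > theta); a score exactly at the threshold
    is not a signal. ``threshold`` may be a :class:`Threshold` or a bare
    number.
    """
    theta = threshold.theta if isinstance(threshold, Threshold) else float(threshold)
    ds = series.ranking_scores
    above = np.flatnonzero(ds > theta)
    exceeded = tuple((series.time_labels[i], float(ds[i])) for i in above)
    if above.size == 0:
        return WarningCall(series.subject_id, None, None, exceeded)
    first = int(above[0])
    return WarningCall(series.subject_id, series.time_labels[first], first,
                       exceeded)


def detect_stage_transition(stage_labels, ranking_scores, *,
                            dataset_id: str = "dataset",
                            min_consecutive_increases: int = 2,
                            min_relative_jump: float = 1.0) -> StageCall:
    """Call a drastic, sustained ranking-score increase after the first stage.

    The rule calls the earliest stage s (never the first) at which the
    score has strictly increased for at least ``min_consecutive_increases``
    consecutive stage steps, and the cumulative rise over that run is at
    least ``min_relative_jump`` times the spread (max - min) of the
    scores before the run. This makes "drastic increase on a continuous
    basis" operational while leaving both knobs exposed; it is a
    heuristic, not a calibrated test.
    """
    labels = tuple(stage_labels)
    scores = np.asarray(ranking_scores, dtype=float)
    if len(labels) != scores.size:
        raise ValueError("stage_labels and ranking_scores lengths differ")
    if scores.size < 3:
        raise ValueError("stage-mode detection needs at least 3 stages")
    if min_consecutive_increases < 1:
        raise ValueError("min_consecutive_increases must be >= 1")
    k = min_consecutive_increases
    params = {"min_consecutive_increases": k,
              "min_relative_jump": min_relative_jump}
    for s in range(k, scores.size):
        run = scores[s - k:s + 1]
        if not np.all(np.diff(run) > 0):
            continue
        start = s - k
        prior = scores[:start + 1]
        spread = float(prior.max() - prior.min())
        rise = float(scores[s] - scores[start])
        if rise >= min_relative_jump * spread:
            return StageCall(dataset_id, labels, scores, labels[s], s, params)
    return StageCall(dataset_id, labels, scores, None, None, params)
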