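"""Rank-change scoring of single samples against a normal baseline.

The statistic works on one sample at a time. Against a baseline profile
built from normal samples it computes, per gene, the expression change
dE and the expression-*ranking* change dR, multiplies them into a local
score S_i = dE_i * dR_i, and aggregates the m largest local scores into
a per-sample score

    S = (1 / (m * N)) * sum of the top-m S_i,

with N the number of genes. For a time course the ranking score
dS^t = S^t - S^0 (S^0 at the first post-baseline time point) is the
early-warning trace: genes that both move in expression and leapfrog
many other genes in rank — the coordinated fluctuation expected of a
dynamic-network-biomarker module near a critical transition — dominate
the top-m sum and make dS^t rise sharply before the transition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import BaselineProfile, ExpressionMatrix, LocalScoreTable, ScoreSeries

__all__ = [
    "rank_expressions",
    "compute_baseline",
    "local_scores",
    "sample_score",
    "score_series",
    "normalize_by_min",
    "DEFAULT_M",
]

#: default number of top local scores aggregated into the sample score
DEFAULT_M = 50


def rank_expressions(values) -> np.ndarray:
    """Ascending fractional ranks (rank 1 = lowest; ties averaged).

    Parameters
    ----------
    values
        Per-gene expression values, length >= 2, no NaN.

    Returns
    -------
    numpy.ndarray
        Fractional ranks summing to N(N+1)/2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D vector of expression values")
    if arr.size < 2:
        raise ValueError("ranking needs at least 2 values")
    if np.isnan(arr).any():
        raise ValueError("cannot rank a vector containing NaN")
    return rankdata(arr, method="average")


def compute_baseline(normal_samples: ExpressionMatrix) -> BaselineProfile:
    """Build the per-gene baseline from normal samples.

    Baseline expression is the arithmetic mean of each gene across the
    normal samples; the baseline rank is the fractional ranking of those
    means.
    """
    if not isinstance(normal_samples, ExpressionMatrix):
        normal_samples = ExpressionMatrix(normal_samples)
    mean = normal_samples.values.mean(axis=1)
    return BaselineProfile(
        gene_ids=tuple(normal_samples.gene_ids),
        expression=mean,
        rank=rank_expressions(mean),
        n_normal=normal_samples.n_samples,
    )


def _align_sample(sample, baseline: BaselineProfile):
    """Intersect the sample's gene universe with the baseline's.

    Returns aligned (gene_ids, sample_values, baseline_expression,
    baseline_rank). A proper subset triggers a warning and re-ranking of
    the baseline on the intersection; fewer than 2 shared genes is an
    error.
    """
    if isinstance(sample, pd.Series):
        sample = sample.copy()
        sample.index = sample.index.astype(str)
        shared = [g for g in baseline.gene_ids if g in sample.index]
        if len(shared) < 2:
            raise ValueError(
                f"sample and baseline share only {len(shared)} gene(s); "
                "at least 2 are required")
        if len(shared) < len(baseline.gene_ids) or len(shared) < sample.size:
            warnings.warn(
                f"gene universes differ; intersecting to {len(shared)} shared "
                "genes and re-ranking the baseline", stacklevel=3)
            base_expr = baseline.as_series().loc[shared].to_numpy()
            base_rank = rank_expressions(base_expr)
        else:
            base_expr = baseline.expression
            base_rank = baseline.rank
        values = sample.loc[shared].to_numpy(dtype=float)
        gene_ids = tuple(shared)
    else:
        values = np.asarray(sample, dtype=float)
        if values.size != baseline.n_genes:
            raise ValueError(
                "unlabelled sample vector must match the baseline gene "
                f"universe ({baseline.n_genes} genes), got {values.size}")
        gene_ids = baseline.gene_ids
        base_expr = baseline.expression
        base_rank = baseline.rank
    if np.isnan(values).any():
        bad = [g for g, v in zip(gene_ids, values) if np.isnan(v)]
        raise ValueError(f"sample contains NaN for gene(s): {bad[:5]}")
    return gene_ids, values, base_expr, base_rank


def local_scores(sample, baseline: BaselineProfile) -> LocalScoreTable:
    """Per-gene dE, dR and local score S_i = dE_i * dR_i for one sample.

    Parameters
    ----------
    sample
        Expression vector of a single sample: a :class:`pandas.Series`
        indexed by gene id (aligned to the baseline by intersection) or a
        bare array in baseline gene order.
    baseline
        Profile from :func:`compute_baseline`.
    """
    gene_ids, values, base_expr, base_rank = _align_sample(sample, baseline)
    delta_e = values - base_expr
    delta_r = rank_expressions(values) - base_rank
    return LocalScoreTable(
        gene_ids=gene_ids,
        delta_expression=delta_e,
        delta_rank=delta_r,
        local_score=delta_e * delta_r,
    )


def _top_m_indices(scores: np.ndarray, gene_ids, m: int,
                   use_absolute: bool) -> np.ndarray:
    """Indices of the m largest (signed or absolute) scores.

    Ties at the cut are broken by gene-id lexicographic order so the
    selected *set* is deterministic; the aggregated score is unaffected
    because tied scores contribute equally.
    """
    key = np.abs(scores) if use_absolute else scores
    # sort by (-score, gene_id): np.lexsort uses the last key as primary
    order = np.lexsort((np.asarray(gene_ids, dtype=object), -key))
    return order[:m]


def sample_score(table: LocalScoreTable, m: int = DEFAULT_M, *,
                 use_absolute: bool = False) -> float:
    """Aggregate the top-m local scores into the sample score.

    Returns ``(1/(m*N)) * sum(top-m local scores)`` where N is the size
    of the gene universe. ``use_absolute`` switches the "largest score"
    criterion from signed values (the default reading) to magnitudes.
    Raises if ``m`` exceeds the number of genes — requesting more top
    genes than exist is treated as a configuration error, not clamped.
    """
    n = table.n_genes
    if n == 0:
        raise ValueError("empty local-score table")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"m={m} exceeds the number of genes N={n}")
    idx = _top_m_indices(table.local_score, table.gene_ids, m, use_absolute)
    return float(table.local_score[idx].sum() / (m * n))


def score_series(course: ExpressionMatrix, baseline: BaselineProfile,
                 m: int = DEFAULT_M, *, subject_id: str = "subject",
                 time_labels=None, use_absolute: bool = False) -> ScoreSeries:
    """Score every time point of one subject's course against a baseline.

    Parameters
    ----------
    course
        Expression matrix whose columns are the subject's time points in
        chronological order (column order is taken as time order unless
        ``time_labels`` overrides the labels).
    baseline
        Normal-sample baseline profile.
    m
        Number of top local scores aggregated per time point.

    Returns
    -------
    ScoreSeries
        Raw scores S^t and ranking scores dS^t = S^t - S^0.
    """
    if not isinstance(course, ExpressionMatrix):
        course = ExpressionMatrix(course)
    labels = tuple(course.sample_ids) if time_labels is None else tuple(time_labels)
    if len(labels) != course.n_samples:
        raise ValueError("time_labels length must match the number of columns")
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate time labels: {labels}")
    raw = np.empty(course.n_samples)
    for j, col in enumerate(course.sample_ids):
        table = local_scores(course.sample(col), baseline)
        raw[j] = sample_score(table, m, use_absolute=use_absolute)
    return ScoreSeries(subject_id=str(subject_id), time_labels=labels,
                       raw_scores=raw, m_used=m)


def normalize_by_min(values) -> np.ndarray:
    """Divide each value by the minimum of the vector (minimum maps to 1).

    Used to put gene expression values and ranking scores on a common
    footing when comparing their dynamic ranges across a gene panel.
    Requires a strictly positive minimum.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("cannot normalize an empty vector")
    lo = arr.min()
    if not lo > 0:
        raise ValueError(
            f"min-normalization requires a strictly positive minimum, got {lo}")
    return arr / lo
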