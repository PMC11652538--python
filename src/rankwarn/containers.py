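"""Core data containers for expression matrices, baselines and score series.

The universal input is a genes x samples real matrix. All downstream
quantities (baseline profile, per-gene local scores, per-time-point score
series) are small typed records built from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BaselineProfile",
    "LocalScoreTable",
    "ScoreSeries",
]


class ExpressionMatrix:
    """A genes x samples expression matrix with identifier bookkeeping.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose index
    holds gene identifiers and whose columns hold sample identifiers.
    Values are real numbers on an arbitrary but internally consistent
    scale (e.g. log2 microarray summaries); missing values are rejected,
    since the scoring statistic has no imputation step.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns, or
        anything :class:`pandas.DataFrame` accepts together with
        ``gene_ids`` / ``sample_ids``.
    """

    def __init__(self, data, gene_ids=None, sample_ids=None):
        if isinstance(data, pd.DataFrame) and gene_ids is None and sample_ids is None:
            frame = data.copy()
        else:
            frame = pd.DataFrame(np.asarray(data, dtype=float),
                                 index=gene_ids, columns=sample_ids)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.shape[0] < 2:
            raise ValueError("expression matrix needs at least 2 genes, "
                             f"got {frame.shape[0]}")
        if frame.shape[1] < 1:
            raise ValueError("expression matrix needs at least 1 sample")
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = frame.to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = frame.index[np.isnan(values).any(axis=1)].tolist()
            raise ValueError("missing values are not allowed; offending "
                             f"gene(s): {bad[:5]}")
        self._frame = frame.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self._frame.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Expression vector of one sample, indexed by gene id."""
        return self._frame[str(sample_id)]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self._frame[[str(s) for s in sample_ids]])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ExpressionMatrix({self.n_genes} genes x "
                f"{self.n_samples} samples)")

    def __eq__(self, other) -> bool:
        return (isinstance(other, ExpressionMatrix)
                and self._frame.equals(other._frame))


@dataclass(frozen=True)
class BaselineProfile:
    """Per-gene baseline expression and baseline rank from normal samples.

    ``expression[i]`` is the arithmetic mean of gene i over the ``n_normal``
    normal samples; ``rank`` holds ascending fractional ranks of the
    baseline expression (rank 1 = lowest, ties averaged).
    """

    gene_ids: tuple
    expression: np.ndarray
    rank: np.ndarray
    n_normal: int

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "expression",
                           np.asarray(self.expression, dtype=float))
        object.__setattr__(self, "rank", np.asarray(self.rank, dtype=float))
        n = len(self.gene_ids)
        if not (len(self.expression) == len(self.rank) == n):
            raise ValueError("gene_ids, expression and rank lengths differ")
        if self.n_normal < 1:
            raise ValueError("baseline requires at least one normal sample")
        # fractional-rank sanity: sum must be N(N+1)/2
        if not np.isclose(self.rank.sum(), n * (n + 1) / 2):
            raise ValueError("baseline ranks are not a valid fractional ranking")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.expression, index=list(self.gene_ids))


@dataclass(frozen=True)
class LocalScoreTable:
    """Per-gene expression change, rank change and their product.

    For one sample scored against a baseline: ``delta_expression`` is
    E_i - E_i(baseline), ``delta_rank`` is R_i - R_i(baseline), and
    ``local_score`` is the elementwise product of the two — the per-gene
    contribution to the sample score.
    """

    gene_ids: tuple
    delta_expression: np.ndarray
    delta_rank: np.ndarray
    local_score: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        for name in ("delta_expression", "delta_rank", "local_score"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = len(self.gene_ids)
        if not (len(self.delta_expression) == len(self.delta_rank)
                == len(self.local_score) == n):
            raise ValueError("column lengths differ")
        if not np.allclose(self.local_score,
                           self.delta_expression * self.delta_rank):
            raise ValueError("local_score must equal delta_expression * delta_rank")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_expression": self.delta_expression,
             "delta_rank": self.delta_rank,
             "local_score": self.local_score},
            index=list(self.gene_ids))


@dataclass(frozen=True)
class ScoreSeries:
    """Per-time-point scores for one subject.

    ``raw_scores[t]`` is the aggregated top-m score S^t; ``ranking_scores``
    is S^t minus the score at the first post-baseline time point, so its
    first entry is exactly zero.
    """

    subject_id: str
    time_labels: tuple
    raw_scores: np.ndarray
    m_used: int
    ranking_scores: np.ndarray = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        raw = np.asarray(self.raw_scores, dtype=float)
        if len(raw) != len(self.time_labels):
            raise ValueError("raw_scores and time_labels lengths differ")
        if len(raw) == 0:
            raise ValueError("score series needs at least one time point")
        object.__setattr__(self, "raw_scores", raw)
        object.__setattr__(self, "ranking_scores", raw - raw[0])

    @property
    def n_timepoints(self) -> int:
        return len(self.time_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject_id,
            "time": list(self.time_labels),
            "S": self.raw_scores,
            "deltaS": self.ranking_scores,
        })
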