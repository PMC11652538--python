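"""Candidate signaling-gene selection at the warning time point.

At the time point where the early-warning signal fires, the genes with
the largest local scores are the ones driving the ranking-score jump;
the top fraction (5% by default) are kept as candidate signaling genes,
and candidates recurring across enough subjects form the common set
handed off to downstream functional analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .containers import LocalScoreTable
from .scoring import _top_m_indices

__all__ = ["GeneSet", "select_top_fraction", "common_genes", "membership_counts"]


@dataclass(frozen=True)
class GeneSet:
    """A set of gene ids with provenance (subject/time or dataset/stage)."""

    gene_ids: frozenset
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "gene_ids",
                           frozenset(str(g) for g in self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene) -> bool:
        return str(gene) in self.gene_ids

    def __iter__(self):
        return iter(sorted(self.gene_ids))


def select_top_fraction(table: LocalScoreTable, fraction: float = 0.05, *,
                        use_absolute: bool = False,
                        source: str = "") -> GeneSet:
    """The ceil(fraction * N) genes with the largest local scores.

    The ceiling guarantees a non-empty selection for any positive
    fraction; ties at the cut are broken by gene id so the set is
    deterministic. ``use_absolute`` mirrors the option in the sample
    score.
    """
    if table.n_genes == 0:
        raise ValueError("empty local-score table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = math.ceil(fraction * table.n_genes)
    idx = _top_m_indices(table.local_score, table.gene_ids, k, use_absolute)
    return GeneSet(frozenset(np.asarray(table.gene_ids, dtype=object)[idx]),
                   source=source)


def membership_counts(sets) -> Counter:
    """How many input sets each gene appears in."""
    counts: Counter = Counter()
    for gs in sets:
        counts.update(gs.gene_ids if isinstance(gs, GeneSet) else set(gs))
    return counts


def common_genes(sets, min_subjects: int = 5) -> GeneSet:
    """Genes present in at least ``min_subjects`` of the input sets.

    The default of 5 encodes "more than four subjects". With
    ``min_subjects=1`` this is the union of the sets.
    """
    sets = list(sets)
    if len(sets) < 1:
        raise ValueError("need at least one gene set")
    if min_subjects < 1:
        raise ValueError("min_subjects must be >= 1")
    counts = membership_counts(sets)
    kept = frozenset(g for g, c in counts.items() if c >= min_subjects)
    return GeneSet(kept, source=f"common(min_subjects={min_subjects})")
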