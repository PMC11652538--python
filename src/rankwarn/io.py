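"""Delimited-text readers/writers, probe collapsing and stage averaging.

Matrix dialect: UTF-8 delimited text, gene ids in the first column,
sample ids in the header row; the delimiter is auto-detected between tab
and comma and can be forced. Metadata is a TSV with columns
``sample_id, subject_id, time, group`` where group is one of
``baseline`` (reference samples), ``case`` (time courses to score) and
``normal`` (time courses pooled for threshold calibration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, ScoreSeries

__all__ = [
    "StudyMetadata",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "collapse_probes",
    "average_by_stage",
    "write_score_series",
    "read_probe_map",
    "sort_time_labels",
]

log = logging.getLogger("rankwarn")

GROUPS = ("baseline", "case", "normal")


@dataclass(frozen=True)
class StudyMetadata:
    """Sample annotations: subject, time label and group per sample."""

    table: pd.DataFrame  # columns: sample_id, subject_id, time, group
    time_order: tuple | None = None  # explicit ordering for non-numeric labels

    def __post_init__(self):
        required = {"sample_id", "subject_id", "time", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata is missing column(s): {sorted(missing)}")
        tab = self.table.copy()
        for col in ("sample_id", "subject_id", "time", "group"):
            tab[col] = tab[col].astype(str)
        if tab["sample_id"].duplicated().any():
            dups = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id in metadata: {dups[:5]}")
        bad = sorted(set(tab["group"]) - set(GROUPS))
        if bad:
            raise ValueError(f"unknown group label(s) {bad}; expected {GROUPS}")
        object.__setattr__(self, "table", tab)
        if self.time_order is not None:
            object.__setattr__(self, "time_order",
                               tuple(str(t) for t in self.time_order))

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def subjects_in_group(self, group: str) -> list[str]:
        return sorted(self.table.loc[self.table["group"] == group,
                                     "subject_id"].unique())

    def course_of(self, subject_id: str, group: str) -> pd.DataFrame:
        """Ordered (sample_id, time) rows of one subject's time course."""
        sub = self.table[(self.table["subject_id"] == str(subject_id))
                         & (self.table["group"] == group)]
        times = sort_time_labels(sub["time"].tolist(), self.time_order)
        order = {t: i for i, t in enumerate(times)}
        return sub.assign(_k=sub["time"].map(order)).sort_values("_k").drop(
            columns="_k")

    def baseline_samples(self, subject_id: str | None = None) -> list[str]:
        sub = self.table[self.table["group"] == "baseline"]
        if subject_id is not None:
            sub = sub[sub["subject_id"] == str(subject_id)]
        return sub["sample_id"].tolist()


def sort_time_labels(labels, explicit_order=None) -> list[str]:
    """Sort time labels numerically when possible, else by explicit order.

    Stage labels such as ``I, IA, IB, II, ...`` are not numerically
    parseable and need the explicit ordering list.
    """
    labels = [str(t) for t in labels]
    seen = list(dict.fromkeys(labels))
    if explicit_order is not None:
        order = [str(t) for t in explicit_order]
        unknown = [t for t in seen if t not in order]
        if unknown:
            raise ValueError(f"time label(s) not in explicit order: {unknown}")
        return [t for t in order if t in seen]
    try:
        return sorted(seen, key=float)
    except ValueError as exc:
        raise ValueError(
            "time labels are not numeric; provide an explicit ordering "
            f"({exc})") from None


def _detect_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_expression_matrix(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text."""
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path,
                            delimiter: str = "\t") -> None:
    """Write a matrix as delimited text with 12 significant digits."""
    frame = matrix.frame
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id" + delimiter + delimiter.join(frame.columns) + "\n")
        for gene, row in zip(frame.index, frame.to_numpy()):
            vals = delimiter.join(format(v, ".12g") for v in row)
            fh.write(f"{gene}{delimiter}{vals}\n")


def read_metadata(path, time_order=None) -> StudyMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return StudyMetadata(table=table, time_order=time_order)


def read_probe_map(path) -> pd.DataFrame:
    """Two-column (probe_id, gene_id) TSV; extra columns ignored."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(table.columns)
    if "probe_id" not in cols or "gene_id" not in cols:
        table = table.iloc[:, :2]
        table.columns = ["probe_id", "gene_id"]
    return table[["probe_id", "gene_id"]]


def collapse_probes(probe_matrix: ExpressionMatrix,
                    probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Average probe rows mapping to the same gene; drop unmapped probes.

    ``probe_map`` needs columns ``probe_id`` and ``gene_id``. Probes with
    no gene assignment are discarded (their count is logged), matching
    standard array preprocessing where probes without a gene symbol are
    dropped.
    """
    mapping = (probe_map.dropna(subset=["gene_id"])
               .astype(str).set_index("probe_id")["gene_id"])
    frame = probe_matrix.frame
    mapped = frame.index.intersection(mapping.index)
    n_dropped = frame.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise ValueError("no probe in the matrix is covered by the probe map")
    if n_dropped:
        log.warning("dropping %d unmapped probe(s) of %d", n_dropped,
                    frame.shape[0])
    collapsed = (frame.loc[mapped]
                 .groupby(mapping.loc[mapped].to_numpy(), sort=True)
                 .mean())
    return ExpressionMatrix(collapsed)


def average_by_stage(matrix: ExpressionMatrix, metadata: StudyMetadata,
                     stage_order=None) -> ExpressionMatrix:
    """One pseudo-sample per stage: per-gene mean over that stage's samples.

    Case samples are averaged per stage (stage = the ``time`` label of
    ``case`` rows), producing a single-sample-per-stage course ordered by
    ``stage_order`` (or the metadata's time ordering). Baseline
    (tumor-adjacent) samples are left out; average them separately as
    the reference pool.
    """
    case = metadata.table[metadata.table["group"] == "case"]
    if case.empty:
        raise ValueError("metadata has no case samples to average")
    order = sort_time_labels(case["time"].tolist(),
                             stage_order or metadata.time_order)
    frame = matrix.frame
    cols = {}
    for stage in order:
        samples = case.loc[case["time"] == stage, "sample_id"].tolist()
        missing = [s for s in samples if s not in frame.columns]
        if missing:
            raise ValueError(f"stage {stage!r}: sample(s) absent from the "
                             f"matrix: {missing[:5]}")
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = frame[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols, index=frame.index))


def write_score_series(series_list, tsv_path=None, json_path=None) -> pd.DataFrame:
    """Write one or many ScoreSeries as a tidy TSV and/or JSON report."""
    if isinstance(series_list, ScoreSeries):
        series_list = [series_list]
    tidy = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    if tsv_path is not None:
        tidy.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")
    if json_path is not None:
        payload = [
            {"subject": s.subject_id,
             "time_labels": list(s.time_labels),
             "S": [float(v) for v in s.raw_scores],
             "deltaS": [float(v) for v in s.ranking_scores],
             "m": s.m_used}
            for s in series_list
        ]
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
    return tidy
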