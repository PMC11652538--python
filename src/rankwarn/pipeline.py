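"""End-to-end pipeline: load, score, calibrate, call, select genes, write.

Time-course mode reproduces the challenge-study design: every subject is
scored against a baseline (its own baseline samples, or a pooled
reference), the threshold is calibrated from the pooled ranking scores
of the ``normal`` subjects, warnings are called for the ``case``
subjects, and candidate signaling genes are selected at each subject's
signal time point. Stage mode averages case samples into one
pseudo-sample per stage against the pooled baseline and applies the
sustained-increase rule instead of a calibrated threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as rio
from .containers import ExpressionMatrix, ScoreSeries
from .detection import (compute_threshold, detect_stage_transition,
                        detect_warning)
from .genes import common_genes, membership_counts, select_top_fraction
from .scoring import DEFAULT_M, compute_baseline, local_scores, score_series

__all__ = ["PipelineConfig", "run_pipeline", "score_subjects"]

log = logging.getLogger("rankwarn")


@dataclass
class PipelineConfig:
    """Everything one run needs; all knobs mirror the method's parameters."""

    matrix_path: str
    metadata_path: str
    out_dir: str
    mode: str = "course"  # course | stage
    baseline_mode: str = "per-subject"  # per-subject | pooled
    m: int = DEFAULT_M
    alpha: float = 0.05
    fraction: float = 0.05
    min_subjects: int = 5
    use_absolute: bool = False
    log2_transform: bool = False
    probe_map_path: str | None = None
    time_order: tuple | None = None
    truth_path: str | None = None
    delimiter: str | None = None
    min_consecutive_increases: int = 2
    min_relative_jump: float = 1.0

    def __post_init__(self):
        if self.mode not in ("course", "stage"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.baseline_mode not in ("per-subject", "pooled"):
            raise ValueError(f"unknown baseline_mode: {self.baseline_mode!r}")


def _load_matrix(cfg: PipelineConfig) -> ExpressionMatrix:
    matrix = rio.read_expression_matrix(cfg.matrix_path, cfg.delimiter)
    if cfg.probe_map_path:
        probe_map = rio.read_probe_map(cfg.probe_map_path)
        matrix = rio.collapse_probes(matrix, probe_map)
    if cfg.log2_transform:
        vals = matrix.values
        if (vals < 0).any():
            raise ValueError("log2(x+1) transform requires non-negative values")
        matrix = ExpressionMatrix(np.log2(vals + 1.0),
                                  gene_ids=matrix.gene_ids,
                                  sample_ids=matrix.sample_ids)
    return matrix


def _baseline_for(matrix: ExpressionMatrix, meta: rio.StudyMetadata,
                  subject: str, mode: str):
    samples = (meta.baseline_samples(subject) if mode == "per-subject"
               else meta.baseline_samples())
    if not samples:
        raise ValueError(
            f"no baseline samples for subject {subject!r} "
            f"(baseline_mode={mode!r})")
    return compute_baseline(matrix.subset_samples(samples))


def score_subjects(matrix: ExpressionMatrix, meta: rio.StudyMetadata,
                   group: str, *, baseline_mode: str = "per-subject",
                   m: int = DEFAULT_M,
                   use_absolute: bool = False) -> dict[str, ScoreSeries]:
    """Score every subject of one metadata group against its baseline."""
    out: dict[str, ScoreSeries] = {}
    for subject in meta.subjects_in_group(group):
        course_rows = meta.course_of(subject, group)
        if course_rows.empty:
            continue
        baseline = _baseline_for(matrix, meta, subject, baseline_mode)
        course = matrix.subset_samples(course_rows["sample_id"].tolist())
        out[subject] = score_series(
            course, baseline, m, subject_id=subject,
            time_labels=tuple(course_rows["time"]),
            use_absolute=use_absolute)
    return out


def _signal_gene_sets(matrix, meta, calls, series_map, cfg):
    """Top-fraction local-score genes at each detected subject's signal time."""
    sets = []
    for subject, call in sorted(calls.items()):
        if not call.detected:
            continue
        course_rows = meta.course_of(subject, "case")
        sample_id = course_rows.iloc[call.signal_index]["sample_id"]
        baseline = _baseline_for(matrix, meta, subject, cfg.baseline_mode)
        table = local_scores(matrix.sample(sample_id), baseline)
        sets.append(select_top_fraction(
            table, cfg.fraction, use_absolute=cfg.use_absolute,
            source=f"{subject}@{call.signal_time}"))
    return sets


def _dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report files.

    Returns the in-memory report dict; writes, under ``out_dir``:
    ``scores.tsv``/``scores.json`` (per-subject series), ``threshold.json``,
    ``calls.json``, ``signaling_genes.txt``, ``gene_membership.tsv`` and
    ``report.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(cfg)
    meta = rio.read_metadata(cfg.metadata_path, cfg.time_order)
    log.info("loaded %d genes x %d samples; parameters m=%d alpha=%g "
             "fraction=%g min_subjects=%d baseline_mode=%s",
             matrix.n_genes, matrix.n_samples, cfg.m, cfg.alpha,
             cfg.fraction, cfg.min_subjects, cfg.baseline_mode)

    report: dict = {"parameters": {
        "mode": cfg.mode, "baseline_mode": cfg.baseline_mode, "m": cfg.m,
        "alpha": cfg.alpha, "fraction": cfg.fraction,
        "min_subjects": cfg.min_subjects, "use_absolute": cfg.use_absolute}}

    if cfg.mode == "stage":
        baseline = compute_baseline(
            matrix.subset_samples(meta.baseline_samples()))
        staged = rio.average_by_stage(matrix, meta)
        series = score_series(staged, baseline, cfg.m, subject_id="stages",
                              use_absolute=cfg.use_absolute)
        call = detect_stage_transition(
            series.time_labels, series.ranking_scores,
            min_consecutive_increases=cfg.min_consecutive_increases,
            min_relative_jump=cfg.min_relative_jump)
        rio.write_score_series(series, out / "scores.tsv", out / "scores.json")
        gene_lines = []
        if call.detected:
            table = local_scores(staged.sample(call.called_stage), baseline)
            gs = select_top_fraction(table, cfg.fraction,
                                     use_absolute=cfg.use_absolute,
                                     source=f"stage {call.called_stage}")
            gene_lines = sorted(gs.gene_ids)
        (out / "signaling_genes.txt").write_text(
            "\n".join(gene_lines) + ("\n" if gene_lines else ""))
        report["stage_call"] = {
            "called_stage": call.called_stage,
            "called_index": call.called_index,
            "ranking_scores": [float(v) for v in call.ranking_scores],
            "stage_labels": list(call.stage_labels),
            "rule_params": call.rule_params,
            "n_signaling_genes": len(gene_lines)}
        _dump(report["stage_call"], out / "calls.json")
        _dump(report, out / "report.json")
        return report

    # ---- time-course mode ----
    case_series = score_subjects(matrix, meta, "case",
                                 baseline_mode=cfg.baseline_mode, m=cfg.m,
                                 use_absolute=cfg.use_absolute)
    normal_series = score_subjects(matrix, meta, "normal",
                                   baseline_mode=cfg.baseline_mode, m=cfg.m,
                                   use_absolute=cfg.use_absolute)
    all_series = list(case_series.values()) + list(normal_series.values())
    if not all_series:
        raise ValueError("no case or normal subjects found in metadata")
    rio.write_score_series(all_series, out / "scores.tsv", out / "scores.json")

    threshold = None
    calls: dict = {}
    if normal_series:
        pool = np.concatenate(
            [s.ranking_scores for s in normal_series.values()])
        threshold = compute_threshold(pool, cfg.alpha)
        _dump({"theta": threshold.theta, "alpha": threshold.alpha,
               "n_normal_scores": threshold.n_normal_scores,
               "mean_normal": threshold.mean_normal,
               "sd_normal": threshold.sd_normal}, out / "threshold.json")
        calls = {subj: detect_warning(s, threshold)
                 for subj, s in {**case_series, **normal_series}.items()}
        report["threshold"] = {"theta": threshold.theta,
                               "alpha": threshold.alpha,
                               "n_normal_scores": threshold.n_normal_scores}
    else:
        log.warning("no normal subjects: threshold not calibrated, "
                    "no warnings called")

    report["calls"] = {
        subj: {"signal_time": call.signal_time,
               "signal_index": call.signal_index,
               "group": "case" if subj in case_series else "normal",
               "exceeded": [[t, v] for t, v in call.exceeded_scores]}
        for subj, call in sorted(calls.items())}
    _dump(report["calls"], out / "calls.json")

    case_calls = {s: c for s, c in calls.items() if s in case_series}
    gene_sets = _signal_gene_sets(matrix, meta, case_calls, case_series, cfg)
    counts = membership_counts(gene_sets)
    common = common_genes(gene_sets, cfg.min_subjects) if gene_sets else None
    common_ids = sorted(common.gene_ids) if common else []
    (out / "signaling_genes.txt").write_text(
        "\n".join(common_ids) + ("\n" if common_ids else ""))
    with open(out / "gene_membership.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_id\tn_subjects\n")
        for gene, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{gene}\t{c}\n")
    report["signaling_genes"] = {
        "n_detected_subjects": len(gene_sets),
        "n_common": len(common_ids),
        "common": common_ids}

    if cfg.truth_path:
        with open(cfg.truth_path, "r", encoding="utf-8") as fh:
            truth = json.load(fh)
        comparison = {}
        for subj, call in sorted(case_calls.items()):
            t_true = truth.get("transition_index")
            comparison[subj] = {
                "signal_index": call.signal_index,
                "truth_transition_index": t_true,
                "offset": (None if call.signal_index is None or t_true is None
                           else call.signal_index - t_true)}
        report["truth_comparison"] = comparison
        _dump(comparison, out / "truth_comparison.json")

    _dump(report, out / "report.json")
    return report
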