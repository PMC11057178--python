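"""Assessment orchestration and report assembly.

Runs parse → clean → match → metrics for a directory of submissions and
assembles per-model metric rows (band counts, mean rank points ± SE,
F-max ± SE, threshold, calls/proband), per-entry detection counts across
models, the pairwise top-k concordance matrix, and the stratified
incomplete-vs-complete family comparison with its paired t-test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from . import metrics as M
from .families import load_families
from .matching import MatchOutcome, resolve_submission
from .submission import ModelSubmission, ValidationReport, clean_submission, parse_submission
from .variants import AnswerKey, DEFAULT_SCHEDULE, RankPointsSchedule, load_answer_key

__all__ = ["AssessConfig", "MetricReport", "AssessmentRun", "assess", "rank_models", "compute_metric_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssessConfig:
    bootstrap_replicates: int = 1000
    seed: int = 0
    top_k: int = 5
    partial_credit: bool = False
    schedule: RankPointsSchedule = DEFAULT_SCHEDULE


@dataclass(frozen=True)
class MetricReport:
    """One model's assessment row (band counts and both metrics with SEs)."""

    team_id: str
    model_id: str
    band_counts: tuple[int, ...]
    mean_rank_points: float
    mean_rank_points_se: float
    fmax: float
    fmax_se: float
    fmax_threshold: Optional[float]
    mean_calls_per_proband: float
    sd_calls_per_proband: float

    @property
    def name(self) -> str:
        return f"{self.team_id}/{self.model_id}"


def compute_metric_report(
    sub: ModelSubmission,
    key: AnswerKey,
    config: AssessConfig = AssessConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[MetricReport, dict[str, MatchOutcome]]:
    """Full metric row for one cleaned submission."""
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.Generator) else None
    rng_mrp, rng_fmax = (
        (np.random.default_rng(s) for s in ss.spawn(2)) if ss is not None else (seed, seed)
    )
    outcomes = resolve_submission(sub, key, partial_credit=config.partial_credit)[1]
    mrp = M.mean_rank_points(outcomes, config.schedule)
    mrp_se = M.bootstrap_se_mean_rank_points(
        outcomes, B=config.bootstrap_replicates, seed=rng_mrp, schedule=config.schedule
    )
    fres = M.fmax_sweep(sub, key, partial_credit=config.partial_credit)
    fmax_se = (
        float("nan")
        if fres.is_na
        else M.bootstrap_se_fmax(
            sub, key, B=config.bootstrap_replicates, seed=rng_fmax,
            partial_credit=config.partial_credit,
        )
    )
    report = MetricReport(
        team_id=sub.team_id,
        model_id=sub.model_id,
        band_counts=M.rank_band_counts(outcomes),
        mean_rank_points=mrp,
        mean_rank_points_se=mrp_se,
        fmax=fres.fmax,
        fmax_se=fmax_se,
        fmax_threshold=fres.threshold,
        mean_calls_per_proband=fres.mean_calls_per_proband,
        sd_calls_per_proband=fres.sd_calls_per_proband,
    )
    return report, outcomes


def rank_models(reports: Sequence[MetricReport]) -> tuple[list[int], list[int]]:
    """Dual 1-based rankings: by mean rank points and by F-max (descending).

    Tied values share the same rank and the next distinct value's rank counts
    the tied block (competition ranking); NA F-max rows rank after every
    numeric value.
    """
    if not reports:
        raise ValueError("rank_models requires at least one report")

    def _rank(values: list[float]) -> list[int]:
        arr = np.array([-math.inf if math.isnan(v) else v for v in values])
        return [int(r) for r in _scipy_stats.rankdata(-arr, method="min")]

    return _rank([r.mean_rank_points for r in reports]), _rank([r.fmax for r in reports])


@dataclass
class AssessmentRun:
    """Everything one assessment produced, ordered as reported."""

    config: AssessConfig
    reports: list[MetricReport]
    rank_by_points: list[int]
    rank_by_fmax: list[int]
    outcomes: dict[str, dict[str, MatchOutcome]]  # model name -> proband -> outcome
    detection: dict[str, tuple[int, ...]]  # proband -> counts across models
    concordance: pd.DataFrame
    stratified: dict[str, tuple[float, float]]  # model name -> (incomplete, complete)
    paired_t: Optional[tuple[float, float]]
    validation: dict[str, ValidationReport] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Model-per-row metric table (one-decimal rank points, as reported)."""
        rows = []
        for rep, rp, rf in zip(self.reports, self.rank_by_points, self.rank_by_fmax):
            rows.append(
                {
                    "team": rep.team_id,
                    "model": rep.model_id,
                    "rank1": rep.band_counts[0],
                    "rank1_5": rep.band_counts[1],
                    "rank1_10": rep.band_counts[2],
                    "rank1_20": rep.band_counts[3],
                    "rank1_50": rep.band_counts[4],
                    "rank1_100": rep.band_counts[5],
                    "mean_rank_points": round(rep.mean_rank_points, 1),
                    "mean_rank_points_se": round(rep.mean_rank_points_se, 1),
                    "fmax": "NA" if math.isnan(rep.fmax) else round(rep.fmax, 2),
                    "fmax_se": "NA" if math.isnan(rep.fmax_se) else round(rep.fmax_se, 2),
                    "fmax_threshold": "NA" if rep.fmax_threshold is None else round(rep.fmax_threshold, 2),
                    "mean_calls": "NA" if math.isnan(rep.mean_calls_per_proband) else round(rep.mean_calls_per_proband, 2),
                    "sd_calls": "NA" if math.isnan(rep.sd_calls_per_proband) else round(rep.sd_calls_per_proband, 2),
                    "rank_by_points": rp,
                    "rank_by_fmax": rf,
                }
            )
        return pd.DataFrame(rows)

    def detection_table(self) -> pd.DataFrame:
        rows = [
            {"proband": pid, "rank1": c[0], "rank1_5": c[1], "rank1_10": c[2],
             "rank1_20": c[3], "rank1_50": c[4], "rank1_100": c[5]}
            for pid, c in self.detection.items()
        ]
        return pd.DataFrame(rows)


def _sort_reports(
    reports: list[MetricReport],
) -> list[MetricReport]:
    # descending mean rank points; ties broken by descending F-max (NA last)
    def sort_key(rep: MetricReport):
        f = -math.inf if math.isnan(rep.fmax) else rep.fmax
        return (-rep.mean_rank_points, -f, rep.team_id, rep.model_id)

    return sorted(reports, key=sort_key)


def assess(
    answer_key_path: str | Path,
    ped_path: str | Path,
    hpo_path: str | Path | None,
    submissions_dir: str | Path,
    out_dir: str | Path | None = None,
    config: AssessConfig = AssessConfig(),
) -> AssessmentRun:
    """Assess every submission TSV in a directory against one answer key.

    Individual unparseable submissions are reported and skipped; an unreadable
    answer key or an empty submissions directory is fatal.
    """
    key = load_answer_key(answer_key_path)
    families = load_families(ped_path, hpo_path)
    subs_dir = Path(submissions_dir)
    paths = sorted(subs_dir.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no submission TSVs found in {subs_dir}")

    subs: dict[str, ModelSubmission] = {}
    validation: dict[str, ValidationReport] = {}
    for path in paths:
        try:
            parsed, parse_report = parse_submission(path)
        except OSError as exc:
            logger.error("skipping unreadable submission %s: %s", path, exc)
            continue
        cleaned, clean_report = clean_submission(parsed)
        combined = ValidationReport(
            errors=parse_report.errors + clean_report.errors,
            warnings=parse_report.warnings + clean_report.warnings,
            n_read=parse_report.n_read,
            n_kept=clean_report.n_kept,
            dropped={**parse_report.dropped, **clean_report.dropped},
        )
        for issue in combined.errors:
            logger.warning("%s line %d [%s] %s", path.name, issue.line, issue.code, issue.message)
        subs[cleaned.name] = cleaned
        validation[cleaned.name] = combined

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(len(subs))
    raw_reports: dict[str, MetricReport] = {}
    outcomes: dict[str, dict[str, MatchOutcome]] = {}
    for (name, sub), child in zip(subs.items(), child_seeds):
        rep, outs = compute_metric_report(sub, key, config, seed=np.random.default_rng(child))
        raw_reports[name] = rep
        outcomes[name] = outs

    ordered = _sort_reports(list(raw_reports.values()))
    rank_pts, rank_f = rank_models(ordered)

    detection = {
        e.proband_id: M.detection_counts(list(subs.values()), e, partial_credit=config.partial_credit)
        for e in key.solved_entries
    }

    names = [r.name for r in ordered]
    conc = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            c = M.concordance(subs[a], subs[b], k=config.top_k)
            conc.iloc[i, j] = conc.iloc[j, i] = c

    stratified = {
        name: M.stratified_mean_rank_points(outcomes[name], families, config.schedule)
        for name in names
    }
    strat_pairs = [
        (inc, comp)
        for inc, comp in stratified.values()
        if not (math.isnan(inc) or math.isnan(comp))
    ]
    paired_t: Optional[tuple[float, float]] = None
    if len(strat_pairs) >= 2:
        paired_t = M.paired_t_test([p[0] for p in strat_pairs], [p[1] for p in strat_pairs])

    run = AssessmentRun(
        config=config,
        reports=ordered,
        rank_by_points=rank_pts,
        rank_by_fmax=rank_f,
        outcomes=outcomes,
        detection=detection,
        concordance=conc,
        stratified=stratified,
        paired_t=paired_t,
        validation=validation,
    )
    if out_dir is not None:
        _write_run(run, Path(out_dir), subs, key)
    return run


def _write_run(run: AssessmentRun, out: Path, subs: dict, key: AnswerKey) -> None:
    out.mkdir(parents=True, exist_ok=True)
    run.to_table().to_csv(out / "model_metrics.tsv", sep="\t", index=False)
    run.detection_table().to_csv(out / "detection_counts.tsv", sep="\t", index=False)
    run.concordance.round(4).to_csv(out / "concordance.tsv", sep="\t")
    strat_rows = [
        {"model": name, "incomplete": round(v[0], 2), "complete": round(v[1], 2)}
        for name, v in run.stratified.items()
    ]
    pd.DataFrame(strat_rows).to_csv(out / "stratified.tsv", sep="\t", index=False)
    bundle = {
        "config": {
            "bootstrap_replicates": run.config.bootstrap_replicates,
            "seed": run.config.seed,
            "top_k": run.config.top_k,
            "partial_credit": run.config.partial_credit,
        },
        "models": [dataclasses.asdict(r) for r in run.reports],
        "rank_by_points": run.rank_by_points,
        "rank_by_fmax": run.rank_by_fmax,
        "paired_t_test": run.paired_t,
        "fmax_curves": {
            name: [list(point) for point in M.fmax_sweep(subs[name], key).curve]
            for name in subs
        },
    }
    with open(out / "run.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
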