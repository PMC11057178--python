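"""Assessment metrics: mean rank points, F-max, bootstrap SEs, and secondary summaries.

Two headline metrics judge a model over the solved probands:

* **Mean rank points** — the mean, over all solved answer-key entries, of a
  band-weighted point award for the rank of the first correct prediction
  (top 5 → 100, top 10 → 50, top 20 → 25, top 50 → 10, top 100 → 5, miss → 0).
  The denominator is always the number of solved entries; a proband the model
  skipped counts as a miss.

* **F-max** — the maximum, over all unique submitted EPCR values, of the
  harmonic mean of precision and recall of causal-variant calls among the
  solved probands.  A call set at threshold t is every solved-proband record
  with EPCR ≥ t; a true positive is a solved entry whose (unique, post
  equivalence-resolution) matching record is in the call set.  Recall counts
  answer-key entries, not variants: a biallelic answer is one positive.

Standard errors for both metrics are bootstrapped by resampling solved
probands with replacement and recomputing the statistic per replicate
(F-max is re-swept on each replicate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .families import Completeness, FamilyInfo
from .matching import MatchOutcome, _score_entry, resolve_submission
from .submission import ModelSubmission
from .variants import AnswerKey, AnswerKeyEntry, DEFAULT_SCHEDULE, RankPointsSchedule

__all__ = [
    "FMaxResult",
    "BAND_CUTOFFS",
    "rank_to_points",
    "outcomes_from_band_counts",
    "mean_rank_points",
    "rank_band_counts",
    "precision_recall_at",
    "fmax_sweep",
    "bootstrap_se",
    "bootstrap_se_mean_rank_points",
    "bootstrap_se_fmax",
    "detection_counts",
    "concordance",
    "stratified_mean_rank_points",
    "paired_t_test",
]

BAND_CUTOFFS: tuple[int, ...] = (1, 5, 10, 20, 50, 100)

_INCOMPLETE = {Completeness.PROBAND_ONLY, Completeness.DUO}


def rank_to_points(rank: Optional[int], schedule: RankPointsSchedule = DEFAULT_SCHEDULE) -> float:
    """Points for one match rank; ``None`` (miss) or rank beyond the last band → miss_points."""
    if rank is None:
        return schedule.miss_points
    if rank < 1:
        raise ValueError(f"rank {rank} < 1")
    for max_rank, points in schedule.bands:
        if rank <= max_rank:
            return points
    return schedule.miss_points


def _outcome_list(outcomes: Mapping[str, MatchOutcome] | Iterable[MatchOutcome]) -> list[MatchOutcome]:
    if isinstance(outcomes, Mapping):
        return list(outcomes.values())
    return list(outcomes)


def mean_rank_points(
    outcomes: Mapping[str, MatchOutcome] | Iterable[MatchOutcome],
    schedule: RankPointsSchedule = DEFAULT_SCHEDULE,
) -> float:
    """Arithmetic mean of rank points over all solved entries (one outcome each)."""
    outs = _outcome_list(outcomes)
    if not outs:
        raise ValueError("mean_rank_points is undefined over zero solved entries")
    return float(np.mean([rank_to_points(o.match_rank, schedule) for o in outs]))


def outcomes_from_band_counts(
    counts: Sequence[int],
    n_solved: int,
    cutoffs: Sequence[int] = BAND_CUTOFFS,
) -> list[MatchOutcome]:
    """Reconstruct per-proband outcomes consistent with cumulative band counts.

    Published assessments often report only the cumulative counts of causal
    variants detected within each rank cutoff.  Because the rank-points metric
    depends only on band membership, any ranks consistent with the counts give
    the same mean rank points; representative mid-band ranks are used.
    """
    if len(counts) != len(cutoffs):
        raise ValueError("counts and cutoffs must have equal length")
    if list(counts) != sorted(counts):
        raise ValueError("cumulative band counts must be non-decreasing")
    if counts[-1] > n_solved:
        raise ValueError("counts exceed the number of solved entries")
    reps = [cutoffs[0]] + [
        (lo + hi + 1) // 2 for lo, hi in zip(cutoffs, cutoffs[1:])
    ]
    outcomes: list[MatchOutcome] = []
    prev = 0
    for rep_rank, c in zip(reps, counts):
        for i in range(c - prev):
            outcomes.append(
                MatchOutcome(f"p{len(outcomes) + 1}", matched=True, match_rank=rep_rank)
            )
        prev = c
    for _ in range(n_solved - counts[-1]):
        outcomes.append(MatchOutcome(f"p{len(outcomes) + 1}", matched=False))
    return outcomes


def rank_band_counts(
    outcomes: Mapping[str, MatchOutcome] | Iterable[MatchOutcome],
    cutoffs: Sequence[int] = BAND_CUTOFFS,
) -> tuple[int, ...]:
    """Cumulative counts of matches with rank ≤ each cutoff (non-decreasing)."""
    ranks = [o.match_rank for o in _outcome_list(outcomes) if o.matched]
    return tuple(sum(1 for r in ranks if r <= c) for c in cutoffs)


# ---------------------------------------------------------------------------
# F-max machinery.  Per solved proband we reduce the (resolved) records to a
# profile: all EPCRs sorted ascending, plus the EPCR of the unique matching
# record if any.  Precision/recall at any threshold are then pure counting.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SolvedProfile:
    epcrs: np.ndarray  # ascending
    matched_epcr: Optional[float]


def _build_profiles(
    sub: ModelSubmission, key: AnswerKey, partial_credit: bool = False
) -> dict[str, _SolvedProfile]:
    resolved, outcomes = resolve_submission(sub, key, partial_credit=partial_credit)
    profiles: dict[str, _SolvedProfile] = {}
    for entry in key.solved_entries:
        records = resolved.records_for(entry.proband_id)
        epcrs = np.sort(np.array([r.epcr for r in records], dtype=float))
        out = outcomes[entry.proband_id]
        matched_epcr = out.matched_record.epcr if out.matched else None
        profiles[entry.proband_id] = _SolvedProfile(epcrs, matched_epcr)
    return profiles


def _prf_from_profiles(
    profiles: Sequence[_SolvedProfile], t: float
) -> tuple[float, float, float]:
    n_solved = len(profiles)
    calls = sum(int(p.epcrs.size - np.searchsorted(p.epcrs, t, side="left")) for p in profiles)
    tp = sum(1 for p in profiles if p.matched_epcr is not None and p.matched_epcr >= t)
    precision = tp / calls if calls else 0.0
    recall = tp / n_solved
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return precision, recall, f


def precision_recall_at(
    sub: ModelSubmission, key: AnswerKey, t: float, partial_credit: bool = False
) -> tuple[float, float, float]:
    """(precision, recall, F) for the call set {records with EPCR ≥ t} over solved probands."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    profiles = list(_build_profiles(sub, key, partial_credit).values())
    return _prf_from_profiles(profiles, t)


@dataclass(frozen=True)
class FMaxResult:
    """F-max with its attaining threshold and per-proband call-volume summary.

    ``fmax`` is NaN (``is_na``) for a model with no records over the solved
    probands, mirroring a withdrawn/empty submission.
    """

    fmax: float
    threshold: Optional[float]
    mean_calls_per_proband: float
    sd_calls_per_proband: float
    curve: tuple[tuple[float, float, float, float], ...]  # (threshold, P, R, F) desc.

    @property
    def is_na(self) -> bool:
        return math.isnan(self.fmax)


_NA_FMAX = FMaxResult(float("nan"), None, float("nan"), float("nan"), ())


def fmax_sweep(
    sub: ModelSubmission, key: AnswerKey, partial_credit: bool = False
) -> FMaxResult:
    """Sweep F over every unique EPCR among the model's solved-proband records.

    On ties the largest tying EPCR is reported (the most conservative call
    set).  Mean/SD calls per proband at that threshold are computed over all
    solved probands, probands with no calls contributing 0 (SD uses the n−1
    denominator).
    """
    profiles = _build_profiles(sub, key, partial_credit)
    plist = list(profiles.values())
    all_epcrs = np.concatenate([p.epcrs for p in plist]) if plist else np.array([])
    if all_epcrs.size == 0:
        return _NA_FMAX
    thresholds = np.unique(all_epcrs)[::-1]  # descending
    curve = []
    best_f, best_t = -1.0, None
    for t in thresholds:
        p, r, f = _prf_from_profiles(plist, float(t))
        curve.append((float(t), p, r, f))
        if f > best_f:  # strict: descending order makes the largest tying t win
            best_f, best_t = f, float(t)
    calls = np.array(
        [p.epcrs.size - np.searchsorted(p.epcrs, best_t, side="left") for p in plist],
        dtype=float,
    )
    sd = float(np.std(calls, ddof=1)) if calls.size > 1 else 0.0
    return FMaxResult(
        fmax=best_f,
        threshold=best_t,
        mean_calls_per_proband=float(np.mean(calls)),
        sd_calls_per_proband=sd,
        curve=tuple(curve),
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_se(
    statistic: Callable[[list], float],
    items: Sequence,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """SD (n−1 denominator) of ``statistic`` over B with-replacement resamples of ``items``.

    ``items`` are the resampling units (solved probands); the statistic must be
    total on any nonempty multiset of them.  Deterministic given a seed.
    """
    if B < 2:
        raise ValueError("B must be ≥ 2")
    items = list(items)
    if not items:
        raise ValueError("cannot bootstrap an empty collection")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(items)
    idx = rng.integers(0, n, size=(B, n))
    vals = np.array([statistic([items[i] for i in row]) for row in idx], dtype=float)
    return float(np.std(vals, ddof=1))


def bootstrap_se_mean_rank_points(
    outcomes: Mapping[str, MatchOutcome] | Iterable[MatchOutcome],
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    schedule: RankPointsSchedule = DEFAULT_SCHEDULE,
) -> float:
    """Vectorized bootstrap SE of mean rank points (identical law to :func:`bootstrap_se`)."""
    if B < 2:
        raise ValueError("B must be ≥ 2")
    points = np.array(
        [rank_to_points(o.match_rank, schedule) for o in _outcome_list(outcomes)], dtype=float
    )
    if points.size == 0:
        raise ValueError("cannot bootstrap zero solved entries")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, points.size, size=(B, points.size))
    return float(np.std(points[idx].mean(axis=1), ddof=1))


def bootstrap_se_fmax(
    sub: ModelSubmission,
    key: AnswerKey,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    partial_credit: bool = False,
) -> float:
    """Bootstrap SE of F-max, re-sweeping the threshold on every replicate.

    Each replicate resamples solved probands with replacement and sweeps F over
    the union grid of unique EPCRs (F is piecewise constant between unique
    values, so the union grid attains every replicate's F-max).  NaN for an
    empty submission.
    """
    if B < 2:
        raise ValueError("B must be ≥ 2")
    plist = list(_build_profiles(sub, key, partial_credit).values())
    n = len(plist)
    all_epcrs = np.concatenate([p.epcrs for p in plist]) if plist else np.array([])
    if all_epcrs.size == 0:
        return float("nan")
    grid = np.unique(all_epcrs)  # ascending thresholds
    U = grid.size
    calls_mat = np.empty((n, U), dtype=np.int64)
    tp_mat = np.empty((n, U), dtype=np.int64)
    for i, p in enumerate(plist):
        calls_mat[i] = p.epcrs.size - np.searchsorted(p.epcrs, grid, side="left")
        if p.matched_epcr is None:
            tp_mat[i] = 0
        else:
            tp_mat[i] = (grid <= p.matched_epcr).astype(np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fmaxes = np.empty(B, dtype=float)
    chunk = max(1, min(B, 256))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        calls = calls_mat[idx].sum(axis=1)  # (b, U)
        tp = tp_mat[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            precision = np.where(calls > 0, tp / np.maximum(calls, 1), 0.0)
            recall = tp / n
            denom = precision + recall
            f = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
        fmaxes[done : done + b] = f.max(axis=1)
        done += b
    return float(np.std(fmaxes, ddof=1))


# ---------------------------------------------------------------------------
# Secondary summaries
# ---------------------------------------------------------------------------


def detection_counts(
    submissions: Sequence[ModelSubmission],
    entry: AnswerKeyEntry,
    cutoffs: Sequence[int] = BAND_CUTOFFS,
    partial_credit: bool = False,
) -> tuple[int, ...]:
    """Per solved entry: cumulative counts of models detecting it within each rank cutoff."""
    if not submissions:
        raise ValueError("detection_counts requires at least one model")
    ranks = []
    for sub in submissions:
        _, outcome = _score_entry(sub.records_for(entry.proband_id), entry, partial_credit)
        if outcome.matched:
            ranks.append(outcome.match_rank)
    return tuple(sum(1 for r in ranks if r <= c) for c in cutoffs)


def concordance(sub_a: ModelSubmission, sub_b: ModelSubmission, k: int = 5) -> float:
    """Mean per-proband Jaccard index of the two models' top-k variant-set collections.

    Averaged over probands where at least one model submitted; symmetric;
    self-concordance of a nonempty submission is 1.  NaN when both
    submissions are empty.
    """
    probands = sorted(set(sub_a.predictions) | set(sub_b.predictions))
    scores = []
    for pid in probands:
        top_a = {r.variants for r in sub_a.records_for(pid)[:k]}
        top_b = {r.variants for r in sub_b.records_for(pid)[:k]}
        if not top_a and not top_b:
            continue
        scores.append(len(top_a & top_b) / len(top_a | top_b))
    if not scores:
        return float("nan")
    return float(np.mean(scores))


def stratified_mean_rank_points(
    outcomes: Mapping[str, MatchOutcome],
    families: Mapping[str, FamilyInfo],
    schedule: RankPointsSchedule = DEFAULT_SCHEDULE,
) -> tuple[float, float]:
    """Mean rank points over (proband-only + duo) vs (trio + quad) solved entries.

    Incomplete familial data hinders segregation-based prioritization; this
    split quantifies the handicap.  An empty stratum yields NaN.
    """
    incomplete, complete = [], []
    for pid, outcome in outcomes.items():
        fam = families.get(pid)
        if fam is None:
            raise KeyError(f"proband {pid!r} has no family metadata")
        points = rank_to_points(outcome.match_rank, schedule)
        (incomplete if fam.completeness in _INCOMPLETE else complete).append(points)
    score_i = float(np.mean(incomplete)) if incomplete else float("nan")
    score_c = float(np.mean(complete)) if complete else float("nan")
    return score_i, score_c


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student's t-test on d = y − x; returns (t, p).

    Degenerate cases: all differences zero → (0, 1); zero-variance nonzero
    differences → (±inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = y - x
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return math.copysign(math.inf, float(np.mean(d))), 0.0
    res = stats.ttest_rel(y, x)
    return float(res.statistic), float(res.pvalue)
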