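"""Matching model predictions against the answer key.

Rules:

* An ALL_OF answer (compound heterozygous) is matched only by a biallelic
  prediction whose unordered pair equals the required set exactly.  A correct
  causal variant submitted together with a non-causal partner in a proposed
  biallelic prediction is incorrect, and a single-variant prediction of one
  allele earns no credit (strict mode; ``partial_credit`` relaxes this for
  exploratory use).
* An ANY_OF answer (cis-pair equivalence group) is matched by a single-variant
  prediction of either member, or by the full pair.  Before metrics are
  computed, the highest-ranked prediction hitting the group is retained and
  every other prediction hitting it is removed from the proband's list;
  surviving records keep their original ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .submission import ModelSubmission, PredictionRecord
from .variants import AnswerKey, AnswerKeyEntry, MatchMode

__all__ = ["MatchOutcome", "match_prediction", "resolve_equivalence", "score_model", "resolve_submission"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchOutcome:
    """Rank of the first correct prediction for one solved answer-key entry."""

    proband_id: str
    matched: bool
    match_rank: Optional[int] = None
    matched_record: Optional[PredictionRecord] = None
    removed_ranks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.matched != (self.match_rank is not None):
            raise ValueError("matched and match_rank must agree")
        if self.match_rank is not None and self.match_rank < 1:
            raise ValueError("match_rank must be ≥ 1")


def match_prediction(
    pred: PredictionRecord, entry: AnswerKeyEntry, partial_credit: bool = False
) -> bool:
    """Does one prediction match one solved answer-key entry?

    Invariant to the order of variants within a biallelic prediction.
    """
    if not entry.solved:
        raise ValueError(f"{entry.proband_id}: matching against an unsolved entry")
    if entry.match_mode is MatchMode.ALL_OF:
        if pred.variants == entry.required_set:
            return True
        if partial_credit and len(entry.required_set) == 2:
            return len(pred.variants) == 1 and pred.variants <= entry.required_set
        return False
    # ANY_OF: either member alone, or the full group; a member paired with a
    # variant outside the group is a wrong-partner biallelic call → incorrect.
    if len(pred.variants) == 1:
        return pred.variants <= entry.required_set
    return pred.variants == entry.required_set


def resolve_equivalence(
    predictions: list[PredictionRecord], entry: AnswerKeyEntry
) -> tuple[list[PredictionRecord], MatchOutcome]:
    """Collapse an ANY_OF equivalence group to its best-ranked hit.

    The lowest-rank record matching any group member is retained as the match;
    all other matching records are deleted before any metric is computed.
    Non-matching records keep their relative order and original ranks.
    """
    if entry.match_mode is not MatchMode.ANY_OF:
        raise ValueError(f"{entry.proband_id}: resolve_equivalence requires an ANY_OF entry")
    hits = [rec for rec in predictions if match_prediction(rec, entry)]
    if not hits:
        return list(predictions), MatchOutcome(entry.proband_id, matched=False)
    best = min(hits, key=lambda r: r.rank)
    removed = tuple(r.rank for r in hits if r is not best)
    filtered = [r for r in predictions if r is best or r not in hits]
    return filtered, MatchOutcome(
        entry.proband_id,
        matched=True,
        match_rank=best.rank,
        matched_record=best,
        removed_ranks=removed,
    )


NEAR_MISS_WINDOW = 10


def _warn_near_misses(records: list[PredictionRecord], entry: AnswerKeyEntry) -> None:
    """Flag predicted variants that nearly coincide with a missed answer.

    Matching is exact by design; a submitted variant on the same contig within
    a few bases of a required variant usually signals representation drift
    (e.g. un-normalized indels) rather than a genuinely wrong call, so it is
    surfaced for manual review instead of being silently credited.
    """
    for rec in records:
        for v in rec.variants:
            for req in entry.required_set:
                if v.contig == req.contig and abs(v.position - req.position) <= NEAR_MISS_WINDOW:
                    logger.warning(
                        "%s: near miss — predicted %s at rank %d vs required %s",
                        entry.proband_id, v, rec.rank, req,
                    )


def _score_entry(
    records: list[PredictionRecord], entry: AnswerKeyEntry, partial_credit: bool
) -> tuple[list[PredictionRecord], MatchOutcome]:
    if entry.match_mode is MatchMode.ANY_OF:
        return resolve_equivalence(records, entry)
    for rec in records:
        if match_prediction(rec, entry, partial_credit=partial_credit):
            return list(records), MatchOutcome(
                entry.proband_id, matched=True, match_rank=rec.rank, matched_record=rec
            )
    return list(records), MatchOutcome(entry.proband_id, matched=False)


def score_model(
    sub: ModelSubmission, key: AnswerKey, partial_credit: bool = False
) -> dict[str, MatchOutcome]:
    """One MatchOutcome per solved answer-key entry (missing probands → no match)."""
    return resolve_submission(sub, key, partial_credit=partial_credit)[1]


def resolve_submission(
    sub: ModelSubmission, key: AnswerKey, partial_credit: bool = False
) -> tuple[ModelSubmission, dict[str, MatchOutcome]]:
    """Score every solved entry and return the equivalence-resolved submission.

    The returned submission has ANY_OF duplicate hits removed, ready for
    threshold-based metrics.  Probands present in the submission but absent
    from the key are left untouched (they are ignored by the solved-proband
    metrics anyway).
    """
    for proband_id in sub.predictions:
        if proband_id not in key:
            logger.warning(
                "%s: proband %s not in answer key; records ignored for scoring",
                sub.name, proband_id,
            )
    outcomes: dict[str, MatchOutcome] = {}
    resolved: dict[str, list[PredictionRecord]] = dict(sub.predictions)
    for entry in key.solved_entries:
        records = sub.records_for(entry.proband_id)
        filtered, outcome = _score_entry(records, entry, partial_credit)
        outcomes[entry.proband_id] = outcome
        resolved[entry.proband_id] = filtered
        if not outcome.matched:
            _warn_near_misses(records, entry)
    return (
        ModelSubmission(team_id=sub.team_id, model_id=sub.model_id, predictions=resolved),
        outcomes,
    )
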