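"""Model submission files: parsing, validation and cleaning.

The submission contract: a tab-delimited file with up to 100 ranked predictions
per proband, each a single variant or a proposed compound-heterozygous pair
(two variants on one line), carrying an estimated probability of causal
relationship (EPCR) in [0, 1].  Rank is the order of appearance within a
proband's block — predictions are ranked by causal likelihood by the
submitter, and file order is authoritative.  EPCR/rank disagreement is flagged
as a warning, never repaired, since re-sorting would silently move records
across scoring bands.

Malformed lines are dropped with per-line diagnostics and never abort a parse:
the assessment corrects formatting problems and removes redundant, duplicate
and incomplete records rather than rejecting a model wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .variants import VariantKey, VariantParseError, normalize_variant

__all__ = [
    "PredictionRecord",
    "ModelSubmission",
    "ValidationIssue",
    "ValidationReport",
    "MAX_PREDICTIONS_PER_PROBAND",
    "parse_submission",
    "clean_submission",
    "render_submission",
]

MAX_PREDICTIONS_PER_PROBAND = 100

# drop-reason codes
FIELD_COUNT = "FIELD_COUNT"
VARIANT_PARSE = "VARIANT_PARSE"
EPCR_PARSE = "EPCR_PARSE"
EPCR_RANGE = "EPCR_RANGE"
SELF_PAIR = "SELF_PAIR"
DUPLICATE = "DUPLICATE"
OVER_LIMIT = "OVER_LIMIT"
EPCR_ORDER = "EPCR_ORDER"


@dataclass(frozen=True, slots=True)
class PredictionRecord:
    """One ranked prediction: a single variant or an unordered biallelic pair."""

    proband_id: str
    variants: frozenset[VariantKey]
    epcr: float
    rank: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.variants) <= 2:
            raise ValueError("a prediction carries 1 or 2 variants")
        if not 0.0 <= self.epcr <= 1.0:
            raise ValueError(f"EPCR {self.epcr} outside [0, 1]")
        if self.rank < 1:
            raise ValueError(f"rank {self.rank} < 1")

    @property
    def is_biallelic(self) -> bool:
        return len(self.variants) == 2


@dataclass(frozen=True, slots=True)
class ValidationIssue:
    line: int
    code: str
    message: str


@dataclass
class ValidationReport:
    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)
    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def drop(self, line: int, code: str, message: str) -> None:
        self.errors.append(ValidationIssue(line, code, message))
        self.dropped[code] = self.dropped.get(code, 0) + 1

    def warn(self, line: int, code: str, message: str) -> None:
        self.warnings.append(ValidationIssue(line, code, message))

    def to_tsv(self) -> str:
        lines = ["#severity\tline\tcode\tmessage"]
        for issue in self.errors:
            lines.append(f"error\t{issue.line}\t{issue.code}\t{issue.message}")
        for issue in self.warnings:
            lines.append(f"warning\t{issue.line}\t{issue.code}\t{issue.message}")
        lines.append(f"#read={self.n_read}\tkept={self.n_kept}\tdropped={self.n_dropped}")
        return "\n".join(lines) + "\n"


@dataclass
class ModelSubmission:
    """A model's ranked, EPCR-scored predictions keyed by proband."""

    team_id: str
    model_id: str
    predictions: dict[str, list[PredictionRecord]] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"{self.team_id}/{self.model_id}"

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.predictions.values())

    def records_for(self, proband_id: str) -> list[PredictionRecord]:
        return self.predictions.get(proband_id, [])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelSubmission):
            return NotImplemented
        return (
            self.team_id == other.team_id
            and self.model_id == other.model_id
            and self.predictions == other.predictions
        )


def parse_submission(
    path: str | Path, team_id: str = "", model_id: str = ""
) -> tuple[ModelSubmission, ValidationReport]:
    """Parse a submission TSV: ``proband_id  variant1  variant2|.  epcr``.

    ``#`` header lines are skipped.  Per-proband rank is the order of
    appearance.  Malformed lines are dropped and reported; only an unreadable
    file is fatal.
    """
    path = Path(path)
    if not team_id and not model_id:
        # convention: files named TEAM_MODEL.tsv, e.g. team9_model1.tsv
        stem = path.stem
        team_id, _, model_id = stem.partition("_")
        model_id = model_id or "model1"
    report = ValidationReport()
    per_proband: dict[str, list[PredictionRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            report.n_read += 1
            parts = line.split("\t")
            if len(parts) != 4:
                report.drop(lineno, FIELD_COUNT, f"expected 4 tab-separated fields, got {len(parts)}")
                continue
            proband_id, v1_s, v2_s, epcr_s = (p.strip() for p in parts)
            if not proband_id:
                report.drop(lineno, FIELD_COUNT, "empty proband_id")
                continue
            try:
                variants = {normalize_variant(v1_s)}
                if v2_s not in (".", ""):
                    variants.add(normalize_variant(v2_s))
            except VariantParseError as exc:
                report.drop(lineno, VARIANT_PARSE, str(exc))
                continue
            if v2_s not in (".", "") and len(variants) == 1:
                report.drop(lineno, SELF_PAIR, "biallelic pair lists the same variant twice")
                continue
            try:
                epcr = float(epcr_s)
            except ValueError:
                report.drop(lineno, EPCR_PARSE, f"EPCR {epcr_s!r} is not a number")
                continue
            if not 0.0 <= epcr <= 1.0:
                report.drop(lineno, EPCR_RANGE, f"EPCR {epcr} outside [0, 1]")
                continue
            records = per_proband.setdefault(proband_id, [])
            records.append(
                PredictionRecord(
                    proband_id=proband_id,
                    variants=frozenset(variants),
                    epcr=epcr,
                    rank=len(records) + 1,
                )
            )
            report.n_kept += 1
    return ModelSubmission(team_id=team_id, model_id=model_id, predictions=per_proband), report


def clean_submission(sub: ModelSubmission) -> tuple[ModelSubmission, ValidationReport]:
    """Remove duplicate variant sets, enforce the 100-prediction cap, renumber ranks.

    Within each proband, a record whose variant set duplicates an earlier
    (better-ranked) record is removed; records beyond position 100 are
    truncated; surviving ranks are renumbered consecutively from 1, preserving
    relative order.  Non-increasing EPCR violations emit warnings only.
    Idempotent: cleaning a clean submission returns it unchanged.
    """
    report = ValidationReport()
    cleaned: dict[str, list[PredictionRecord]] = {}
    for proband_id, records in sub.predictions.items():
        report.n_read += len(records)
        seen: set[frozenset[VariantKey]] = set()
        kept: list[PredictionRecord] = []
        for rec in records:
            if rec.variants in seen:
                report.drop(rec.rank, DUPLICATE, f"{proband_id}: duplicate of an earlier variant set")
                continue
            if len(kept) >= MAX_PREDICTIONS_PER_PROBAND:
                report.drop(rec.rank, OVER_LIMIT, f"{proband_id}: beyond {MAX_PREDICTIONS_PER_PROBAND}-prediction cap")
                continue
            seen.add(rec.variants)
            kept.append(rec)
        renumbered = [
            rec if rec.rank == i else replace(rec, rank=i)
            for i, rec in enumerate(kept, start=1)
        ]
        for prev, cur in zip(renumbered, renumbered[1:]):
            if cur.epcr > prev.epcr:
                report.warn(
                    cur.rank,
                    EPCR_ORDER,
                    f"{proband_id}: EPCR rises from {prev.epcr} (rank {prev.rank}) "
                    f"to {cur.epcr} (rank {cur.rank})",
                )
        report.n_kept += len(renumbered)
        cleaned[proband_id] = renumbered
    return ModelSubmission(team_id=sub.team_id, model_id=sub.model_id, predictions=cleaned), report


def render_submission(sub: ModelSubmission, path: str | Path) -> None:
    """Write a submission in the dialect read by :func:`parse_submission`."""
    with open(path, "w") as fh:
        fh.write("#proband_id\tvariant1\tvariant2\tepcr\n")
        for proband_id in sub.predictions:
            for rec in sub.predictions[proband_id]:
                vs = sorted(str(v) for v in rec.variants)
                v1 = vs[0]
                v2 = vs[1] if len(vs) == 2 else "."
                fh.write(f"{proband_id}\t{v1}\t{v2}\t{rec.epcr!r}\n")
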