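"""Core domain types: normalized variant keys, answer-key entries, rank-points schedule.

A challenge distributes one canonical VCF to all participants, so variant identity
is exact string identity after contig/case normalization: no indel left-alignment
or allele minimalization is attempted.  Silently "repairing" representations would
credit matches the real assessment would have missed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "VariantKey",
    "VariantParseError",
    "AnswerKeyError",
    "MatchMode",
    "AnswerKeyEntry",
    "AnswerKey",
    "RankPointsSchedule",
    "DEFAULT_SCHEDULE",
    "normalize_variant",
    "load_answer_key",
    "write_answer_key",
]

_VALID_CONTIGS = frozenset([str(c) for c in range(1, 23)] + ["X", "Y", "MT"])
_DNA_RE = re.compile(r"^[ACGT]+$")


class VariantParseError(ValueError):
    """A variant string failed normalization; the message names the offending field."""


class AnswerKeyError(ValueError):
    """An answer-key file violated the dialect or its invariants."""


@dataclass(frozen=True, slots=True)
class VariantKey:
    """One normalized genomic small variant (SNV or small indel), 1-based coordinates.

    Two keys compare equal iff contig, position, ref and alt all match after
    normalization; this is the unit being predicted and matched.
    """

    contig: str
    position: int
    ref: str
    alt: str
    build: str = "GRCh38"

    def __post_init__(self) -> None:
        if self.contig not in _VALID_CONTIGS:
            raise VariantParseError(f"contig: {self.contig!r} is not 1-22, X, Y or MT")
        if self.position < 1:
            raise VariantParseError(f"position: {self.position} < 1")
        if not _DNA_RE.match(self.ref):
            raise VariantParseError(f"ref: {self.ref!r} is not a non-empty A/C/G/T string")
        if not _DNA_RE.match(self.alt):
            raise VariantParseError(f"alt: {self.alt!r} is not a non-empty A/C/G/T string")
        if self.ref == self.alt:
            raise VariantParseError(f"alt: equals ref ({self.ref!r})")

    def __str__(self) -> str:
        return f"{self.contig}:{self.position}:{self.ref}:{self.alt}"


def normalize_variant(raw: str) -> VariantKey:
    """Parse ``CONTIG:POS:REF:ALT`` into a :class:`VariantKey`.

    Normalization strips any leading ``chr`` from the contig and uppercases
    the alleles, so ``chr7:100:c:t`` and ``7:100:C:T`` yield equal keys.
    Idempotent: ``normalize_variant(str(key)) == key``.
    """
    parts = raw.strip().split(":")
    if len(parts) != 4:
        raise VariantParseError(
            f"variant: expected 4 colon-separated fields, got {len(parts)} in {raw!r}"
        )
    contig, pos_s, ref, alt = parts
    contig = contig.strip()
    if contig.lower().startswith("chr"):
        contig = contig[3:]
    contig = contig.upper()
    try:
        position = int(pos_s)
    except ValueError:
        raise VariantParseError(f"position: {pos_s!r} is not an integer") from None
    return VariantKey(contig=contig, position=position, ref=ref.upper(), alt=alt.upper())


class MatchMode(Enum):
    """How a multi-variant answer is matched.

    ALL_OF: every variant in the required set must be predicted jointly (one
    biallelic, compound-heterozygous prediction).  ANY_OF: the variants form an
    equivalence group (e.g. two candidates in cis on one haplotype) and a
    prediction of either member counts.
    """

    ALL_OF = "ALL_OF"
    ANY_OF = "ANY_OF"


@dataclass(frozen=True, slots=True)
class AnswerKeyEntry:
    """A proband's acceptable causal variant set(s), or an unsolved placeholder."""

    proband_id: str
    solved: bool
    match_mode: MatchMode = MatchMode.ALL_OF
    required_set: frozenset[VariantKey] = field(default_factory=frozenset)
    label: str = ""

    def __post_init__(self) -> None:
        if self.solved and not self.required_set:
            raise AnswerKeyError(f"{self.proband_id}: solved entry without variants")
        if not self.solved and self.required_set:
            raise AnswerKeyError(f"{self.proband_id}: unsolved entry must have empty set")
        if len(self.required_set) > 2:
            raise AnswerKeyError(f"{self.proband_id}: more than 2 required variants")


class AnswerKey:
    """Ordered collection of answer-key entries, one per proband."""

    def __init__(self, entries: Iterable[AnswerKeyEntry]):
        self.entries: list[AnswerKeyEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.proband_id in seen:
                raise AnswerKeyError(f"duplicate proband_id {e.proband_id!r}")
            seen.add(e.proband_id)
        self._by_id = {e.proband_id: e for e in self.entries}

    def __iter__(self) -> Iterator[AnswerKeyEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, proband_id: str) -> AnswerKeyEntry:
        return self._by_id[proband_id]

    def __contains__(self, proband_id: str) -> bool:
        return proband_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnswerKey):
            return NotImplemented
        return self.entries == other.entries

    @property
    def solved_entries(self) -> list[AnswerKeyEntry]:
        return [e for e in self.entries if e.solved]

    @property
    def n_solved(self) -> int:
        return len(self.solved_entries)

    @property
    def n_unsolved(self) -> int:
        return len(self.entries) - self.n_solved


def load_answer_key(path: str | Path) -> AnswerKey:
    """Read an answer-key TSV.

    Dialect (tab-separated, ``#`` header lines ignored)::

        proband_id  solved{0,1}  match_mode{ALL_OF,ANY_OF}  variants  label

    ``variants`` is a semicolon-joined list of ``CONTIG:POS:REF:ALT`` strings
    (``.`` or empty for unsolved probands).
    """
    entries: list[AnswerKeyEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnswerKeyError(f"line {lineno}: expected ≥4 tab-separated fields")
            proband_id, solved_s, mode_s, variants_s = parts[:4]
            label = parts[4] if len(parts) > 4 else ""
            if solved_s not in ("0", "1"):
                raise AnswerKeyError(f"line {lineno}: solved must be 0 or 1, got {solved_s!r}")
            solved = solved_s == "1"
            try:
                mode = MatchMode(mode_s)
            except ValueError:
                raise AnswerKeyError(
                    f"line {lineno}: unknown match_mode {mode_s!r}"
                ) from None
            if variants_s in (".", ""):
                variants: frozenset[VariantKey] = frozenset()
            else:
                try:
                    variants = frozenset(
                        normalize_variant(v) for v in variants_s.split(";")
                    )
                except VariantParseError as exc:
                    raise AnswerKeyError(f"line {lineno}: {exc}") from None
            entries.append(
                AnswerKeyEntry(
                    proband_id=proband_id,
                    solved=solved,
                    match_mode=mode,
                    required_set=variants,
                    label=label,
                )
            )
    return AnswerKey(entries)


def write_answer_key(key: AnswerKey, path: str | Path) -> None:
    """Write an answer key in the dialect read by :func:`load_answer_key`."""
    with open(path, "w") as fh:
        fh.write("#proband_id\tsolved\tmatch_mode\tvariants\tlabel\n")
        for e in key:
            variants_s = (
                ";".join(sorted(str(v) for v in e.required_set)) if e.required_set else "."
            )
            fh.write(
                f"{e.proband_id}\t{int(e.solved)}\t{e.match_mode.value}\t"
                f"{variants_s}\t{e.label}\n"
            )


@dataclass(frozen=True)
class RankPointsSchedule:
    """Band-weighted point schedule rewarding highly-ranked causal variants.

    ``bands`` is an ordered list of (inclusive max rank, points); a matched rank
    scores the points of the first band whose max_rank covers it, and anything
    beyond the last band (or a miss) scores ``miss_points``.
    """

    bands: tuple[tuple[int, float], ...] = ((5, 100.0), (10, 50.0), (20, 25.0), (50, 10.0), (100, 5.0))
    miss_points: float = 0.0

    def __post_init__(self) -> None:
        maxes = [m for m, _ in self.bands]
        pts = [p for _, p in self.bands]
        if maxes != sorted(maxes) or len(set(maxes)) != len(maxes):
            raise ValueError("band max_rank values must be strictly increasing")
        if pts != sorted(pts, reverse=True) or len(set(pts)) != len(pts):
            raise ValueError("band points must be strictly decreasing")

    @property
    def max_rank(self) -> int:
        return self.bands[-1][0]


DEFAULT_SCHEDULE = RankPointsSchedule()
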