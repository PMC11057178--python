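"""Synthetic Mendelian challenge generation.

Builds complete, self-consistent challenges — families with realistic
completeness classes (proband-only/duo/trio/quad), an answer key covering de
novo, recessive (homozygous and compound-heterozygous), X-linked recessive and
sex-limited dominant diagnoses (including one cis-pair equivalence entry), a
decoy variant pool — and skill-parameterized model submissions, so the whole
assessment pipeline can be exercised end-to-end without access to restricted
patient data.

A model's "skill" is a probability distribution over the rank band in which it
places the causal variant (or misses), plus Beta laws for the EPCRs of causal
and decoy records.  The analytic expectation of the mean-rank-points metric
under a skill profile is a dot product with the point schedule, which makes
generated challenges an oracle for metric-recovery tests.

Decoy variants are sampled uniformly over contigs 1–22 and X with positions in
[1, 2.5e8] and random SNV alleles; allele-frequency spectra and gene context
are deliberately absent because no assessment metric consumes them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .families import FamilyInfo, FamilyMember, Completeness, Relation, write_hpo, write_ped
from .submission import ModelSubmission, PredictionRecord, render_submission
from .variants import (
    AnswerKey,
    AnswerKeyEntry,
    DEFAULT_SCHEDULE,
    MatchMode,
    RankPointsSchedule,
    VariantKey,
    write_answer_key,
)

__all__ = [
    "Inheritance",
    "SkillProfile",
    "ChallengeConfig",
    "Challenge",
    "generate_challenge",
    "generate_model_submission",
    "expected_mean_rank_points",
    "graded_skill_ladder",
    "run_recovery_experiment",
    "write_challenge",
    "BAND_RANGES",
]

# (lo, hi) rank ranges for the five scoring bands; index 5 is the miss outcome.
BAND_RANGES: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 20), (21, 50), (51, 100))

_BAND_POINTS = np.array([100.0, 50.0, 25.0, 10.0, 5.0, 0.0])

_HPO_VOCAB = (
    "HP:0001250",  # seizure
    "HP:0001263",  # global developmental delay
    "HP:0001252",  # hypotonia
    "HP:0000365",  # hearing impairment
    "HP:0000505",  # visual impairment
    "HP:0001249",  # intellectual disability
    "HP:0002119",  # ventriculomegaly
    "HP:0001332",  # dystonia
    "HP:0002072",  # chorea
    "HP:0000252",  # microcephaly
)

_BASES = ("A", "C", "G", "T")
_AUTOSOMES_X = tuple(str(c) for c in range(1, 23)) + ("X",)


class Inheritance(Enum):
    DE_NOVO = "de_novo"
    AR_COMPOUND_HET = "ar_compound_het"
    AR_HOMOZYGOUS = "ar_homozygous"
    XLR = "xlr"
    DOMINANT_SEX_LIMITED = "dominant_sex_limited"


@dataclass(frozen=True)
class SkillProfile:
    """Parameterized model skill: band-hit probabilities and EPCR calibration.

    ``band_probs`` covers the outcomes (rank 1–5, 6–10, 11–20, 21–50, 51–100,
    miss) and must sum to 1.  EPCRs of causal and decoy records are drawn from
    Beta(α, β) laws; a well-calibrated model has a larger causal than decoy
    Beta mean.
    """

    band_probs: tuple[float, float, float, float, float, float]
    epcr_causal: tuple[float, float] = (8.0, 2.0)
    epcr_decoy: tuple[float, float] = (1.0, 4.0)
    n_preds_per_proband: int = 100

    def __post_init__(self) -> None:
        if len(self.band_probs) != 6:
            raise ValueError("band_probs must have 6 entries (5 bands + miss)")
        if any(p < 0 for p in self.band_probs):
            raise ValueError("band_probs must be non-negative")
        if abs(sum(self.band_probs) - 1.0) > 1e-9:
            raise ValueError("band_probs must sum to 1")
        for a, b in (self.epcr_causal, self.epcr_decoy):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        if self.n_preds_per_proband < 1:
            raise ValueError("n_preds_per_proband must be ≥ 1")
        for (lo, _hi), p in zip(BAND_RANGES, self.band_probs):
            if p > 0 and lo > self.n_preds_per_proband:
                raise ValueError(
                    f"band starting at rank {lo} is unreachable with "
                    f"{self.n_preds_per_proband} predictions per proband"
                )


def expected_mean_rank_points(
    skill: SkillProfile, schedule: RankPointsSchedule = DEFAULT_SCHEDULE
) -> float:
    """Analytic expectation of mean rank points under a skill profile."""
    points = np.array([p for _m, p in schedule.bands] + [schedule.miss_points])
    return float(np.dot(np.asarray(skill.band_probs), points))


def graded_skill_ladder(n_preds: int = 100) -> list[SkillProfile]:
    """Ten skill profiles with well-separated expected scores.

    Single-band profiles give the five band point values and 0 exactly (zero
    band-membership variance); 50/50 mixtures of adjacent bands fill the gaps.
    Expected scores: 100, 75, 50, 37.5, 25, 17.5, 10, 7.5, 5, 0.
    """
    rows = [
        (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        (0.5, 0.5, 0.0, 0.0, 0.0, 0.0),
        (0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
        (0.0, 0.5, 0.5, 0.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 0.5, 0.5, 0.0, 0.0),
        (0.0, 0.0, 0.0, 1.0, 0.0, 0.0),
        (0.0, 0.0, 0.0, 0.5, 0.5, 0.0),
        (0.0, 0.0, 0.0, 0.0, 1.0, 0.0),
        (0.0, 0.0, 0.0, 0.0, 0.0, 1.0),
    ]
    return [SkillProfile(band_probs=r, n_preds_per_proband=n_preds) for r in rows]


@dataclass(frozen=True)
class ChallengeConfig:
    """Cohort composition for a synthetic challenge.

    Defaults mirror a 30-family test cohort: 14 solved / 16 unsolved, a
    completeness mix of 2 proband-only / 3 duos / 23 trios / 2 quads, and an
    inheritance mix dominated by de novo diagnoses with one compound-het and
    one sex-limited dominant (cis-pair) entry.
    """

    n_solved: int = 14
    n_unsolved: int = 16
    completeness_mix: dict = field(
        default_factory=lambda: {
            Completeness.PROBAND_ONLY: 2 / 30,
            Completeness.DUO: 3 / 30,
            Completeness.TRIO: 23 / 30,
            Completeness.QUAD: 2 / 30,
        }
    )
    inheritance_mix: dict = field(
        default_factory=lambda: {
            Inheritance.DE_NOVO: 9 / 14,
            Inheritance.AR_HOMOZYGOUS: 2 / 14,
            Inheritance.AR_COMPOUND_HET: 1 / 14,
            Inheritance.XLR: 1 / 14,
            Inheritance.DOMINANT_SEX_LIMITED: 1 / 14,
        }
    )
    include_cis_pair: bool = True
    decoy_pool_size: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_solved < 1:
            raise ValueError("n_solved must be ≥ 1")
        if self.n_unsolved < 0:
            raise ValueError("n_unsolved must be ≥ 0")
        for name, mix in (("completeness_mix", self.completeness_mix),
                          ("inheritance_mix", self.inheritance_mix)):
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} weights must be non-negative")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


@dataclass(frozen=True)
class Challenge:
    """A generated cohort: families, answer key, decoy pool, and provenance."""

    config: ChallengeConfig
    families: dict  # proband_id -> FamilyInfo
    answer_key: AnswerKey
    decoy_pool: tuple[VariantKey, ...]
    inheritance: dict  # proband_id -> Inheritance (solved probands only)


def _largest_remainder(weights: dict, n: int) -> dict:
    """Apportion n items over categories by largest-remainder quota (deterministic)."""
    items = list(weights.items())
    exact = [w * n for _k, w in items]
    floors = [int(np.floor(e)) for e in exact]
    short = n - sum(floors)
    order = sorted(range(len(items)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return {k: c for (k, _w), c in zip(items, floors)}


def _random_variant(rng: np.random.Generator, contig: str | None = None) -> VariantKey:
    if contig is None:
        contig = _AUTOSOMES_X[rng.integers(0, len(_AUTOSOMES_X))]
    pos = int(rng.integers(1, 250_000_001))
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 4)]
    while alt == ref:
        alt = _BASES[rng.integers(0, 4)]
    return VariantKey(contig=contig, position=pos, ref=ref, alt=alt)


def _sample_variants(rng: np.random.Generator, n: int, exclude: set[VariantKey],
                     contig: str | None = None) -> list[VariantKey]:
    out: list[VariantKey] = []
    seen = set(exclude)
    while len(out) < n:
        v = _random_variant(rng, contig)
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def _make_family(proband_id: str, completeness: Completeness) -> FamilyInfo:
    fam_id = "F" + proband_id[1:]
    members = {FamilyMember(proband_id, Relation.PROBAND, affected=True)}
    if completeness in (Completeness.TRIO, Completeness.QUAD, Completeness.DUO):
        members.add(FamilyMember(f"{proband_id}_fa", Relation.FATHER, affected=False))
    if completeness in (Completeness.TRIO, Completeness.QUAD):
        members.add(FamilyMember(f"{proband_id}_mo", Relation.MOTHER, affected=False))
    if completeness is Completeness.QUAD:
        members.add(FamilyMember(f"{proband_id}_sib", Relation.SIBLING, affected=True))
    return FamilyInfo(family_id=fam_id, proband_id=proband_id, members=frozenset(members))


def generate_challenge(cfg: ChallengeConfig) -> Challenge:
    """Generate families, answer key and decoy pool; byte-deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_solved + cfg.n_unsolved

    comp_quota = _largest_remainder(cfg.completeness_mix, n_total)
    comp_classes: list[Completeness] = []
    for comp, count in comp_quota.items():
        comp_classes.extend([comp] * count)
    rng.shuffle(comp_classes)  # completeness unlinked from solved status

    inh_quota = _largest_remainder(cfg.inheritance_mix, cfg.n_solved)
    inheritances: list[Inheritance] = []
    for inh, count in inh_quota.items():
        inheritances.extend([inh] * count)
    rng.shuffle(inheritances)

    # cis-pair equivalence entry rides on a sex-limited dominant diagnosis
    cis_idx: int | None = None
    if cfg.include_cis_pair:
        candidates = [i for i, inh in enumerate(inheritances)
                      if inh is Inheritance.DOMINANT_SEX_LIMITED]
        cis_idx = candidates[0] if candidates else cfg.n_solved - 1

    families: dict[str, FamilyInfo] = {}
    entries: list[AnswerKeyEntry] = []
    inheritance_of: dict[str, Inheritance] = {}
    causal: set[VariantKey] = set()

    for i in range(n_total):
        proband_id = f"P{i + 1:02d}"
        comp = comp_classes[i]
        solved = i < cfg.n_solved
        families[proband_id] = _make_family(proband_id, comp)
        if not solved:
            entries.append(AnswerKeyEntry(proband_id=proband_id, solved=False))
            continue
        inh = inheritances[i]
        inheritance_of[proband_id] = inh
        if inh is Inheritance.AR_COMPOUND_HET:
            variants = frozenset(_sample_variants(rng, 2, causal))
            mode = MatchMode.ALL_OF
        elif i == cis_idx:
            # two candidate variants in cis, a few bases apart, either causal
            anchor = _sample_variants(rng, 1, causal)[0]
            partner = VariantKey(
                contig=anchor.contig,
                position=anchor.position + 6,
                ref=anchor.ref,
                alt=anchor.alt,
            )
            variants = frozenset({anchor, partner})
            mode = MatchMode.ANY_OF
        elif inh is Inheritance.XLR:
            variants = frozenset(_sample_variants(rng, 1, causal, contig="X"))
            mode = MatchMode.ALL_OF
        else:
            variants = frozenset(_sample_variants(rng, 1, causal))
            mode = MatchMode.ALL_OF
        causal.update(variants)
        entries.append(
            AnswerKeyEntry(
                proband_id=proband_id,
                solved=True,
                match_mode=mode,
                required_set=variants,
                label=inh.value,
            )
        )

    # proband phenotype terms from a fixed small vocabulary (carried, unused by metrics)
    for proband_id in list(families):
        k = int(rng.integers(2, 6))
        terms = rng.choice(len(_HPO_VOCAB), size=k, replace=False)
        fam = families[proband_id]
        families[proband_id] = FamilyInfo(
            family_id=fam.family_id,
            proband_id=fam.proband_id,
            members=fam.members,
            hpo_terms=frozenset(_HPO_VOCAB[t] for t in terms),
        )

    decoys = tuple(_sample_variants(rng, cfg.decoy_pool_size, causal))
    return Challenge(
        config=cfg,
        families=families,
        answer_key=AnswerKey(entries),
        decoy_pool=decoys,
        inheritance=inheritance_of,
    )


def generate_model_submission(
    challenge: Challenge,
    skill: SkillProfile,
    seed: int | np.random.Generator | None = None,
    team_id: str = "sim",
    model_id: str = "model1",
    miscalibrated: bool = False,
) -> ModelSubmission:
    """Draw a submission under a skill profile.

    Per solved proband an outcome band is drawn from ``band_probs``; unless a
    miss, the causal record (the full required set for ALL_OF answers, one
    member for ANY_OF answers) is placed at a uniform-random rank inside that
    band among decoy records.  EPCRs are drawn from the causal/decoy Beta laws
    and sorted non-increasing so file order, rank and EPCR are mutually
    consistent; ``miscalibrated=True`` skips the sort to exercise the
    EPCR-monotonicity warning path.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = skill.n_preds_per_proband
    pool = challenge.decoy_pool
    band_probs = np.asarray(skill.band_probs)
    a_c, b_c = skill.epcr_causal
    a_d, b_d = skill.epcr_decoy

    predictions: dict[str, list[PredictionRecord]] = {}
    for proband_id, _fam in challenge.families.items():
        entry = challenge.answer_key[proband_id]
        causal_rank: int | None = None
        causal_variants: frozenset[VariantKey] | None = None
        if entry.solved:
            band = int(rng.choice(6, p=band_probs))
            if band < 5:
                lo, hi = BAND_RANGES[band]
                hi = min(hi, n)
                causal_rank = int(rng.integers(lo, hi + 1))
                if entry.match_mode is MatchMode.ANY_OF:
                    members = sorted(entry.required_set, key=str)
                    causal_variants = frozenset({members[rng.integers(0, len(members))]})
                else:
                    causal_variants = entry.required_set

        n_decoys = n - (1 if causal_rank is not None else 0)
        decoy_idx = rng.choice(len(pool), size=n_decoys, replace=False)
        decoys = iter(pool[j] for j in decoy_idx)

        epcrs = rng.beta(a_d, b_d, size=n)
        if causal_rank is not None:
            epcrs[0] = rng.beta(a_c, b_c)
        if not miscalibrated:
            epcrs = np.sort(epcrs)[::-1]

        records: list[PredictionRecord] = []
        for rank in range(1, n + 1):
            if rank == causal_rank:
                variants = causal_variants
            else:
                variants = frozenset({next(decoys)})
            records.append(
                PredictionRecord(
                    proband_id=proband_id,
                    variants=variants,
                    epcr=float(epcrs[rank - 1]),
                    rank=rank,
                )
            )
        predictions[proband_id] = records
    return ModelSubmission(team_id=team_id, model_id=model_id, predictions=predictions)


def run_recovery_experiment(
    n_replicates: int = 100,
    seed: int | None = 0,
    skills: list[SkillProfile] | None = None,
    n_solved: int = 14,
    n_unsolved: int = 16,
) -> dict:
    """Metric-recovery experiment: simulate, assess, compare with expectation.

    Each replicate generates a fresh challenge and one submission per skill
    profile, scores them against the answer key, and records the assessed mean
    rank points.  Returns the score matrix (replicates × models), the analytic
    expectations, and the fraction of replicates in which the assessed scores
    strictly recover the true (expected) skill ordering.
    """
    from .matching import score_model
    from .metrics import mean_rank_points

    if skills is None:
        skills = graded_skill_ladder()
    expected = np.array([expected_mean_rank_points(s) for s in skills])
    order = np.argsort(-expected, kind="stable")
    rng = np.random.default_rng(seed)
    scores = np.empty((n_replicates, len(skills)))
    for rep in range(n_replicates):
        cfg = ChallengeConfig(
            n_solved=n_solved,
            n_unsolved=n_unsolved,
            seed=int(rng.integers(0, 2**31)),
        )
        challenge = generate_challenge(cfg)
        for j, skill in enumerate(skills):
            sub = generate_model_submission(challenge, skill, seed=rng, model_id=f"m{j}")
            scores[rep, j] = mean_rank_points(score_model(sub, challenge.answer_key))
    ordered_scores = scores[:, order]
    recovered = np.all(ordered_scores[:, :-1] > ordered_scores[:, 1:], axis=1)
    return {
        "scores": scores,
        "expected": expected,
        "ordering_recovery_rate": float(np.mean(recovered)),
        "n_replicates": n_replicates,
    }


def write_challenge(
    challenge: Challenge,
    out_dir: str | Path,
    submissions: dict[str, ModelSubmission] | None = None,
    manifest_extra: dict | None = None,
) -> None:
    """Write a challenge directory: families.ped, hpo.tsv, answer_key.tsv,
    one submission TSV per synthetic model, and a manifest of parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped(challenge.families, out / "families.ped")
    write_hpo(challenge.families, out / "hpo.tsv")
    write_answer_key(challenge.answer_key, out / "answer_key.tsv")
    subs_dir = out / "submissions"
    if submissions:
        subs_dir.mkdir(exist_ok=True)
        for name, sub in submissions.items():
            render_submission(sub, subs_dir / f"{name}.tsv")
    cfg = challenge.config
    manifest = {
        "n_solved": cfg.n_solved,
        "n_unsolved": cfg.n_unsolved,
        "completeness_mix": {k.value: v for k, v in cfg.completeness_mix.items()},
        "inheritance_mix": {k.value: v for k, v in cfg.inheritance_mix.items()},
        "include_cis_pair": cfg.include_cis_pair,
        "decoy_pool_size": cfg.decoy_pool_size,
        "seed": cfg.seed,
        "models": sorted(submissions) if submissions else [],
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
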