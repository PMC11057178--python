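"""Family metadata: pedigree structure, affected status, HPO terms.

Pedigrees arrive as standard 6-column PED (family, individual, father, mother,
sex, affected) and phenotype terms as a two-column TSV mapping individual id to
comma-separated HPO identifiers.  The amount of familial data available per
proband — proband-only, duo, trio or quad — is derived here and drives the
stratified analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

__all__ = [
    "Completeness",
    "Relation",
    "FamilyMember",
    "FamilyInfo",
    "PedigreeError",
    "load_families",
    "write_ped",
    "write_hpo",
]

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    pass


class Completeness(Enum):
    """Familial sequencing completeness class.

    quad = proband + both parents + ≥1 sibling; trio = proband + both parents;
    duo = proband + exactly one parent; proband_only otherwise (a sibling
    without parental data does not upgrade the class, since phasing needs
    parental genotypes).
    """

    PROBAND_ONLY = "proband_only"
    DUO = "duo"
    TRIO = "trio"
    QUAD = "quad"


class Relation(Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"
    SIBLING = "sibling"


@dataclass(frozen=True, slots=True)
class FamilyMember:
    individual_id: str
    relation: Relation
    affected: bool


@dataclass(frozen=True)
class FamilyInfo:
    family_id: str
    proband_id: str
    members: frozenset[FamilyMember]
    hpo_terms: frozenset[str] = field(default_factory=frozenset)

    @property
    def completeness(self) -> Completeness:
        relations = {m.relation for m in self.members}
        has_mother = Relation.MOTHER in relations
        has_father = Relation.FATHER in relations
        has_sib = Relation.SIBLING in relations
        if has_mother and has_father:
            return Completeness.QUAD if has_sib else Completeness.TRIO
        if has_mother or has_father:
            return Completeness.DUO
        return Completeness.PROBAND_ONLY


def _parse_ped(path: str | Path) -> dict[str, list[tuple[str, str, str, bool]]]:
    """Read PED rows grouped by family: (individual, father, mother, affected)."""
    rows: dict[str, list[tuple[str, str, str, bool]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"line {lineno}: expected 6 whitespace-separated columns")
            fam, ind, father, mother, _sex, aff = parts[:6]
            if aff not in ("1", "2", "0", "-9"):
                raise PedigreeError(f"line {lineno}: affected status {aff!r} not in PED coding")
            rows.setdefault(fam, []).append((ind, father, mother, aff == "2"))
    return rows


def _classify_family(family_id: str, rows: list[tuple[str, str, str, bool]]) -> FamilyInfo:
    ids = {r[0] for r in rows}
    parents_of: dict[str, set[str]] = {}
    for ind, father, mother, _aff in rows:
        parents_of[ind] = {p for p in (father, mother) if p not in ("0", "")}
    all_parents = set().union(*parents_of.values()) if parents_of else set()

    # The proband is the first affected non-parent (file order); any further
    # affected non-parent must share a listed parent with the proband (sibling).
    candidates = [r for r in rows if r[3] and r[0] not in all_parents]
    if not candidates:
        raise PedigreeError(f"family {family_id}: no affected individual flagged as proband")
    proband_row = candidates[0]
    proband_id = proband_row[0]
    proband_parents = parents_of[proband_id]
    for ind, _f, _m, _aff in candidates[1:]:
        if not (parents_of[ind] & proband_parents):
            raise PedigreeError(
                f"family {family_id}: >1 affected individual flagged as proband "
                f"({proband_id!r}, {ind!r} share no listed parent)"
            )

    father_id, mother_id = proband_row[1], proband_row[2]
    members: set[FamilyMember] = set()
    for ind, _f, _m, aff in rows:
        if ind == proband_id:
            rel = Relation.PROBAND
        elif ind == father_id:
            rel = Relation.FATHER
        elif ind == mother_id:
            rel = Relation.MOTHER
        elif parents_of[ind] & proband_parents:
            rel = Relation.SIBLING
        else:
            raise PedigreeError(
                f"family {family_id}: individual {ind!r} has no recognizable relation "
                f"to proband {proband_id!r}"
            )
        members.add(FamilyMember(ind, rel, aff))
    return FamilyInfo(family_id=family_id, proband_id=proband_id, members=frozenset(members))


def _parse_hpo(path: str | Path) -> dict[str, frozenset[str]]:
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise PedigreeError(f"HPO line {lineno}: expected 2 tab-separated columns")
            ind, terms_s = parts[0], parts[1]
            terms[ind] = frozenset(t.strip() for t in terms_s.split(",") if t.strip())
    return terms


def load_families(ped_path: str | Path, hpo_path: str | Path | None = None) -> dict[str, FamilyInfo]:
    """Load pedigrees (+ optional HPO terms), keyed by proband id.

    Probands without an HPO row get an empty term set with a logged warning.
    """
    hpo = _parse_hpo(hpo_path) if hpo_path is not None else {}
    families: dict[str, FamilyInfo] = {}
    for fam_id, rows in _parse_ped(ped_path).items():
        info = _classify_family(fam_id, rows)
        if info.proband_id in families:
            raise PedigreeError(f"proband {info.proband_id!r} appears in more than one family")
        proband_terms = hpo.get(info.proband_id)
        if proband_terms is None:
            if hpo_path is not None:
                logger.warning("proband %s has no HPO terms", info.proband_id)
            proband_terms = frozenset()
        families[info.proband_id] = FamilyInfo(
            family_id=info.family_id,
            proband_id=info.proband_id,
            members=info.members,
            hpo_terms=proband_terms,
        )
    return families


_PED_SEX = {Relation.MOTHER: "2", Relation.FATHER: "1"}


def write_ped(families: dict[str, FamilyInfo], path: str | Path) -> None:
    """Write families as standard 6-column PED (proband listed first)."""
    with open(path, "w") as fh:
        for info in families.values():
            by_rel: dict[Relation, list[FamilyMember]] = {}
            for m in info.members:
                by_rel.setdefault(m.relation, []).append(m)
            father = by_rel.get(Relation.FATHER, [None])[0]
            mother = by_rel.get(Relation.MOTHER, [None])[0]
            father_id = father.individual_id if father else "0"
            mother_id = mother.individual_id if mother else "0"
            ordered = sorted(info.members, key=lambda m: (m.relation != Relation.PROBAND, m.individual_id))
            for m in ordered:
                if m.relation in (Relation.PROBAND, Relation.SIBLING):
                    f, mo, sex = father_id, mother_id, "0"
                else:
                    f, mo, sex = "0", "0", _PED_SEX[m.relation]
                fh.write(
                    f"{info.family_id}\t{m.individual_id}\t{f}\t{mo}\t{sex}\t"
                    f"{'2' if m.affected else '1'}\n"
                )


def write_hpo(families: dict[str, FamilyInfo], path: str | Path) -> None:
    with open(path, "w") as fh:
        for info in families.values():
            if info.hpo_terms:
                fh.write(f"{info.proband_id}\t{','.join(sorted(info.hpo_terms))}\n")
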