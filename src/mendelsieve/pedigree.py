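"""PED-format pedigree parsing, validation, and relationship queries.

Pedigrees use standard 6-column PED semantics: family id, individual id,
father id, mother id, sex (1=male, 2=female, other=unknown) and phenotype
(1=unaffected, 2=affected, 0/-9=unknown). A parent id of "0" means the
parent is not in the pedigree. Extra columns are ignored. Individual ids
(including Roman-numeral style labels such as "II.1") are opaque strings;
generation structure comes only from the parent links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class PedigreeError(ValueError):
    """Malformed PED content or an internally inconsistent pedigree."""


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    UNAFFECTED = "unaffected"
    AFFECTED = "affected"
    UNKNOWN = "unknown"


_SEX_FROM_CODE = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_CODE = {
    "1": Affection.UNAFFECTED,
    "2": Affection.AFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_AFF_TO_CODE = {
    Affection.UNAFFECTED: "1",
    Affection.AFFECTED: "2",
    Affection.UNKNOWN: "0",
}


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids of ``None`` mean founder."""

    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A single family: ordered members with resolved, acyclic parent links."""

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {m.individual_id: m for m in self.members}
        self.validate()

    # -- queries ---------------------------------------------------------

    def member(self, individual_id: str) -> Individual:
        try:
            return self._index[individual_id]
        except KeyError:
            raise PedigreeError(
                f"unknown individual {individual_id!r} in family {self.family_id!r}"
            ) from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    def parents_of(
        self, individual_id: str
    ) -> tuple[Optional[Individual], Optional[Individual]]:
        """(father, mother) of a member; founders give (None, None)."""
        ind = self.member(individual_id)
        father = self._index.get(ind.father_id) if ind.father_id else None
        mother = self._index.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            m
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        ]

    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def affected_members(self) -> list[Individual]:
        return [m for m in self.members if m.affected is Affection.AFFECTED]

    def unaffected_members(self) -> list[Individual]:
        return [m for m in self.members if m.affected is Affection.UNAFFECTED]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"member {m.individual_id!r} belongs to family "
                    f"{m.family_id!r}, not {self.family_id!r}"
                )
            if m.individual_id in seen:
                raise PedigreeError(
                    f"duplicate individual id {m.individual_id!r} "
                    f"in family {self.family_id!r}"
                )
            seen.add(m.individual_id)
        for m in self.members:
            for parent_id, expected in (
                (m.father_id, Sex.MALE),
                (m.mother_id, Sex.FEMALE),
            ):
                if parent_id is None:
                    continue
                parent = self._index.get(parent_id)
                if parent is None:
                    raise PedigreeError(
                        f"individual {m.individual_id!r} references parent "
                        f"{parent_id!r} absent from family {self.family_id!r}"
                    )
                if parent.sex not in (expected, Sex.UNKNOWN):
                    raise PedigreeError(
                        f"parent {parent_id!r} of {m.individual_id!r} has "
                        f"sex {parent.sex.value}, expected {expected.value}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative colouring over the parent graph
        WHITE, GRAY, BLACK = 0, 1, 2
        colour = {m.individual_id: WHITE for m in self.members}
        for start in colour:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, bool]] = [(start, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    colour[node] = BLACK
                    continue
                if colour[node] == BLACK:
                    continue
                if colour[node] == GRAY:
                    raise PedigreeError(
                        f"parent cycle involving {node!r} in family "
                        f"{self.family_id!r}"
                    )
                colour[node] = GRAY
                stack.append((node, True))
                ind = self._index[node]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is not None and colour.get(pid) != BLACK:
                        if colour.get(pid) == GRAY:
                            raise PedigreeError(
                                f"parent cycle involving {pid!r} in family "
                                f"{self.family_id!r}"
                            )
                        stack.append((pid, False))


# -- module-level operation surface ------------------------------------------


def parse_ped(text: str) -> list[Pedigree]:
    """Parse 6-column PED content into one Pedigree per family.

    Families appear in order of first mention; members keep file order.
    Raises :class:`PedigreeError` naming the offending line on malformed
    input or dangling parent references.
    """
    families: dict[str, list[Individual]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedigreeError(
                f"PED line {lineno}: expected >=6 columns, got {len(cols)}"
            )
        fam, iid, fid, mid, sex_code, aff_code = cols[:6]
        if aff_code not in _AFF_FROM_CODE:
            raise PedigreeError(
                f"PED line {lineno}: bad phenotype code {aff_code!r}"
            )
        ind = Individual(
            individual_id=iid,
            family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_SEX_FROM_CODE.get(sex_code, Sex.UNKNOWN),
            affected=_AFF_FROM_CODE[aff_code],
        )
        families.setdefault(fam, []).append(ind)
    return [Pedigree(fam, members) for fam, members in families.items()]


def write_ped(pedigrees: Iterable[Pedigree]) -> str:
    """Serialize pedigrees back to 6-column PED text."""
    lines = []
    for ped in pedigrees:
        for m in ped.members:
            lines.append(
                "\t".join(
                    (
                        m.family_id,
                        m.individual_id,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_TO_CODE[m.sex],
                        _AFF_TO_CODE[m.affected],
                    )
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def affected_members(ped: Pedigree) -> list[Individual]:
    """Members with affected status, in pedigree order."""
    return ped.affected_members()


def parents_of(
    ped: Pedigree, individual_id: str
) -> tuple[Optional[Individual], Optional[Individual]]:
    """(father, mother) of a member; founders give (None, None)."""
    return ped.parents_of(individual_id)
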