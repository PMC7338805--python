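"""Pedigree representation and PED file input/output.

A minimal 6-column pre-makeped PED dialect is used throughout:
``family_id individual_id father_id mother_id sex phenotype`` with
``0`` for unknown parents, sex coded 1/2/0 and phenotype coded
1 (unaffected), 2 (affected), 0 (unknown).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_PHENO_CODE = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
_CODE_PHENO = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # "male" | "female" | "unknown"
    status: str = UNKNOWN

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A family: individuals keyed by id, with affection status.

    ``consanguineous`` records known parental relatedness; it is carried
    as metadata (homozygosity mapping assumes it but no operation
    branches on it).
    """

    individuals: dict[str, Individual] = field(default_factory=dict)
    family_id: str = "FAM1"
    consanguineous: bool = False

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in self.individuals:
                    raise ValueError(
                        f"parent {parent!r} of {ind.id!r} is not in the pedigree"
                    )
        if not self.affected:
            raise ValueError("pedigree must contain at least one affected individual")

    @property
    def affected(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.status == AFFECTED]

    @property
    def unaffected(self) -> list[str]:
        return [i.id for i in self.individuals.values() if i.status == UNAFFECTED]

    def parents_of_affected(self) -> list[str]:
        out: list[str] = []
        for aid in self.affected:
            ind = self.individuals[aid]
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in out:
                    out.append(parent)
        return out

    def add(self, ind: Individual) -> None:
        self.individuals[ind.id] = ind


_SEX_CODE = {"male": "1", "female": "2", "unknown": "0"}
_CODE_SEX = {"1": "male", "2": "female", "0": "unknown"}


def write_ped(ped: Pedigree, path: str | Path) -> None:
    lines = []
    for ind in ped.individuals.values():
        lines.append(
            "\t".join(
                [
                    ped.family_id,
                    ind.id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    _SEX_CODE.get(ind.sex, "0"),
                    _PHENO_CODE.get(ind.status, "0"),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path, consanguineous: bool = False) -> Pedigree:
    individuals: dict[str, Individual] = {}
    family_id = "FAM1"
    rows: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line has {len(fields)} fields, expected 6: {line!r}")
        rows.append(fields)
    for fam, iid, fid, mid, sex, pheno in (r[:6] for r in rows):
        family_id = fam
        individuals[iid] = Individual(
            id=iid,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=_CODE_SEX.get(sex, "unknown"),
            status=_CODE_PHENO.get(pheno, UNKNOWN),
        )
    return Pedigree(individuals=individuals, family_id=family_id, consanguineous=consanguineous)


def family_pedigree() -> Pedigree:
    """The study family: three consanguineous couples, three affected children.

    Affected sibs II.2, II.4 and II.7; unaffected sibs II.1, II.3, II.5 and
    II.6; founder parents I.1-I.6. Array genotyping covered the affected
    trio plus II.1 and II.3.
    """
    individuals: dict[str, Individual] = {}
    for i in range(1, 7):
        sex = "male" if i % 2 == 1 else "female"
        individuals[f"I.{i}"] = Individual(id=f"I.{i}", sex=sex, status=UNAFFECTED)
    couples = {
        ("I.1", "I.2"): ["II.1", "II.2", "II.3"],
        ("I.3", "I.4"): ["II.4", "II.5", "II.6"],
        ("I.5", "I.6"): ["II.7"],
    }
    affected = {"II.2", "II.4", "II.7"}
    for (father, mother), children in couples.items():
        for child in children:
            individuals[child] = Individual(
                id=child,
                father_id=father,
                mother_id=mother,
                sex="unknown",
                status=AFFECTED if child in affected else UNAFFECTED,
            )
    return Pedigree(individuals=individuals, family_id="FAM1", consanguineous=True)


ARRAY_SAMPLES: tuple[str, ...] = ("II.2", "II.4", "II.7", "II.1", "II.3")
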