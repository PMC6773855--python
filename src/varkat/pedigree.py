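"""Pedigree containers and PLINK-style PED I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

MISSING = "0"


@dataclass
class Individual:
    family_id: str
    iid: str
    father_id: str = MISSING
    mother_id: str = MISSING
    sex: int = 0  # 1 male, 2 female, 0 unknown
    affected: bool = False

    @property
    def has_parents(self) -> bool:
        return self.father_id != MISSING and self.mother_id != MISSING


@dataclass
class Trio:
    """A proband with both parents, the unit of inheritance-model calling."""

    proband: Individual
    father: Individual
    mother: Individual

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.proband.iid, self.father.iid, self.mother.iid)


@dataclass
class Pedigree:
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {ind.iid: ind for ind in self.individuals}

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def get(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.family_id, []).append(ind)
        return fams

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affected]

    def trios(self, affected_only: bool = True) -> list[Trio]:
        """All (child, father, mother) triples with both parents present."""
        out = []
        for ind in self.individuals:
            if affected_only and not ind.affected:
                continue
            if not ind.has_parents:
                continue
            if ind.father_id in self._by_id and ind.mother_id in self._by_id:
                out.append(
                    Trio(ind, self._by_id[ind.father_id], self._by_id[ind.mother_id])
                )
        return out


def read_ped(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (FID IID FATHER MOTHER SEX PHENO).

    Phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown.
    """
    inds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fid, iid, fat, mot, sex, pheno = line.split()[:6]
        inds.append(
            Individual(
                family_id=fid,
                iid=iid,
                father_id=fat,
                mother_id=mot,
                sex=int(sex),
                affected=pheno == "2",
            )
        )
    return Pedigree(inds)


def write_ped(pedigree: Pedigree | Iterable[Individual], path: str | Path) -> None:
    lines = []
    for ind in pedigree:
        pheno = "2" if ind.affected else "1"
        lines.append(
            f"{ind.family_id}\t{ind.iid}\t{ind.father_id}\t{ind.mother_id}"
            f"\t{ind.sex}\t{pheno}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
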