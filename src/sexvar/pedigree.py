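"""Pedigrees for sex-specific quantitative-genetic breeding designs.

A pedigree is an ordered list of individual records with parent links, sex,
generation index and line label.  The central constructor,
:func:`generate_quantgen_design`, builds the three-generation (GP -> P -> F1)
paternal half-sib design used to partition autosomal additive, dominance and
sex-linked variance components: founder pairs produce one sex-balanced
offspring per grandparental family, those are paired into parental families,
and every parental sire is mated to several dams drawn from distinct other
parental families, giving nested full-sib / paternal half-sib F1 families.

Founders are marked with the sentinel parent token ``"0"`` (the common
pedigree-file convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FOUNDER = "0"

FEMALE = "F"
MALE = "M"

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation", "line", "family"]


class PedigreeFormatError(ValueError):
    """A pedigree file is structurally unreadable (missing columns etc.)."""


class PedigreeIntegrityError(ValueError):
    """A pedigree violates its invariants (bad parent links, sexes, cycles)."""


class DesignError(ValueError):
    """A breeding design is infeasible for the requested parameters."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parents (``"0"`` = founder), sex, bookkeeping."""

    id: str
    sire: str
    dam: str
    sex: str
    generation: int
    line: str = "ANC"
    family: str = ""

    @property
    def is_founder(self) -> bool:
        return self.sire == FOUNDER and self.dam == FOUNDER


@dataclass
class ValidationReport:
    """All invariant violations found in a pedigree; empty means valid."""

    problems: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.problems.append(msg)

    @property
    def ok(self) -> bool:
        return not self.problems

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok


class Pedigree:
    """Topologically ordered, validated collection of :class:`PedigreeRecord`.

    Records are stored so that every parent precedes its offspring; the
    constructor re-sorts if needed and raises :class:`PedigreeIntegrityError`
    if no such order exists (cycles, missing parents, sex-role conflicts).
    """

    def __init__(self, records: Iterable[PedigreeRecord], validate: bool = True):
        records = list(records)
        if validate:
            records = _toposort(records)
            report = _validate_records(records, assume_sorted=True)
            if not report.ok:
                raise PedigreeIntegrityError("; ".join(report.problems))
        self.records: list[PedigreeRecord] = records
        self._index = {r.id: i for i, r in enumerate(records)}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, id_: str) -> PedigreeRecord:
        return self.records[self._index[id_]]

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, Pedigree) and self.records == other.records

    def index_of(self, id_: str) -> int:
        return self._index[id_]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def founders(self) -> list[PedigreeRecord]:
        return [r for r in self.records if r.is_founder]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) array of (sire, dam) positional indices; -1 for founders."""
        out = np.full((len(self.records), 2), -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if not r.is_founder:
                out[i, 0] = self._index[r.sire]
                out[i, 1] = self._index[r.dam]
        return out

    def sexes(self) -> np.ndarray:
        """Boolean array, True where the individual is female."""
        return np.array([r.sex == FEMALE for r in self.records], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.sire, r.dam, r.sex, r.generation, r.line, r.family) for r in self.records],
            columns=PEDIGREE_COLUMNS,
        )

    def subset_lines(self, lines: Sequence[str]) -> "Pedigree":
        keep = set(lines)
        return Pedigree([r for r in self.records if r.line in keep])


def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    """Order records parents-first (stable); raise on cycles / missing parents."""
    by_id: dict[str, PedigreeRecord] = {}
    for r in records:
        if r.id in by_id:
            raise PedigreeIntegrityError(f"duplicate id {r.id!r}")
        by_id[r.id] = r
    order: list[PedigreeRecord] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    for root in records:
        stack = [(root, False)]
        while stack:
            rec, expanded = stack.pop()
            if state.get(rec.id) == 1:
                continue
            if expanded:
                state[rec.id] = 1
                order.append(rec)
                continue
            if state.get(rec.id) == 0:
                raise PedigreeIntegrityError(f"cycle through {rec.id!r}")
            state[rec.id] = 0
            stack.append((rec, True))
            for parent in (rec.dam, rec.sire):
                if parent == FOUNDER:
                    continue
                if parent not in by_id:
                    raise PedigreeIntegrityError(
                        f"unresolvable parent {parent!r} of {rec.id!r}"
                    )
                if state.get(parent) != 1:
                    stack.append((by_id[parent], False))
    return order


def _validate_records(records: list[PedigreeRecord], assume_sorted: bool = False) -> ValidationReport:
    report = ValidationReport()
    seen: dict[str, PedigreeRecord] = {}
    sires: set[str] = set()
    dams: set[str] = set()
    for r in records:
        if r.id in seen:
            report.add(f"duplicate id {r.id!r}")
        seen[r.id] = r
        if r.sex not in (FEMALE, MALE):
            report.add(f"{r.id!r}: invalid sex {r.sex!r}")
        if (r.sire == FOUNDER) != (r.dam == FOUNDER):
            report.add(f"{r.id!r}: exactly one parent founder-marked")
        if r.sire != FOUNDER:
            sires.add(r.sire)
        if r.dam != FOUNDER:
            dams.add(r.dam)

    position = {r.id: i for i, r in enumerate(records)}
    for r in records:
        if r.is_founder:
            continue
        for parent, role, want_sex in ((r.sire, "sire", MALE), (r.dam, "dam", FEMALE)):
            if parent not in seen:
                report.add(f"{r.id!r}: missing {role} {parent!r}")
                continue
            if seen[parent].sex != want_sex:
                report.add(f"{r.id!r}: {role} {parent!r} is not {want_sex}")
            if assume_sorted and position[parent] >= position[r.id]:
                report.add(f"{r.id!r}: {role} {parent!r} does not precede it")
    both = sires & dams
    for id_ in sorted(both):
        report.add(f"{id_!r} appears as both sire and dam")
    if not assume_sorted:
        try:
            _toposort(records)
        except PedigreeIntegrityError as exc:
            report.add(str(exc))
    return report


def validate_pedigree(ped: "Pedigree | Iterable[PedigreeRecord]") -> ValidationReport:
    """Collect every invariant violation; an empty report means the pedigree is valid."""
    records = list(ped.records if isinstance(ped, Pedigree) else ped)
    try:
        ordered = _toposort(records)
    except PedigreeIntegrityError as exc:
        report = _validate_records(records)
        if str(exc) not in report.problems:
            report.add(str(exc))
        return report
    return _validate_records(ordered, assume_sorted=True)


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (columns id,sire,dam,sex,generation,line,family).

    Records may appear in any order; the result is re-sorted parents-first.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "sire", "dam", "sex") if c not in df.columns]
    if missing:
        raise PedigreeFormatError(f"missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PedigreeRecord(
                id=row.id,
                sire=row.sire,
                dam=row.dam,
                sex=row.sex,
                generation=int(getattr(row, "generation", 0) or 0),
                line=getattr(row, "line", "ANC") or "ANC",
                family=getattr(row, "family", "") or "",
            )
        )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write the pedigree as CSV; ``read_pedigree(write_pedigree(p)) == p``."""
    ped.to_frame().to_csv(path, index=False)


@dataclass
class DesignParams:
    """Parameters of the GP -> P -> F1 half-sib breeding design.

    Defaults give 120 grandparental families reduced to 60 parental families,
    each parental sire mated to 4 dams from distinct families, and 7 measured
    offspring per F1 full-sib family -- roughly two thousand individuals.
    """

    n_gp_families: int = 120
    n_p_families: int = 60
    dams_per_sire: int = 4
    offspring_per_f1_family: int = 7
    sex_ratio: float = 0.5
    line: str = "ANC"
    seed: int | None = None

    def validate(self) -> None:
        if min(self.n_gp_families, self.n_p_families, self.dams_per_sire,
               self.offspring_per_f1_family) < 1:
            raise DesignError("all design counts must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise DesignError("sex_ratio must be a probability")
        if 2 * self.n_p_families > self.n_gp_families:
            raise DesignError(
                "need one sex-balanced GP offspring per P parent: "
                f"{self.n_p_families} P families require {2 * self.n_p_families} GP families"
            )
        # every sire's dams come from distinct *other* parental families
        if self.n_p_families < 2 or self.dams_per_sire > self.n_p_families - 1:
            raise DesignError("dams_per_sire must leave enough distinct donor families")


# reduced preset of the same design: identical structure at roughly 600
# measured individuals, used where a full-size fit would be wasteful
REDUCED_DESIGN = DesignParams(n_gp_families=60, n_p_families=30,
                              dams_per_sire=4, offspring_per_f1_family=5)


def generate_quantgen_design(params: DesignParams | None = None,
                             seed: int | None = None) -> Pedigree:
    """Generate the three-generation half-sib design pedigree.

    Structure: each grandparental (GP) family is an unrelated founder pair with
    one offspring of predetermined, sex-balanced sex; GP offspring are randomly
    paired into parental (P) families; from every P family one son and
    ``dams_per_sire`` daughters are taken, and each P son is mated to
    ``dams_per_sire`` P daughters from distinct other families, yielding
    ``n_p_families * dams_per_sire`` F1 full-sib families nested in paternal
    half-sib groups.
    """
    params = params or DesignParams()
    params.validate()
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    line = params.line
    records: list[PedigreeRecord] = []

    # generation 0: founder pairs, one pair per GP family
    # generation 1: one offspring per GP family, sexes balanced overall
    n_gp = params.n_gp_families
    gp_sex = np.array([FEMALE, MALE] * (n_gp // 2) + [FEMALE] * (n_gp % 2))
    rng.shuffle(gp_sex)
    gp_offspring: list[PedigreeRecord] = []
    for f in range(n_gp):
        sire = f"{line}_G0_S{f}"
        dam = f"{line}_G0_D{f}"
        fam = f"GP{f}"
        records.append(PedigreeRecord(sire, FOUNDER, FOUNDER, MALE, 0, line, fam))
        records.append(PedigreeRecord(dam, FOUNDER, FOUNDER, FEMALE, 0, line, fam))
        child = PedigreeRecord(f"{line}_G1_{f}", sire, dam, gp_sex[f], 1, line, fam)
        records.append(child)
        gp_offspring.append(child)

    females = [r for r in gp_offspring if r.sex == FEMALE]
    males = [r for r in gp_offspring if r.sex == MALE]
    if len(females) < params.n_p_families or len(males) < params.n_p_families:
        raise DesignError("not enough sex-balanced GP offspring to form P families")
    rng.shuffle(females)
    rng.shuffle(males)

    # generation 2: P families = random (GP daughter x GP son) pairs; from each we
    # later use 1 son and dams_per_sire daughters, so generate exactly those.
    n_p = params.n_p_families
    k = params.dams_per_sire
    p_sons: list[PedigreeRecord] = []
    p_daughters: list[list[PedigreeRecord]] = []
    for p in range(n_p):
        sire, dam = males[p], females[p]
        fam = f"P{p}"
        son = PedigreeRecord(f"{line}_G2_P{p}_M", sire.id, dam.id, MALE, 2, line, fam)
        records.append(son)
        p_sons.append(son)
        daughters = []
        for j in range(k):
            d = PedigreeRecord(f"{line}_G2_P{p}_F{j}", sire.id, dam.id, FEMALE, 2, line, fam)
            records.append(d)
            daughters.append(d)
        p_daughters.append(daughters)

    # generation 3: each P son mates k dams from k distinct other P families.
    # A random cyclic-shift assignment guarantees feasibility: sire from family
    # perm[i] receives the j-th daughter of family perm[(i + j + 1) % n_p].
    perm = rng.permutation(n_p)
    n_off = params.offspring_per_f1_family
    f1_count = 0
    for i in range(n_p):
        sire = p_sons[perm[i]]
        for j in range(k):
            donor = perm[(i + j + 1) % n_p] if n_p > 1 else perm[i]
            dam = p_daughters[donor][j]
            fam = f"F1_{f1_count}"
            child_sexes = np.where(rng.random(n_off) < params.sex_ratio, FEMALE, MALE)
            for c, sx in enumerate(child_sexes):
                records.append(
                    PedigreeRecord(f"{line}_G3_{f1_count}_{c}", sire.id, dam.id,
                                   str(sx), 3, line, fam)
                )
            f1_count += 1

    return Pedigree(records)

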