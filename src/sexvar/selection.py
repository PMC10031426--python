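"""Family-truncation artificial selection on simulated populations.

Three regimes act on full-sib family means each generation:

* ``SA`` (sexually antagonistic): keep the families with the highest sexual
  size dimorphism, measured as mean female / mean male body weight.
* ``ML`` (male-limited): keep the families with the smallest mean male
  weight; females are not directly selected.
* ``RS`` (random selection): keep a uniformly random family set -- the drift
  control.

Each generation the top ``n_selected`` of ``n_families`` families are crossed
fully factorially excluding within-family (full-sib) crosses, so every
ordered pair of distinct selected families yields one new full-sib family:
``n_selected * (n_selected - 1)`` families, restoring ``n_families`` when 8
of 56 are kept.  After the final selection round the top families are pooled
and carried through one or more generations of panmictic random mating, which
is the population the follow-up variance-decomposition design samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, DesignError, Pedigree, PedigreeRecord
from .simulator import (
    GeneticArchitecture,
    GenotypeTable,
    simulate_genotypes,
    simulate_phenotypes,
)

REGIMES = ("SA", "ML", "RS")


class SelectionError(ValueError):
    pass


@dataclass
class RegimeSpec:
    regime: str = "SA"
    n_families: int = 56
    n_selected: int = 8
    n_generations: int = 10
    # collected per family, sexes balanced; must allow 1 male + (n_selected-1)
    # females per selected family for the factorial cross
    offspring_per_family: int = 16
    panmictic_generations: int = 1  # 1 for replicate a, 2 for replicate b
    replicate: str = "a"
    seed: int | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise SelectionError(f"regime must be one of {REGIMES}")
        if not 0 < self.n_selected < self.n_families:
            raise SelectionError("need 0 < n_selected < n_families")
        if min(self.n_generations, self.offspring_per_family) < 0:
            raise SelectionError("counts must be non-negative")
        need = (self.n_selected - 1) + 1
        if self.n_generations > 0 and self.offspring_per_family < 2 * need - 1:
            raise SelectionError(
                f"offspring_per_family={self.offspring_per_family} cannot reliably "
                f"supply 1 male and {self.n_selected - 1} females per selected family"
            )


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Sex-balanced collection: half female, half male, odd one at random."""
    n_f = n // 2 + (int(rng.integers(2)) if n % 2 else 0)
    sexes = np.array([FEMALE] * n_f + [MALE] * (n - n_f), dtype=object)
    rng.shuffle(sexes)
    return sexes


@dataclass
class FamilyStats:
    family: str
    mean_f: float
    mean_m: float
    n_f: int
    n_m: int

    @property
    def ssd_ratio(self) -> float:
        if self.n_m == 0 or self.n_f == 0 or self.mean_m <= 0:
            return np.nan
        return self.mean_f / self.mean_m


@dataclass
class Cohort:
    """One generation of measured individuals with their genotypes."""

    phen: pd.DataFrame          # id, sex, value, family, sire, dam
    genos: GenotypeTable        # aligned with phen rows
    generation: int = 0

    def __len__(self) -> int:
        return len(self.phen)

    @property
    def female(self) -> np.ndarray:
        return (self.phen["sex"] == FEMALE).to_numpy()


@dataclass
class GenerationRecord:
    generation: int
    stats: list[FamilyStats]
    selected: list[str]
    mean_f: float
    mean_m: float
    sel_diff_f: float
    sel_diff_m: float
    freqs: np.ndarray  # allele frequency per locus, architecture order


@dataclass
class SelectionHistory:
    regime: str
    replicate: str
    records: list[GenerationRecord] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "generation": r.generation,
                "mean_f": r.mean_f,
                "mean_m": r.mean_m,
                "sel_diff_f": r.sel_diff_f,
                "sel_diff_m": r.sel_diff_m,
                "n_selected": len(r.selected),
            }
            for r in self.records
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "regime", self.regime)
        df.insert(1, "replicate", self.replicate)
        return df


def family_stats(phen: pd.DataFrame) -> list[FamilyStats]:
    """Per-family sex-specific means and counts of the focal cohort.

    Families with no measured offspring are absent by construction; families
    lacking one sex get NaN for that sex's mean and an undefined SSD ratio.
    """
    out = []
    for fam, grp in phen.groupby("family", sort=True):
        f = grp.loc[grp["sex"] == FEMALE, "value"]
        m = grp.loc[grp["sex"] == MALE, "value"]
        out.append(FamilyStats(str(fam), float(f.mean()) if len(f) else np.nan,
                               float(m.mean()) if len(m) else np.nan,
                               int(len(f)), int(len(m))))
    return out


def rank_and_select(stats: list[FamilyStats], spec: RegimeSpec,
                    rng: np.random.Generator | int | None = None) -> list[str]:
    """Pick ``n_selected`` family labels under the regime's criterion.

    SA ranks by descending female/male weight ratio, ML by ascending male
    mean, RS uniformly at random.  Ties break by a seeded random key so the
    choice is deterministic given the generator state.  Families that cannot
    be ranked (missing a required sex) are excluded.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if spec.regime == "RS":
        labels = [s.family for s in stats]
        if len(labels) < spec.n_selected:
            raise SelectionError("too few families to select from")
        pick = rng.choice(len(labels), size=spec.n_selected, replace=False)
        return [labels[i] for i in sorted(pick)]

    if spec.regime == "SA":
        keyed = [(s.ssd_ratio, s) for s in stats]
        reverse = True
    else:  # ML: smallest male mean, no selection on females
        keyed = [(s.mean_m if s.n_m > 0 else np.nan, s) for s in stats]
        reverse = False
    rankable = [(k, s) for k, s in keyed if np.isfinite(k)]
    if len(rankable) < spec.n_selected:
        raise SelectionError(
            f"only {len(rankable)} rankable families, need {spec.n_selected}"
        )
    tiebreak = rng.random(len(rankable))
    order = sorted(range(len(rankable)),
                   key=lambda i: (rankable[i][0], tiebreak[i]), reverse=reverse)
    return [rankable[i][1].family for i in order[: spec.n_selected]]


def factorial_cross(selected: list[str], cohort: Cohort,
                    rng: np.random.Generator | int | None = None,
                    generation: int | None = None) -> list[tuple[str, str, str]]:
    """Full-factorial crosses among selected families, excluding full sibs.

    From every selected family one virgin male and ``len(selected) - 1``
    virgin females are drawn at random; the male of family *i* is mated once
    to one female from every other family *j*, so each ordered pair of
    distinct families yields exactly one cross and each female mates once.
    Returns ``n(n-1)`` (new-family-label, sire-id, dam-id) triples; the
    offspring records are generated from these by the regime driver.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    phen = cohort.phen
    gen = cohort.generation + 1 if generation is None else generation
    n_sel = len(selected)
    males: dict[str, str] = {}
    females: dict[str, list[str]] = {}
    for fam in selected:
        grp = phen[phen["family"] == fam]
        ms = grp.loc[grp["sex"] == MALE, "id"].tolist()
        fs = grp.loc[grp["sex"] == FEMALE, "id"].tolist()
        if not ms:
            raise DesignError(f"family {fam!r} cannot supply a sire")
        if len(fs) < n_sel - 1:
            raise DesignError(
                f"family {fam!r} has {len(fs)} virgin females, needs {n_sel - 1}"
            )
        males[fam] = ms[int(rng.integers(len(ms)))]
        pick = rng.choice(len(fs), size=n_sel - 1, replace=False)
        females[fam] = [fs[i] for i in pick]

    crosses = []
    counter = 0
    for i, sire_fam in enumerate(selected):
        for dam_fam in selected:
            if dam_fam == sire_fam:
                continue
            dam = females[dam_fam].pop()
            crosses.append(
                (f"G{gen}_fam{counter}", males[sire_fam], dam)
            )
            counter += 1
    return crosses


def _offspring_cohort(crosses: list[tuple[str, str, str]], cohort: Cohort,
                      arch: GeneticArchitecture, n_offspring: int,
                      generation: int, line: str, rng: np.random.Generator,
                      sex_ratio: float = 0.5) -> Cohort:
    """Build, genotype and phenotype the offspring of the given crosses."""
    records = []
    parent_ids = set()
    for fam, sire, dam in crosses:
        parent_ids.update((sire, dam))
        sexes = _balanced_sexes(n_offspring, rng)
        for c, sx in enumerate(sexes):
            records.append(
                PedigreeRecord(f"{line}_{fam}_{c}", sire, dam, str(sx),
                               generation, line, fam)
            )
    # minimal two-generation pedigree: the parents (as founders) + offspring
    idx = {pid: cohort.phen.index[cohort.phen["id"] == pid][0] for pid in parent_ids}
    parent_recs = [
        PedigreeRecord(pid, "0", "0",
                       FEMALE if cohort.female[idx[pid]] else MALE,
                       generation - 1, line, "")
        for pid in sorted(parent_ids)
    ]
    ped = Pedigree(parent_recs + records, validate=False)
    rows = np.array([idx[r.id] for r in parent_recs])
    founder_genos = cohort.genos.subset(rows, [r.id for r in parent_recs])
    genos = simulate_genotypes(ped, arch, seed=int(rng.integers(2**31)),
                               founder_genotypes=founder_genos)
    phen = simulate_phenotypes(ped, genos, arch, seed=int(rng.integers(2**31)))
    keep = phen["generation"] == generation
    rows_keep = np.where(keep.to_numpy())[0]
    phen = phen.loc[keep, ["id", "sex", "value", "family", "dam"]].reset_index(drop=True)
    phen["sire"] = [r.sire for r in records]
    return Cohort(phen, genos.subset(rows_keep, phen["id"].tolist()), generation)


def founder_population(arch: GeneticArchitecture, spec: RegimeSpec,
                       rng: np.random.Generator | int | None = None,
                       line: str = "BASE") -> Cohort:
    """Hardy-Weinberg founder pairs crossed into the first cohort of families."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    records = []
    for fam in range(spec.n_families):
        records.append(PedigreeRecord(f"{line}_S{fam}", "0", "0", MALE, 0, line, ""))
        records.append(PedigreeRecord(f"{line}_D{fam}", "0", "0", FEMALE, 0, line, ""))
        sexes = _balanced_sexes(spec.offspring_per_family, rng)
        for c, sx in enumerate(sexes):
            records.append(
                PedigreeRecord(f"{line}_F{fam}_{c}", f"{line}_S{fam}", f"{line}_D{fam}",
                               str(sx), 1, line, f"G1_fam{fam}")
            )
    ped = Pedigree(records, validate=False)
    genos = simulate_genotypes(ped, arch, seed=int(rng.integers(2**31)))
    phen = simulate_phenotypes(ped, genos, arch, seed=int(rng.integers(2**31)))
    keep = phen["generation"] == 1
    rows = np.where(keep.to_numpy())[0]
    phen = phen.loc[keep, ["id", "sex", "value", "family", "dam"]].reset_index(drop=True)
    sires = {r.id: r.sire for r in records if not r.is_founder}
    phen["sire"] = phen["id"].map(sires)
    return Cohort(phen, genos.subset(rows, phen["id"].tolist()), 1)


def allele_frequencies(cohort: Cohort, arch: GeneticArchitecture) -> np.ndarray:
    """Current allele frequencies per locus, in architecture order.

    X counts weight females twice (two copies); Y counts males only.
    """
    female = cohort.female
    aut_loci, x_loci, y_loci = arch.split()
    it = {
        "A": iter(cohort.genos.aut.mean(axis=0) / 2.0) if aut_loci else None,
        "X": iter(cohort.genos.x.sum(axis=0) / np.where(female, 2, 1).sum())
             if x_loci else None,
        "Y": iter(np.clip(cohort.genos.y[~female], 0, None).astype(float).mean(axis=0))
             if y_loci and (~female).any() else iter(np.full(len(y_loci), np.nan)),
    }
    out = np.empty(len(arch.loci))
    for k, l in enumerate(arch.loci):
        out[k] = next(it[l.chrom])
    return out


def _record_generation(cohort: Cohort, arch: GeneticArchitecture,
                       stats: list[FamilyStats], selected: list[str],
                       parent_ids: set[str]) -> GenerationRecord:
    phen = cohort.phen
    female = cohort.female
    mean_f = float(phen.loc[female, "value"].mean())
    mean_m = float(phen.loc[~female, "value"].mean())
    sel = phen["id"].isin(parent_ids).to_numpy()
    sel_f = phen.loc[sel & female, "value"]
    sel_m = phen.loc[sel & ~female, "value"]
    return GenerationRecord(
        generation=cohort.generation,
        stats=stats,
        selected=list(selected),
        mean_f=mean_f,
        mean_m=mean_m,
        sel_diff_f=float(sel_f.mean() - mean_f) if len(sel_f) else 0.0,
        sel_diff_m=float(sel_m.mean() - mean_m) if len(sel_m) else 0.0,
        freqs=allele_frequencies(cohort, arch),
    )


def run_regime(arch: GeneticArchitecture, spec: RegimeSpec,
               founders: Cohort | None = None,
               ) -> tuple[SelectionHistory, Cohort]:
    """Run a full selection experiment; returns history + terminal cohort.

    ``n_generations`` rounds of measure -> rank -> select -> factorial cross,
    then a final selection whose families are pooled and random-mated for
    ``panmictic_generations`` generations.  The terminal cohort carries the
    evolved genotypes and seeds the follow-up quantitative-genetics design.
    """
    rng = np.random.default_rng(spec.seed)
    line = f"{spec.regime}{spec.replicate}"
    cohort = founders if founders is not None else founder_population(arch, spec, rng, line)
    history = SelectionHistory(spec.regime, spec.replicate)

    for g in range(spec.n_generations):
        stats = family_stats(cohort.phen)
        selected = rank_and_select(stats, spec, rng)
        gen = cohort.generation + 1
        crosses = factorial_cross(selected, cohort, rng, generation=gen)
        parent_ids = {x for _, s, d in crosses for x in (s, d)}
        history.records.append(
            _record_generation(cohort, arch, stats, selected, parent_ids)
        )
        cohort = _offspring_cohort(crosses, cohort, arch,
                                   spec.offspring_per_family, gen, line, rng)

    # terminal selection + pooling into a panmictic population
    stats = family_stats(cohort.phen)
    selected = rank_and_select(stats, spec, rng)
    pooled = cohort.phen["family"].isin(selected).to_numpy()
    parent_ids = set(cohort.phen.loc[pooled, "id"])
    history.records.append(
        _record_generation(cohort, arch, stats, selected, parent_ids)
    )
    rows = np.where(pooled)[0]
    pool = Cohort(cohort.phen.loc[pooled].reset_index(drop=True),
                  cohort.genos.subset(rows, cohort.phen.loc[pooled, "id"].tolist()),
                  cohort.generation)

    for _ in range(spec.panmictic_generations):
        pool = _panmictic_generation(pool, arch, spec, line, rng)
        history.records.append(
            _record_generation(pool, arch, family_stats(pool.phen), [], set())
        )
    return history, pool


def _panmictic_generation(cohort: Cohort, arch: GeneticArchitecture,
                          spec: RegimeSpec, line: str,
                          rng: np.random.Generator) -> Cohort:
    """Random monogamous mating among the pooled individuals."""
    phen = cohort.phen
    female = cohort.female
    f_ids = phen.loc[female, "id"].tolist()
    m_ids = phen.loc[~female, "id"].tolist()
    n_pairs = min(len(f_ids), len(m_ids), spec.n_families)
    if n_pairs == 0:
        raise SelectionError("panmictic pool lacks one sex entirely")
    f_pick = rng.choice(len(f_ids), size=n_pairs, replace=False)
    m_pick = rng.choice(len(m_ids), size=n_pairs, replace=False)
    gen = cohort.generation + 1
    crosses = [
        (f"G{gen}_fam{k}", m_ids[m_pick[k]], f_ids[f_pick[k]])
        for k in range(n_pairs)
    ]
    return _offspring_cohort(crosses, cohort, arch, spec.offspring_per_family,
                             gen, line, rng)


def selection_differential(history: SelectionHistory) -> pd.DataFrame:
    """Per-generation and cumulative selection differentials per sex.

    The differential is (mean of the parents actually used in crosses) minus
    (cohort mean), per sex; cumulative is the running sum over generations.
    Under random selection its expectation is zero.
    """
    df = history.frame()[["generation", "sel_diff_f", "sel_diff_m"]].copy()
    df["cum_diff_f"] = df["sel_diff_f"].cumsum()
    df["cum_diff_m"] = df["sel_diff_m"].cumsum()
    return df


def heterozygosity_trace(history: SelectionHistory,
                         arch: GeneticArchitecture) -> pd.DataFrame:
    """Expected heterozygosity 2pq per locus per generation, with locus tags."""
    rows = []
    for rec in history.records:
        for k, (l, p) in enumerate(zip(arch.loci, rec.freqs)):
            rows.append({
                "generation": rec.generation,
                "locus": k,
                "chrom": l.chrom,
                "label": l.label,
                "p": p,
                "het": 2.0 * p * (1.0 - p),
            })
    return pd.DataFrame(rows)
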