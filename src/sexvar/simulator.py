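"""Synthetic genotypes and phenotypes with a known sex-specific architecture.

Simulation is locus-explicit: every architecture lists biallelic loci with a
chromosome class (autosome, X or Y), a founder frequency of the "1" allele
and sex-specific additive / dominance effects in trait units.  Founders draw
genotypes from Hardy-Weinberg proportions; descendants inherit by Mendelian
transmission (sons take their single X from the dam; the Y is patrilineal and
haploid).  Because allele frequencies are explicit, variances can respond to
selection and drift, which is the point of the whole exercise.

Phenotype = sex intercept + summed genotypic values + maternal effect (one
draw per dam, shared by her offspring and scaled by each offspring's sex) +
Gaussian residual.  Genotypic values per autosomal locus follow the textbook
-a / d / +a coding for 0/1/2 copies using the individual's sex's effects.

:func:`expected_components` returns the exact founder-population variance
components implied by an architecture (optionally at evolved allele
frequencies), which is what the estimation machinery should recover.

A matrix-Gaussian shortcut (:func:`simulate_phenotypes_gaussian`) draws
breeding values directly from the pedigree kernels with specified true
components; it cannot respond to selection and exists for estimator
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .components import VarianceComponents
from .pedigree import Pedigree
from .relatedness import (
    additive_matrix,
    dominance_matrix,
    x_kinship,
    y_patrilines,
)

CHROMOSOMES = ("A", "X", "Y")


@dataclass(frozen=True)
class Locus:
    """One biallelic locus; effects in trait units, ``p`` = founder freq of allele 1."""

    chrom: str = "A"
    p: float = 0.5
    a_f: float = 0.0
    a_m: float = 0.0
    d_f: float = 0.0
    d_m: float = 0.0
    label: str = "neutral"  # free tag, e.g. neutral / SA / concordant / male

    def __post_init__(self):
        if self.chrom not in CHROMOSOMES:
            raise ValueError(f"chrom must be one of {CHROMOSOMES}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")


@dataclass
class GeneticArchitecture:
    """Loci plus maternal-effect, residual and intercept parameters.

    ``v_me`` and ``v_res`` are (female, male) pairs in squared trait units;
    intercepts are in trait units (mg).
    """

    loci: list[Locus] = field(default_factory=list)
    v_me: tuple[float, float] = (0.0, 0.0)
    v_res: tuple[float, float] = (1.0, 1.0)
    mu_f: float = 0.0
    mu_m: float = 0.0

    def __post_init__(self):
        if min(*self.v_me, *self.v_res) < 0:
            raise ValueError("variances must be non-negative")

    def split(self):
        aut = [l for l in self.loci if l.chrom == "A"]
        x = [l for l in self.loci if l.chrom == "X"]
        y = [l for l in self.loci if l.chrom == "Y"]
        return aut, x, y

    def frequencies(self) -> np.ndarray:
        return np.array([l.p for l in self.loci])

    def with_frequencies(self, p: np.ndarray) -> "GeneticArchitecture":
        loci = [replace(l, p=float(pi)) for l, pi in zip(self.loci, p)]
        return GeneticArchitecture(loci, self.v_me, self.v_res, self.mu_f, self.mu_m)


@dataclass
class GenotypeTable:
    """Allele counts per individual.

    ``aut``: autosomal counts 0..2.  ``x``: X counts, 0..2 for females and
    0..1 for hemizygous males.  ``y``: the single Y allele (0/1) for males,
    -1 for females.
    """

    ids: list[str]
    aut: np.ndarray  # (n, n_aut) int8 counts
    x: np.ndarray    # (n, n_x) int8 counts (0..2 females, 0..1 males)
    y: np.ndarray    # (n, n_y) int8 allele (0/1 males, -1 females)

    def subset(self, indices: np.ndarray, ids: list[str]) -> "GenotypeTable":
        return GenotypeTable(ids, self.aut[indices], self.x[indices], self.y[indices])


class GenotypeError(ValueError):
    pass


def simulate_genotypes(ped: Pedigree, arch: GeneticArchitecture,
                       seed: int | None = None,
                       founder_genotypes: GenotypeTable | None = None,
                       founder_ids: list[str] | None = None) -> GenotypeTable:
    """Drop genotypes through a pedigree.

    Founders draw from Hardy-Weinberg at each locus's ``p`` unless
    ``founder_genotypes`` supplies their rows (keyed by ``founder_ids``),
    which is how selection lines carry evolved genotypes forward.
    """
    rng = np.random.default_rng(seed)
    aut_loci, x_loci, y_loci = arch.split()
    p_aut = np.array([l.p for l in aut_loci])
    p_x = np.array([l.p for l in x_loci])
    p_y = np.array([l.p for l in y_loci])
    n = len(ped)
    female = ped.sexes()
    parents = ped.parent_indices()

    aut = np.zeros((n, len(aut_loci)), dtype=np.int8)
    x = np.zeros((n, len(x_loci)), dtype=np.int8)
    y = np.full((n, len(y_loci)), -1, dtype=np.int8)

    provided = {}
    if founder_genotypes is not None:
        keys = founder_ids if founder_ids is not None else founder_genotypes.ids
        provided = {k: i for i, k in enumerate(keys)}

    for j, rec in enumerate(ped.records):
        s, d = parents[j]
        if s < 0:
            if rec.id in provided:
                row = provided[rec.id]
                aut[j] = founder_genotypes.aut[row]
                x[j] = founder_genotypes.x[row]
                y[j] = founder_genotypes.y[row]
                continue
            aut[j] = rng.binomial(2, p_aut) if p_aut.size else 0
            if p_x.size:
                x[j] = rng.binomial(2 if female[j] else 1, p_x)
            if p_y.size and not female[j]:
                y[j] = rng.binomial(1, p_y)
            continue
        # Mendelian transmission from stored allele counts (loci unlinked)
        if p_aut.size:
            from_sire = rng.random(p_aut.size) < aut[s] / 2.0
            from_dam = rng.random(p_aut.size) < aut[d] / 2.0
            aut[j] = from_sire.astype(np.int8) + from_dam.astype(np.int8)
        if p_x.size:
            dam_copies = 2.0 if female[d] else 1.0
            from_dam = (rng.random(p_x.size) < x[d] / dam_copies).astype(np.int8)
            if female[j]:
                x[j] = x[s] + from_dam  # sire passes his whole X to daughters
            else:
                x[j] = from_dam
        if p_y.size and not female[j]:
            y[j] = y[s]
    return GenotypeTable(list(ped.ids), aut, x, y)


def _genetic_values(genos: GenotypeTable, arch: GeneticArchitecture,
                    female: np.ndarray) -> np.ndarray:
    """Summed genotypic values per individual, using each individual's sex."""
    aut_loci, x_loci, y_loci = arch.split()
    n = len(genos.ids)
    g = np.zeros(n)
    if aut_loci:
        a = np.where(female[:, None],
                     np.array([l.a_f for l in aut_loci]),
                     np.array([l.a_m for l in aut_loci]))
        d = np.where(female[:, None],
                     np.array([l.d_f for l in aut_loci]),
                     np.array([l.d_m for l in aut_loci]))
        c = genos.aut.astype(float)
        g += (a * (c - 1.0) + d * (c == 1.0)).sum(axis=1)
    if x_loci:
        a_f = np.array([l.a_f for l in x_loci])
        d_f = np.array([l.d_f for l in x_loci])
        a_m = np.array([l.a_m for l in x_loci])
        c = genos.x.astype(float)
        gf = (a_f * (c - 1.0) + d_f * (c == 1.0)).sum(axis=1)
        gm = (a_m * c).sum(axis=1)  # hemizygous: one copy, effect per copy
        g += np.where(female, gf, gm)
    if y_loci:
        a_m = np.array([l.a_m for l in y_loci])
        c = np.clip(genos.y.astype(float), 0.0, None)
        g += np.where(female, 0.0, (a_m * c).sum(axis=1))
    return g


def simulate_phenotypes(ped: Pedigree, genos: GenotypeTable,
                        arch: GeneticArchitecture, seed: int | None = None,
                        measured_generations: list[int] | None = None) -> pd.DataFrame:
    """Phenotype every (measured) individual of a genotyped pedigree.

    Returns a DataFrame with columns id, sex, value, dam, line, generation,
    family.  The maternal effect is a single standardized draw per dam,
    scaled by the sex-specific maternal SD, hence identical (up to the sex
    scale) across maternal sibs.
    """
    if genos.ids != ped.ids:
        raise GenotypeError("genotype table does not cover this pedigree")
    rng = np.random.default_rng(seed)
    female = ped.sexes()
    g = _genetic_values(genos, arch, female)

    dams = np.array([r.dam for r in ped.records], dtype=object)
    uniq_dams, dam_idx = np.unique(dams, return_inverse=True)
    dam_z = rng.standard_normal(uniq_dams.size)
    me_sd = np.where(female, np.sqrt(arch.v_me[0]), np.sqrt(arch.v_me[1]))
    maternal = np.where(dams == "0", 0.0, me_sd * dam_z[dam_idx])

    res_sd = np.where(female, np.sqrt(arch.v_res[0]), np.sqrt(arch.v_res[1]))
    mu = np.where(female, arch.mu_f, arch.mu_m)
    value = mu + g + maternal + res_sd * rng.standard_normal(len(ped))

    df = pd.DataFrame({
        "id": ped.ids,
        "sex": [r.sex for r in ped.records],
        "value": value,
        "dam": dams,
        "line": [r.line for r in ped.records],
        "generation": [r.generation for r in ped.records],
        "family": [r.family for r in ped.records],
    })
    if measured_generations is not None:
        df = df[df["generation"].isin(measured_generations)].reset_index(drop=True)
    return df


def expected_components(arch: GeneticArchitecture,
                        frequencies: np.ndarray | None = None) -> VarianceComponents:
    """Exact founder-population variance components of an architecture.

    Standard single-locus decomposition: per autosomal locus and sex ``s``,
    the average allelic effect is ``alpha_s = a_s + d_s (q - p)``; then
    ``V_A,s += 2 p q alpha_s^2``, ``V_D,s += (2 p q d_s)^2`` and
    ``COV_Aa += 2 p q alpha_f alpha_m``.  Female X loci decompose like
    autosomes with the female effects; hemizygous male X contributes
    ``p q a_m^2``; the haploid Y contributes ``p q a_m^2``.  Dominance on the
    X is not part of the component vector and presets keep X ``d`` at zero.
    Pass ``frequencies`` to evaluate at evolved allele frequencies.
    """
    arch = arch if frequencies is None else arch.with_frequencies(frequencies)
    c = dict.fromkeys(
        ["VA_fa", "VA_ma", "COV_Aa", "VD_f", "VD_m", "VA_fX", "VA_mX", "VA_Y"], 0.0
    )
    for l in arch.loci:
        p, q = l.p, 1.0 - l.p
        two_pq = 2.0 * p * q
        if l.chrom == "A":
            alpha_f = l.a_f + l.d_f * (q - p)
            alpha_m = l.a_m + l.d_m * (q - p)
            c["VA_fa"] += two_pq * alpha_f**2
            c["VA_ma"] += two_pq * alpha_m**2
            c["COV_Aa"] += two_pq * alpha_f * alpha_m
            c["VD_f"] += (two_pq * l.d_f) ** 2
            c["VD_m"] += (two_pq * l.d_m) ** 2
        elif l.chrom == "X":
            alpha_f = l.a_f + l.d_f * (q - p)
            c["VA_fX"] += two_pq * alpha_f**2
            c["VA_mX"] += p * q * l.a_m**2
        else:  # Y
            c["VA_Y"] += p * q * l.a_m**2
    # COV can exceed the CS bound by float error when r = 1; clip politely
    bound = np.sqrt(c["VA_fa"] * c["VA_ma"])
    c["COV_Aa"] = float(np.clip(c["COV_Aa"], -bound, bound))
    return VarianceComponents(
        **c, VME_f=arch.v_me[0], VME_m=arch.v_me[1],
        VR_f=arch.v_res[0], VR_m=arch.v_res[1],
    )


def simulate_phenotypes_gaussian(ped: Pedigree, comps: VarianceComponents,
                                 seed: int | None = None,
                                 mu_f: float = 0.0, mu_m: float = 0.0,
                                 measured_generations: list[int] | None = None,
                                 ) -> pd.DataFrame:
    """Matrix-Gaussian phenotypes with exactly the requested true components.

    Breeding values are drawn from N(0, G (x) A) with G the 2x2 cross-sex
    autosomal covariance, dominance / X / Y / maternal effects from their
    respective kernels.  No allele frequencies exist here, so this generator
    cannot be selected on; it is the reference input for estimator tests.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    female = ped.sexes()

    A = additive_matrix(ped).values
    jitter = 1e-8 * np.eye(n)
    La = np.linalg.cholesky(A + jitter)
    G = np.array([[comps.VA_fa, comps.COV_Aa], [comps.COV_Aa, comps.VA_ma]])
    # G may be singular at r = 1; use eigen square root
    w, v = np.linalg.eigh(G)
    Lg = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, 2))
    u = (La @ z) @ Lg.T  # columns: female-trait, male-trait breeding values
    g = np.where(female, u[:, 0], u[:, 1])

    if comps.VD_f > 0 or comps.VD_m > 0:
        D = dominance_matrix(ped, A).values
        Ld = np.linalg.cholesky(D + jitter)
        df_ = Ld @ rng.standard_normal(n)
        dm_ = Ld @ rng.standard_normal(n)
        g = g + np.where(female, np.sqrt(comps.VD_f) * df_, np.sqrt(comps.VD_m) * dm_)

    if comps.VA_fX > 0 or comps.VA_mX > 0:
        phi = x_kinship(ped)
        Lx = np.linalg.cholesky(phi + jitter)
        scale = np.where(female, np.sqrt(2.0), 1.0)
        xf = scale * (Lx @ rng.standard_normal(n))
        xm = scale * (Lx @ rng.standard_normal(n))
        g = g + np.where(female, np.sqrt(comps.VA_fX) * xf, np.sqrt(comps.VA_mX) * xm)

    if comps.VA_Y > 0:
        pat = y_patrilines(ped)
        labels = sorted(set(pat.values()))
        eff = dict(zip(labels, np.sqrt(comps.VA_Y) * rng.standard_normal(len(labels))))
        g = g + np.array([0.0 if r.sex == "F" else eff[pat[r.id]] for r in ped.records])

    dams = np.array([r.dam for r in ped.records], dtype=object)
    uniq_dams, dam_idx = np.unique(dams, return_inverse=True)
    dam_z = rng.standard_normal(uniq_dams.size)
    me_sd = np.where(female, np.sqrt(comps.VME_f), np.sqrt(comps.VME_m))
    maternal = np.where(dams == "0", 0.0, me_sd * dam_z[dam_idx])

    res_sd = np.where(female, np.sqrt(comps.VR_f), np.sqrt(comps.VR_m))
    value = np.where(female, mu_f, mu_m) + g + maternal + res_sd * rng.standard_normal(n)

    df = pd.DataFrame({
        "id": ped.ids,
        "sex": [r.sex for r in ped.records],
        "value": value,
        "dam": dams,
        "line": [r.line for r in ped.records],
        "generation": [r.generation for r in ped.records],
        "family": [r.family for r in ped.records],
    })
    if measured_generations is not None:
        df = df[df["generation"].isin(measured_generations)].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def polygenic_preset(n_loci: int = 200, seed: int = 7) -> GeneticArchitecture:
    """Many small concordant autosomal loci: the infinitesimal-ish option."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.12, n_loci)
    p = rng.uniform(0.2, 0.8, n_loci)
    loci = [Locus("A", float(pi), float(ai), float(ai)) for pi, ai in zip(p, a)]
    return GeneticArchitecture(loci, v_res=(1.0, 1.0), mu_f=5.8, mu_m=4.0)


def oligogenic_preset(seed: int = 7) -> GeneticArchitecture:
    """A few large-effect loci on top of a small-effect polygenic background."""
    rng = np.random.default_rng(seed)
    loci = [Locus("A", 0.5, 0.6, 0.6, label="concordant") for _ in range(5)]
    a = rng.normal(0.0, 0.08, 50)
    p = rng.uniform(0.2, 0.8, 50)
    loci += [Locus("A", float(pi), float(ai), float(ai)) for pi, ai in zip(p, a)]
    return GeneticArchitecture(loci, v_res=(1.0, 1.0), mu_f=5.8, mu_m=4.0)


def ancestral_preset() -> GeneticArchitecture:
    """Architecture emulating the ancestral-population pattern.

    High cross-sex additive correlation, female-limited dominance, male X- and
    Y-linked additive variance, no female X variance, no maternal variance.
    """
    loci: list[Locus] = []
    # shared additive background (high r_mf)
    loci += [Locus("A", 0.5, 0.25, 0.25, label="concordant") for _ in range(20)]
    # female-limited dominance loci (no male effect -> VD_m = 0)
    loci += [Locus("A", 0.5, 0.0, 0.0, d_f=0.45, label="Dfem") for _ in range(8)]
    # male X-linked additive (a_f = 0 -> VA_fX = 0)
    loci += [Locus("X", 0.5, 0.0, 0.35, label="maleX") for _ in range(6)]
    # Y haplotype variation
    loci += [Locus("Y", 0.5, 0.0, 0.5, label="Y") for _ in range(3)]
    return GeneticArchitecture(loci, v_me=(0.0, 0.0), v_res=(1.0, 1.0),
                               mu_f=5.8, mu_m=4.0)


def sa_reversal_preset() -> GeneticArchitecture:
    """Sexually antagonistic loci with sex-specific dominance reversal.

    At SA loci allele 1 enlarges both sexes but is dominant in females and
    recessive in males, so heterozygotes are large as females and small as
    males -- the genotype a female-biased dimorphism selection favours.
    Male-limited X and Y loci supply the sex-limited response channel, and a
    concordant polygenic background carries the shared variance.
    """
    loci: list[Locus] = []
    loci += [Locus("A", 0.5, 0.4, 0.4, d_f=0.4, d_m=-0.4, label="SA")
             for _ in range(8)]
    loci += [Locus("A", 0.5, 0.18, 0.18, label="concordant") for _ in range(24)]
    loci += [Locus("X", 0.5, 0.0, 0.3, label="maleX") for _ in range(4)]
    loci += [Locus("Y", 0.5, 0.0, 0.5, label="Y") for _ in range(3)]
    return GeneticArchitecture(loci, v_me=(0.0, 0.0), v_res=(1.0, 1.0),
                               mu_f=5.8, mu_m=4.0)
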