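"""Locus-explicit simulation: transmission rules, expected components, scaling."""

import numpy as np
import pandas as pd
import pytest

from sexvar.pedigree import Pedigree, PedigreeRecord
from sexvar.simulator import (
    GeneticArchitecture,
    Locus,
    ancestral_preset,
    expected_components,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_phenotypes_gaussian,
)


def unrelated_pedigree(n, alternate_sex=True):
    return Pedigree([
        PedigreeRecord(f"i{k}", "0", "0", "F" if (k % 2 == 0 and alternate_sex) else "M", 0)
        for k in range(n)
    ], validate=False)


@pytest.fixture(scope="module")
def family_pedigree():
    recs = [
        PedigreeRecord("s", "0", "0", "M", 0), PedigreeRecord("d", "0", "0", "F", 0),
    ]
    recs += [PedigreeRecord(f"c{k}", "s", "d", "F" if k % 2 else "M", 1)
             for k in range(6)]
    return Pedigree(recs)


class TestGenotypes:
    def test_fixed_allele_stays_fixed(self, family_pedigree):
        arch = GeneticArchitecture([Locus("A", p=1.0, a_f=1, a_m=1)])
        g = simulate_genotypes(family_pedigree, arch, seed=0)
        assert (g.aut == 2).all()

    def test_y_constant_within_patriline(self):
        recs = [PedigreeRecord("s", "0", "0", "M", 0), PedigreeRecord("d", "0", "0", "F", 0)]
        recs += [PedigreeRecord(f"m{k}", "s", "d", "M", 1) for k in range(5)]
        recs += [PedigreeRecord("g", "m0", "d2", "M", 2)
                 for _ in range(0)]  # keep simple: one generation
        ped = Pedigree(recs, validate=False)
        arch = GeneticArchitecture([Locus("Y", p=0.5, a_m=1.0)])
        g = simulate_genotypes(ped, arch, seed=3)
        sons = g.y[2:, 0]
        assert (sons == g.y[0, 0]).all()

    def test_founder_heterozygosity_near_hardy_weinberg(self):
        ped = unrelated_pedigree(10_000)
        arch = GeneticArchitecture([Locus("A", p=0.5, a_f=1, a_m=1)])
        g = simulate_genotypes(ped, arch, seed=1)
        het = (g.aut[:, 0] == 1).mean()
        assert het == pytest.approx(0.5, abs=0.02)

    def test_sons_x_comes_from_dam(self, family_pedigree):
        # dam fixed for allele 1, sire carries allele 0: sons always 1
        arch = GeneticArchitecture([Locus("X", p=0.0, a_m=1.0)])
        g = simulate_genotypes(family_pedigree, arch, seed=0)
        g.x[1, 0] = 2  # force the dam homozygous for allele 1
        g2 = simulate_genotypes(family_pedigree, arch, seed=0,
                                founder_genotypes=g, founder_ids=g.ids)
        sons = [i for i, r in enumerate(family_pedigree.records) if r.sex == "M" and not r.is_founder]
        assert (g2.x[sons, 0] == 1).all()


class TestPhenotypes:
    def test_zero_architecture_gives_zero(self, family_pedigree):
        arch = GeneticArchitecture([], v_res=(0.0, 0.0), mu_f=0.0, mu_m=0.0)
        g = simulate_genotypes(family_pedigree, arch, seed=0)
        phen = simulate_phenotypes(family_pedigree, g, arch, seed=0)
        assert (phen.value == 0).all()

    def test_single_locus_no_noise_three_values_per_sex(self):
        ped = unrelated_pedigree(400)
        arch = GeneticArchitecture([Locus("A", 0.5, a_f=1.0, a_m=2.0, d_f=0.3)],
                                   v_res=(0.0, 0.0))
        g = simulate_genotypes(ped, arch, seed=2)
        phen = simulate_phenotypes(ped, g, arch, seed=2)
        for sex in ("F", "M"):
            assert phen.loc[phen.sex == sex, "value"].nunique() <= 3

    def test_maternal_effect_shared_by_sibs(self, family_pedigree):
        arch = GeneticArchitecture([], v_me=(1.0, 1.0), v_res=(0.0, 0.0))
        g = simulate_genotypes(family_pedigree, arch, seed=0)
        phen = simulate_phenotypes(family_pedigree, g, arch, seed=7)
        sibs = phen[phen.dam == "d"]
        assert sibs.value.nunique() == 1

    def test_total_variance_matches_expectation(self):
        ped = unrelated_pedigree(10_000)
        arch = ancestral_preset()
        g = simulate_genotypes(ped, arch, seed=4)
        phen = simulate_phenotypes(ped, g, arch, seed=5)
        comps = expected_components(arch)
        for sex, expect in (("F", comps.VP_f), ("M", comps.VP_m)):
            emp = phen.loc[phen.sex == sex, "value"].var()
            assert emp == pytest.approx(expect, rel=0.05)


class TestExpectedComponents:
    def test_additive_plugin(self):
        arch = GeneticArchitecture([Locus("A", 0.5, a_f=1.0, a_m=1.0)])
        c = expected_components(arch)
        assert c.VA_fa == pytest.approx(0.5)
        assert c.VD_f == 0.0
        assert c.COV_Aa == pytest.approx(0.5)
        assert c.r_mf == pytest.approx(1.0)

    def test_pure_dominance_plugin(self):
        arch = GeneticArchitecture([Locus("A", 0.5, d_f=1.0, d_m=1.0)])
        c = expected_components(arch)
        assert c.VA_fa == 0.0  # alpha = 0 at p = q
        assert c.VD_f == pytest.approx(0.25)

    def test_random_architecture_against_monte_carlo(self):
        rng = np.random.default_rng(6)
        loci = [Locus("A", float(p), float(a), float(am), float(d), float(dm))
                for p, a, am, d, dm in zip(rng.uniform(0.1, 0.9, 50),
                                           rng.normal(0, 0.2, 50),
                                           rng.normal(0, 0.2, 50),
                                           rng.normal(0, 0.1, 50),
                                           rng.normal(0, 0.1, 50))]
        arch = GeneticArchitecture(loci, v_res=(0.5, 0.5))
        c = expected_components(arch)
        ped = unrelated_pedigree(100_000)
        g = simulate_genotypes(ped, arch, seed=7)
        phen = simulate_phenotypes(ped, g, arch, seed=8)
        for sex, expect in (("F", c.VP_f), ("M", c.VP_m)):
            emp = phen.loc[phen.sex == sex, "value"].var()
            assert emp == pytest.approx(expect, rel=0.03)

    def test_scaling_law(self):
        """Doubling every effect quadruples variances, quadruples COV."""
        rng = np.random.default_rng(9)
        loci = [Locus("A", 0.3, 0.5, 0.4, 0.2, 0.1), Locus("X", 0.4, 0.3, 0.6),
                Locus("Y", 0.5, a_m=0.7)]
        arch1 = GeneticArchitecture(loci)
        arch2 = GeneticArchitecture([
            Locus(l.chrom, l.p, 2 * l.a_f, 2 * l.a_m, 2 * l.d_f, 2 * l.d_m)
            for l in loci])
        c1, c2 = expected_components(arch1), expected_components(arch2)
        for name in ("VA_fa", "VA_ma", "COV_Aa", "VD_f", "VA_fX", "VA_mX", "VA_Y"):
            assert getattr(c2, name) == pytest.approx(4 * getattr(c1, name))

    def test_identical_effects_force_perfect_correlation(self):
        rng = np.random.default_rng(10)
        loci = [Locus("A", float(p), float(a), float(a), float(d), float(d))
                for p, a, d in zip(rng.uniform(0.1, 0.9, 20),
                                   rng.normal(0, 0.3, 20), rng.normal(0, 0.1, 20))]
        c = expected_components(GeneticArchitecture(loci))
        assert c.r_mf == pytest.approx(1.0)

    def test_ancestral_preset_pattern(self):
        c = expected_components(ancestral_preset())
        assert c.r_mf > 0.9
        assert c.VD_f > 0 and c.VD_m == 0
        assert c.VA_Y > 0 and c.VA_fX == 0 and c.VA_mX > 0

    def test_components_additive_over_loci(self):
        l1 = Locus("A", 0.3, 0.5, 0.2, 0.1, 0.0)
        l2 = Locus("A", 0.7, 0.1, 0.4, 0.0, 0.2)
        c12 = expected_components(GeneticArchitecture([l1, l2]))
        c1 = expected_components(GeneticArchitecture([l1]))
        c2 = expected_components(GeneticArchitecture([l2]))
        for name in ("VA_fa", "VA_ma", "COV_Aa", "VD_f", "VD_m"):
            assert getattr(c12, name) == pytest.approx(
                getattr(c1, name) + getattr(c2, name))


class TestComponentAlgebraProperties:
    """Algebraic invariants of the single-locus decomposition."""

    from hypothesis import given, settings, strategies as st

    locus_params = st.tuples(
        st.floats(0.01, 0.99), st.floats(-1.0, 1.0), st.floats(-1.0, 1.0),
        st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))

    @given(st.lists(locus_params, min_size=1, max_size=8))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_components_valid_and_bounded(self, params):
        loci = [Locus("A", p, af, am, df, dm) for p, af, am, df, dm in params]
        c = expected_components(GeneticArchitecture(loci))
        assert c.VA_fa >= 0 and c.VA_ma >= 0 and c.VD_f >= 0 and c.VD_m >= 0
        assert abs(c.COV_Aa) <= np.sqrt(c.VA_fa * c.VA_ma) + 1e-9

    @given(st.lists(locus_params, min_size=1, max_size=6),
           st.floats(0.1, 3.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_effect_scaling_quadruples_variances(self, params, k):
        loci = [Locus("A", p, af, am, df, dm) for p, af, am, df, dm in params]
        scaled = [Locus("A", l.p, k * l.a_f, k * l.a_m, k * l.d_f, k * l.d_m)
                  for l in loci]
        c1 = expected_components(GeneticArchitecture(loci))
        c2 = expected_components(GeneticArchitecture(scaled))
        for name in ("VA_fa", "VA_ma", "COV_Aa", "VD_f", "VD_m"):
            assert getattr(c2, name) == pytest.approx(
                k**2 * getattr(c1, name), rel=1e-9, abs=1e-12)


class TestGaussianShortcut:
    def test_maternal_and_residual_structure(self, family_pedigree):
        from sexvar.components import VarianceComponents

        comps = VarianceComponents(VME_f=1.0, VME_m=1.0, VR_f=0.0, VR_m=0.0)
        phen = simulate_phenotypes_gaussian(family_pedigree, comps, seed=0)
        sibs = phen[phen.dam == "d"]
        assert sibs.value.std() == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_given_seed(self, family_pedigree):
        from sexvar.components import VarianceComponents

        comps = VarianceComponents(VA_fa=0.5, VA_ma=0.5, COV_Aa=0.4,
                                   VR_f=0.5, VR_m=0.5)
        a = simulate_phenotypes_gaussian(family_pedigree, comps, seed=42)
        b = simulate_phenotypes_gaussian(family_pedigree, comps, seed=42)
        pd.testing.assert_frame_equal(a, b)
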