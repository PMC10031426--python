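"""Selection regimes: ranking, factorial crossing, drift and response."""

import numpy as np
import pandas as pd
import pytest

from sexvar.pedigree import DesignError
from sexvar.simulator import (
    GeneticArchitecture,
    Locus,
    expected_components,
    sa_reversal_preset,
)
from sexvar.selection import (
    Cohort,
    FamilyStats,
    RegimeSpec,
    SelectionError,
    factorial_cross,
    family_stats,
    founder_population,
    heterozygosity_trace,
    rank_and_select,
    run_regime,
    selection_differential,
)


def make_stats(male_means, female_means=None):
    female_means = female_means or [10.0] * len(male_means)
    return [FamilyStats(f"fam{i}", f, m, 3, 3)
            for i, (f, m) in enumerate(zip(female_means, male_means))]


class TestFamilyStats:
    def test_arithmetic(self):
        phen = pd.DataFrame({
            "id": list("abcd"),
            "sex": ["F", "F", "M", "M"],
            "value": [10.0, 12.0, 8.0, 8.0],
            "family": ["f1"] * 4,
        })
        (s,) = family_stats(phen)
        assert s.mean_f == 11.0 and s.mean_m == 8.0
        assert s.ssd_ratio == pytest.approx(1.375)

    def test_single_sex_family_flagged_undefined(self):
        phen = pd.DataFrame({"id": ["a"], "sex": ["M"], "value": [5.0],
                             "family": ["f1"]})
        (s,) = family_stats(phen)
        assert np.isnan(s.ssd_ratio)

    def test_one_stat_per_family(self):
        rng = np.random.default_rng(0)
        phen = pd.DataFrame({
            "id": [str(i) for i in range(56 * 4)],
            "sex": ["F", "M"] * (56 * 2),
            "value": rng.normal(size=56 * 4),
            "family": np.repeat([f"f{i}" for i in range(56)], 4),
        })
        assert len(family_stats(phen)) == 56


class TestRankAndSelect:
    def test_ml_picks_smallest_males(self):
        stats = make_stats([9.0, 7.0, 8.0])
        spec = RegimeSpec(regime="ML", n_families=3, n_selected=2, n_generations=0)
        assert set(rank_and_select(stats, spec, 0)) == {"fam1", "fam2"}

    def test_sa_picks_highest_ratio(self):
        stats = [FamilyStats("a", 11.0, 10.0, 2, 2),
                 FamilyStats("b", 15.0, 10.0, 2, 2),
                 FamilyStats("c", 13.0, 10.0, 2, 2)]
        spec = RegimeSpec(regime="SA", n_families=3, n_selected=1, n_generations=0)
        assert rank_and_select(stats, spec, 0) == ["b"]

    def test_rs_deterministic_given_seed(self):
        stats = make_stats(list(range(10)))
        spec = RegimeSpec(regime="RS", n_families=10, n_selected=3, n_generations=0)
        assert rank_and_select(stats, spec, 5) == rank_and_select(stats, spec, 5)

    def test_unrankable_families_excluded(self):
        stats = make_stats([9.0, 7.0]) + [FamilyStats("allf", 10.0, np.nan, 3, 0)]
        spec = RegimeSpec(regime="ML", n_families=4, n_selected=3, n_generations=0)
        with pytest.raises(SelectionError):
            rank_and_select(stats, spec, 0)


def cohort_with_families(n_families, n_f=8, n_m=2, seed=0):
    from sexvar.pedigree import Pedigree, PedigreeRecord
    from sexvar.simulator import simulate_genotypes

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_families):
        for j in range(n_f):
            rows.append((f"F{i}_{j}", "F", rng.normal(10), f"fam{i}"))
        for j in range(n_m):
            rows.append((f"M{i}_{j}", "M", rng.normal(8), f"fam{i}"))
    phen = pd.DataFrame(rows, columns=["id", "sex", "value", "family"])
    phen["sire"] = "0"
    phen["dam"] = "0"
    ped = Pedigree([
        __import__("sexvar.pedigree", fromlist=["PedigreeRecord"]).PedigreeRecord(
            r.id, "0", "0", r.sex, 0) for r in phen.itertuples()
    ], validate=False)
    arch = GeneticArchitecture([Locus("A", 0.5, 0.1, 0.1)])
    genos = simulate_genotypes(ped, arch, seed=seed)
    return Cohort(phen, genos, 1)


class TestFactorialCross:
    @pytest.mark.parametrize("n_sel,expected", [(8, 56), (3, 6), (2, 2)])
    def test_cross_counts(self, n_sel, expected):
        cohort = cohort_with_families(n_sel)
        selected = [f"fam{i}" for i in range(n_sel)]
        crosses = factorial_cross(selected, cohort, 0)
        assert len(crosses) == expected

    def test_never_within_family_and_each_dam_once(self):
        cohort = cohort_with_families(8)
        fam_of = dict(zip(cohort.phen["id"], cohort.phen["family"]))
        crosses = factorial_cross([f"fam{i}" for i in range(8)], cohort, 1)
        dams = [d for _, _, d in crosses]
        assert len(set(dams)) == len(dams)          # each dam mates once
        for _, sire, dam in crosses:
            assert fam_of[sire] != fam_of[dam]      # no full-sib cross
        sire_counts = pd.Series([s for _, s, _ in crosses]).value_counts()
        assert (sire_counts == 7).all()             # each sire mates n-1 times

    def test_insufficient_females_raises(self):
        cohort = cohort_with_families(8, n_f=3)
        with pytest.raises(DesignError, match="fam0"):
            factorial_cross([f"fam{i}" for i in range(8)], cohort, 0)


@pytest.fixture(scope="module")
def small_spec():
    return dict(n_families=12, n_selected=4, offspring_per_family=10)


class TestRunRegime:
    def test_zero_generations_history(self, small_spec):
        arch = sa_reversal_preset()
        spec = RegimeSpec(regime="RS", n_generations=0, panmictic_generations=0,
                          seed=0, **small_spec)
        hist, pool = run_regime(arch, spec)
        assert len(hist.records) == 1  # founder stats only
        assert len(pool) > 0

    def test_rs_is_a_martingale_and_drift_erodes_va(self, small_spec):
        """Neutral allele-frequency change averages ~0; V_A decays by drift."""
        arch = GeneticArchitecture(
            [Locus("A", 0.5, 0.0, 0.0, label="neutral") for _ in range(30)],
            v_res=(1.0, 1.0))
        deltas, va_ratio = [], []
        for rep in range(12):
            spec = RegimeSpec(regime="RS", n_generations=4,
                              panmictic_generations=0, seed=100 + rep, **small_spec)
            hist, _ = run_regime(arch, spec)
            f0, fT = hist.records[0].freqs, hist.records[-1].freqs
            deltas.append(np.mean(fT - f0))
            va_ratio.append(expected_components(arch, fT).VA_fa /
                            max(expected_components(arch, f0).VA_fa, 1e-12))
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se + 1e-3
        # the neutral architecture has a = 0, so VA is 0 throughout; use 2pq
        het0 = 2 * hist.records[0].freqs * (1 - hist.records[0].freqs)
        hetT = 2 * hist.records[-1].freqs * (1 - hist.records[-1].freqs)
        assert hetT.mean() < het0.mean()  # drift erodes heterozygosity

    def test_ml_declines_male_mean(self, small_spec):
        arch = GeneticArchitecture(
            [Locus("A", 0.5, 0.0, 0.3) for _ in range(20)], v_res=(0.5, 0.5))
        trends = []
        for rep in range(8):
            spec = RegimeSpec(regime="ML", n_generations=4,
                              panmictic_generations=0, seed=rep, **small_spec)
            hist, _ = run_regime(arch, spec)
            m = hist.frame()["mean_m"].to_numpy()
            trends.append(m[-1] - m[0])
        assert np.mean(trends) < 0


class TestSelectionDifferential:
    def test_hand_computed_history(self):
        from sexvar.selection import GenerationRecord, SelectionHistory

        hist = SelectionHistory("ML", "a", [
            GenerationRecord(1, [], ["f"], 10.0, 8.0, -0.5, -1.0, np.array([])),
            GenerationRecord(2, [], ["f"], 9.5, 7.0, -0.25, -0.75, np.array([])),
        ])
        df = selection_differential(hist)
        assert df["cum_diff_m"].tolist() == [-1.0, -1.75]
        assert df["cum_diff_f"].tolist() == [-0.5, -0.75]

    def test_ml_differential_male_negative_female_null(self, small_spec):
        """ML selects male family means only; with male-limited effects the
        female differential is pure noise around zero."""
        arch = GeneticArchitecture(
            [Locus("A", 0.5, 0.0, 0.3) for _ in range(20)], v_res=(0.5, 0.5))
        cum_m, cum_f = [], []
        for rep in range(8):
            spec = RegimeSpec(regime="ML", n_generations=3,
                              panmictic_generations=0, seed=50 + rep, **small_spec)
            hist, _ = run_regime(arch, spec)
            d = selection_differential(hist)
            cum_m.append(d["cum_diff_m"].iloc[-1])
            cum_f.append(d["cum_diff_f"].iloc[-1])
        assert np.mean(cum_m) < 0
        se = np.std(cum_f, ddof=1) / np.sqrt(len(cum_f))
        assert abs(np.mean(cum_f)) < 3 * se + 0.05

    def test_rs_differential_near_zero(self, small_spec):
        arch = GeneticArchitecture(
            [Locus("A", 0.5, 0.2, 0.2) for _ in range(10)], v_res=(0.5, 0.5))
        cums = []
        for rep in range(10):
            spec = RegimeSpec(regime="RS", n_generations=3,
                              panmictic_generations=0, seed=200 + rep, **small_spec)
            hist, _ = run_regime(arch, spec)
            cums.append(selection_differential(hist)["cum_diff_m"].iloc[-1])
        se = np.std(cums, ddof=1) / np.sqrt(len(cums))
        assert abs(np.mean(cums)) < 3 * se + 0.02


class TestHeterozygosity:
    def test_fixed_locus_zero_forever(self, small_spec):
        arch = GeneticArchitecture([Locus("A", 1.0, 0.1, 0.1)], v_res=(1.0, 1.0))
        spec = RegimeSpec(regime="RS", n_generations=2, panmictic_generations=0,
                          seed=0, **small_spec)
        hist, _ = run_regime(arch, spec)
        trace = heterozygosity_trace(hist, arch)
        assert (trace["het"] == 0).all()

    def test_sa_maintains_het_at_reversal_loci(self, small_spec):
        """Dominance-reversal SA loci keep intermediate frequencies under SA
        but fix under ML: the core balancing-selection mechanism."""
        arch = sa_reversal_preset()
        sa_het, ml_het = [], []
        for rep in range(6):
            for regime, sink in (("SA", sa_het), ("ML", ml_het)):
                spec = RegimeSpec(regime=regime, n_families=24, n_selected=6,
                                  offspring_per_family=12, n_generations=8,
                                  panmictic_generations=0, seed=300 + rep)
                hist, _ = run_regime(arch, spec)
                trace = heterozygosity_trace(hist, arch)
                last = trace[trace.generation == trace.generation.max()]
                sink.append(last.loc[last.label == "SA", "het"].mean())
        assert np.mean(sa_het) > np.mean(ml_het)
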