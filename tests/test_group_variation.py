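import numpy as np
import pytest

from privar.core_io import MISSING
from privar.group_variation import (
    diagnostic_sites,
    domestication_score,
    genotype_pca,
    specific_snp_clustering,
    venn_partition,
)
from privar.synthetic_data import (
    AncientSpec,
    SimConfig,
    simulate_nuclear,
)

from conftest import make_meta


def brute_force_venn(table, meta):
    """Oracle: per-site per-group set construction with explicit loops."""
    groups = {}
    for g in ("cultivar", "landrace", "wild"):
        members = [i for i, s in enumerate(table.samples)
                   if meta.set_index("sample").loc[s, "status"] == g]
        sites = set()
        for s in range(table.n_sites):
            alleles = set()
            for n in members:
                a, b = table.genotypes[s, n]
                if a != MISSING:
                    alleles.update((int(a), int(b)))
            if len(alleles) >= 2:
                sites.add(s)
        groups[g] = sites
    return groups


class TestVennPartition:
    @pytest.fixture
    def toy(self, table_builder):
        # 2 cultivars, 2 landraces, 2 wild over 10 hand-set sites
        calls = [
            [(0, 1), (0, 0), (0, 0), (0, 0), (0, 0), (0, 0)],  # cult only
            [(0, 0), (0, 0), (0, 1), (0, 0), (0, 0), (0, 0)],  # land only
            [(0, 0), (0, 0), (0, 0), (0, 0), (1, 1), (0, 0)],  # wild only
            [(0, 1), (0, 0), (1, 1), (0, 0), (0, 1), (0, 0)],  # all three
            [(0, 1), (0, 0), (0, 1), (0, 0), (0, 0), (0, 0)],  # cult+land
            [(0, 0), (0, 0), (0, 0), (0, 0), (0, 0), (0, 0)],  # monomorphic
            [(1, 1), (1, 1), (1, 1), (1, 1), (1, 1), (1, 1)],  # monomorphic alt
            [(0, 1), (0, 0), (0, 0), (0, 0), (0, 1), (0, 0)],  # cult+wild
            [(0, 0), (0, 0), (0, 1), (0, 0), (1, 1), (0, 0)],  # land+wild
            [(0, 0), None, (0, 1), (0, 1), None, (0, 0)],      # land only
        ]
        table = table_builder(calls)
        meta = make_meta(table.samples,
                         ["cultivar", "cultivar", "landrace", "landrace",
                          "wild", "wild"])
        return table, meta

    def test_counts_match_brute_force(self, toy):
        table, meta = toy
        part = venn_partition(table, meta)
        oracle = brute_force_venn(table, meta)
        assert part.sites_by_group == oracle
        total_regions = sum(part.region_counts.values())
        assert total_regions == len(set().union(*oracle.values()))

    def test_exclusive_and_triple_regions(self, toy):
        table, meta = toy
        part = venn_partition(table, meta)
        assert part.region_counts[frozenset(["cultivar"])] == 1
        assert part.region_counts[frozenset(["wild"])] == 1
        assert part.region_counts[
            frozenset(["cultivar", "landrace", "wild"])] == 1

    def test_wild_carryover_fraction(self, toy):
        table, meta = toy
        part = venn_partition(table, meta)
        # wild-variable sites: {2,3,7,8}; of these {3,7,8} also variable in
        # the domesticated union
        assert part.wild_carryover == pytest.approx(3 / 4)

    def test_invariant_under_permutation(self, toy):
        table, meta = toy
        rng = np.random.default_rng(1)
        shuffled = table.take_samples(list(rng.permutation(table.n_samples)))
        a = venn_partition(table, meta).region_counts
        b = venn_partition(shuffled, meta).region_counts
        assert a == b

    def test_empty_group_named_in_error(self, toy):
        table, meta = toy
        meta = meta[meta["status"] != "wild"]
        with pytest.raises(ValueError, match="wild"):
            venn_partition(table, meta)


class TestClusteringTest:
    @pytest.fixture
    def simulated(self):
        cfg = SimConfig(seed=17, n_wild=6, n_landrace=10, n_cultivar=6,
                        n_sites=4000, n_chromosomes=2,
                        n_diagnostic=30, n_diagnostic_blocks=3,
                        diagnostic_block_size=10, region_site_base=10)
        return simulate_nuclear(cfg)

    def test_planted_block_is_detected(self, simulated):
        table, _, truth = simulated
        block = truth.diagnostic_sites.query("block")["site"].tolist()
        res = specific_snp_clustering(table, block, n_draws=999, seed=5)
        assert res.p_value <= 0.01
        assert res.observed < res.null.mean()

    def test_single_site_rejected(self, simulated):
        table, _, _ = simulated
        with pytest.raises(ValueError):
            specific_snp_clustering(table, [3], n_draws=9, seed=0)

    def test_subset_must_be_variable(self, simulated):
        table, _, _ = simulated
        with pytest.raises(ValueError, match="subset"):
            specific_snp_clustering(table, [0, 1], n_draws=9, seed=0,
                                    variable_sites=[5, 6, 7])

    def test_deterministic_under_seed(self, simulated):
        table, _, truth = simulated
        block = truth.diagnostic_sites.query("block")["site"].tolist()
        a = specific_snp_clustering(table, block, n_draws=99, seed=11)
        b = specific_snp_clustering(table, block, n_draws=99, seed=11)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)


class TestDiagnosticSites:
    def build(self, dom_freq, wild_freq, table_builder, n_dom=10, n_wild=10):
        n_dom_alt = int(round(dom_freq * n_dom))
        n_wild_alt = int(round(wild_freq * n_wild))
        calls = [[(1, 1)] * n_dom_alt + [(0, 0)] * (n_dom - n_dom_alt)
                 + [(1, 1)] * n_wild_alt + [(0, 0)] * (n_wild - n_wild_alt)]
        table = table_builder(calls)
        meta = make_meta(table.samples,
                         ["landrace"] * n_dom + ["wild"] * n_wild)
        return table, meta

    def test_clear_separation_included(self, table_builder):
        table, meta = self.build(0.96, 0.10, table_builder, n_dom=25)
        sites = diagnostic_sites(table, meta)
        assert len(sites) == 1 and sites.alleles[0] == 1

    def test_boundary_frequency_excluded(self, table_builder):
        # domesticated frequency exactly 0.95 fails the strict inequality
        table, meta = self.build(0.95, 0.10, table_builder, n_dom=20)
        assert len(diagnostic_sites(table, meta)) == 0

    def test_common_in_wild_excluded(self, table_builder):
        table, meta = self.build(0.99, 0.30, table_builder, n_dom=100)
        assert len(diagnostic_sites(table, meta)) == 0

    def test_hybrid_and_ancient_excluded_from_groups(self, table_builder):
        calls = [[(1, 1)] * 10 + [(0, 0), (0, 0)] + [(0, 0)] * 10]
        table = table_builder(calls)
        meta = make_meta(table.samples, ["landrace"] * 10
                         + ["hybrid/feral", "ancient"] + ["wild"] * 10)
        sites = diagnostic_sites(table, meta)
        # the two non-group samples carry 0/0 but must not dilute the
        # domesticated frequency below the threshold
        assert len(sites) == 1


class TestDomesticationScore:
    @pytest.fixture
    def scenario(self):
        cfg = SimConfig(seed=23, n_wild=12, n_landrace=20, n_cultivar=8,
                        n_sites=2000, ancient=AncientSpec(n_eroded=10),
                        n_diagnostic=40, region_site_base=10)
        return simulate_nuclear(cfg)

    def test_noise_free_domesticated_sample_scores_one(self, table_builder):
        table, meta = TestDiagnosticSites().build(1.0, 0.10, table_builder,
                                                  n_dom=20)
        sites = diagnostic_sites(table, meta)
        assert domestication_score(table, "s0", sites) == 1.0

    def test_all_missing_undefined(self, table_builder):
        calls = [[(1, 1)] * 10 + [(0, 0)] * 10 + [None]]
        table = table_builder(calls)
        meta = make_meta(table.samples, ["landrace"] * 10 + ["wild"] * 10
                         + ["ancient"])
        sites = diagnostic_sites(table, meta)
        assert np.isnan(domestication_score(table, "s20", sites))

    def test_wild_scores_match_planted_frequency(self, scenario):
        table, meta, truth = scenario
        sites = diagnostic_sites(table, meta)
        wild_scores = [domestication_score(table, s, sites)
                       for s in meta.loc[meta.status == "wild", "sample"]]
        # planted wild frequency 0.10; binomial error over ~40 sites
        assert 0.0 <= np.mean(wild_scores) < 0.30

    def test_domesticated_dominate_wild(self, scenario):
        table, meta, truth = scenario
        sites = diagnostic_sites(table, meta)
        dom = [domestication_score(table, s, sites) for s in
               meta.loc[meta.status.isin(["landrace", "cultivar"]), "sample"]]
        wild = [domestication_score(table, s, sites) for s in
                meta.loc[meta.status == "wild", "sample"]]
        assert min(dom) > max(wild)
        ancient = domestication_score(table, "ANC001", sites)
        assert ancient > 0.8  # near-fully domesticated, like the planted 0.95


class TestGenotypePca:
    def test_planted_clusters_separate_on_pc1(self):
        cfg = SimConfig(seed=29, n_wild=15, n_landrace=15, n_cultivar=10,
                        n_sites=1500, n_diagnostic=80,
                        n_diagnostic_blocks=0, region_site_base=5)
        table, meta, _ = simulate_nuclear(cfg)
        coords, var_frac = genotype_pca(table, k=2)
        status = meta.set_index("sample")["status"]
        wild = coords.loc[[s for s in coords.index
                           if status[s] == "wild"], "PC1"]
        dom = coords.loc[[s for s in coords.index
                          if status[s] in ("landrace", "cultivar")], "PC1"]
        # >= 95% of cross-group pairs fall on opposite sides
        pairs = [(w, d) for w in wild for d in dom]
        opposite = sum(1 for w, d in pairs if w * d < 0)
        assert opposite / len(pairs) >= 0.95
        assert var_frac.sum() <= 1.0 + 1e-9

    def test_duplicated_samples_coincide(self, table_builder):
        rng = np.random.default_rng(4)
        calls = [[tuple(sorted(rng.integers(0, 2, 2))) for _ in range(5)]
                 for _ in range(60)]
        for row in calls:
            row.append(row[0])  # exact copy of sample 0
        table = table_builder(calls)
        coords, _ = genotype_pca(table, k=2)
        assert np.allclose(coords.iloc[0], coords.iloc[-1])

    def test_k_bounds_checked(self, table_builder):
        t = table_builder([[(0, 1), (0, 0)]])
        with pytest.raises(ValueError):
            genotype_pca(t, k=3)
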