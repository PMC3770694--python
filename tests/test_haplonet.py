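"""LD, haplotype blocks, median-joining networks, rho dating, Rmin, CIs."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tyrscan import haplonet as hn
from tyrscan.exceptions import ConfigError

from conftest import make_panel


class TestLd:
    def test_perfectly_coinherited_pair(self):
        col = np.array([0] * 5 + [1] * 5, dtype=np.int8)
        panel = make_panel(np.column_stack([col, col]))
        ld = hn.ld_pairwise(panel)
        assert ld.dprime[0, 1] == pytest.approx(1.0)
        assert ld.r2[0, 1] == pytest.approx(1.0)

    def test_hand_counted_two_by_two_table(self):
        # AB=40, Ab=10, aB=10, ab=40 -> D=0.15, D'=0.6, r2=0.36
        a = np.array([1] * 50 + [0] * 50, dtype=np.int8)
        b = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40, dtype=np.int8)
        ld = hn.ld_pairwise(make_panel(np.column_stack([a, b])))
        assert ld.dprime[0, 1] == pytest.approx(0.6)
        assert ld.r2[0, 1] == pytest.approx(0.36)

    def test_independent_pair_near_zero_r2(self, rng):
        a = (rng.random(2000) < 0.5).astype(np.int8)
        b = (rng.random(2000) < 0.5).astype(np.int8)
        ld = hn.ld_pairwise(make_panel(np.column_stack([a, b])))
        assert ld.r2[0, 1] < 0.01

    def test_monomorphic_member_undefined(self):
        a = np.zeros(20, dtype=np.int8)
        b = np.array([0, 1] * 10, dtype=np.int8)
        ld = hn.ld_pairwise(make_panel(np.column_stack([a, b])))
        assert np.isnan(ld.dprime[0, 1])

    def test_r2_one_implies_dprime_one(self, rng):
        for _ in range(20):
            a = (rng.random(60) < rng.uniform(0.2, 0.8)).astype(np.int8)
            b = a if rng.random() < 0.5 else (1 - a).astype(np.int8)
            ld = hn.ld_pairwise(make_panel(np.column_stack([a, b])))
            if ld.r2[0, 1] == pytest.approx(1.0):
                assert abs(ld.dprime[0, 1]) == pytest.approx(1.0)


class TestBlocks:
    def test_single_block_when_all_pairs_perfect(self, rng):
        col = (rng.random(80) < 0.5).astype(np.int8)
        panel = make_panel(np.column_stack([col] * 4))
        assert hn.find_blocks(panel) == [(0, 3)]

    def test_free_column_splits_two_perfect_blocks(self):
        rng = np.random.default_rng(7)
        b1 = (rng.random(200) < 0.5).astype(np.int8)
        b2 = (rng.random(200) < 0.5).astype(np.int8)
        free = (rng.random(200) < 0.5).astype(np.int8)
        geno = np.column_stack([b1, b1, b1, free, b2, b2, b2])
        blocks = hn.find_blocks(make_panel(geno))
        assert blocks == [(0, 2), (4, 6)]

    def test_too_few_qualifying_snps_empty(self):
        panel = make_panel(np.zeros((10, 3), dtype=np.int8))
        assert hn.find_blocks(panel) == []


class TestMedianJoining:
    def test_perfect_phylogeny_recovers_tree(self):
        haps = np.array([
            [0, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 1, 1],
        ])
        net = hn.median_joining(haps)
        assert net.number_of_nodes() == 5          # no extra medians
        assert net.number_of_edges() == 4          # a tree
        assert nx.is_connected(net)
        kinds = {net.nodes[n]["kind"] for n in net.nodes}
        assert kinds == {"sampled"}

    def test_triangle_resolved_by_one_median(self):
        haps = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        net = hn.median_joining(haps)
        medians = [n for n in net.nodes if net.nodes[n]["kind"] == "median"]
        assert len(medians) == 1
        assert net.degree(medians[0]) == 3         # star topology

    def test_multiplicities_sum_to_total_chromosomes(self, rng):
        haps = rng.integers(0, 2, size=(12, 6))
        net = hn.median_joining(haps)
        total = sum(net.nodes[n]["multiplicity"] for n in net.nodes)
        assert total == 12

    def test_contains_true_haplotypes_on_recombination_free_data(self):
        from tyrscan import coalsim
        for seed in range(8):
            rep = coalsim.simulate_fixed_s(10, 8, seed=seed + 1)
            net = hn.median_joining(rep.geno)
            sampled = {tuple(int(x) for x in row) for row in rep.geno}
            assert sampled <= set(net.nodes)
            assert nx.is_connected(net)

    def test_outgroup_attachment_sets_root(self):
        haps = np.array([[0, 0], [1, 0], [1, 1]])
        net = hn.median_joining(haps)
        hn.attach_outgroup(net, [0, 1])
        assert "root" in net.graph
        root = net.graph["root"]
        assert all(nx.has_path(net, root, n) for n in net.nodes)


def star_network(n_tips=4, branch=1):
    net = nx.Graph()
    root = ("root",)
    net.add_node(root, kind="median", multiplicity=0, pops={})
    for i in range(n_tips):
        tip = ("tip", i)
        net.add_node(tip, kind="sampled", multiplicity=1, pops={})
        net.add_edge(root, tip, weight=float(branch), sites=[i] * branch)
    return net, root


class TestRhoAge:
    def test_tips_identical_to_root_age_zero(self):
        net = nx.Graph()
        net.add_node("r", kind="sampled", multiplicity=4, pops={})
        age = hn.rho_age(net, "r", tip_set=["r"], mu_site=1e-4, seq_len=1.0)
        assert age.rho == 0 and age.age_years == 0

    def test_star_of_four_tips(self):
        net, root = star_network()
        age = hn.rho_age(net, root, mu_site=1e-4, seq_len=1.0, gen_time=29)
        assert age.rho == pytest.approx(1.0)
        assert age.sigma_rho == pytest.approx(0.5)
        assert age.age_years == pytest.approx(290_000)
        assert age.sd_years == pytest.approx(145_000)

    def test_rho_unbiased_on_simulated_star_genealogies(self, rng):
        """Mean rho over replicates matches t * mu_seq within 3 SE."""
        t, mu_seq, n_tips, reps = 500.0, 2e-3, 6, 1000
        rhos = []
        for _ in range(reps):
            net = nx.Graph()
            root = ("r",)
            net.add_node(root, kind="median", multiplicity=0, pops={})
            for i in range(n_tips):
                k = rng.poisson(t * mu_seq)
                net.add_node(("t", i), kind="sampled", multiplicity=1, pops={})
                net.add_edge(root, ("t", i), weight=float(k), sites=[])
            rhos.append(hn.rho_age(net, root, mu_site=mu_seq,
                                   seq_len=1.0).rho)
        se = np.std(rhos) / math.sqrt(reps)
        assert abs(np.mean(rhos) - t * mu_seq) < 3 * se + 1e-12


class TestRmin:
    def test_no_incompatibility(self):
        g = np.array([[0, 0], [0, 1], [1, 1]])
        assert hn.rmin_hudson_kaplan(g)[0] == 0

    def test_adjacent_disjoint_intervals_need_two(self):
        g = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]])
        rmin, iv = hn.rmin_hudson_kaplan(g)
        assert rmin == 2 and iv == [(0, 1), (1, 2)]

    def test_overlapping_intervals_need_one(self):
        g = np.array([[0, 0, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]])
        rmin, iv = hn.rmin_hudson_kaplan(g)
        assert rmin == 1


class TestHaplogroups:
    def _motifs(self):
        return pd.DataFrame([
            dict(haplogroup="B", parent="root", snp_id="1:1000",
                 required_allele="1"),
            dict(haplogroup="B1", parent="B", snp_id="1:2000",
                 required_allele="1"),
        ])

    def test_deepest_match_wins(self):
        geno = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.int8)
        out = hn.assign_haplogroups(make_panel(geno), self._motifs(),
                                    rare_freq=0.0)
        assert list(out.haplogroup) == ["B1", "B", "root"]

    def test_all_ancestral_panel_at_root(self):
        geno = np.zeros((4, 3), dtype=np.int8)
        out = hn.assign_haplogroups(make_panel(geno), self._motifs())
        assert set(out.haplogroup) == {"root"}

    def test_rare_haplotype_flagged(self):
        geno = np.zeros((101, 3), dtype=np.int8)
        geno[0] = [1, 1, 0]
        out = hn.assign_haplogroups(make_panel(geno), self._motifs(),
                                    rare_freq=0.01)
        assert bool(out.iloc[0].rare)
        assert not out.iloc[1:].rare.any()

    def test_conflicting_same_depth_motifs_raise(self):
        motifs = pd.DataFrame([
            dict(haplogroup="X", parent="root", snp_id="1:1000",
                 required_allele="1"),
            dict(haplogroup="Y", parent="root", snp_id="1:2000",
                 required_allele="1"),
        ])
        geno = np.array([[1, 1, 0]], dtype=np.int8)
        with pytest.raises(ConfigError):
            hn.assign_haplogroups(make_panel(geno), motifs)


class TestBinomialCi:
    def test_zero_successes_lower_bound_zero(self):
        lo, hi = hn.binomial_ci(0, 30)
        assert lo == 0.0 and 0 < hi < 0.2

    def test_four_of_126(self):
        lo, hi = hn.binomial_ci(4, 126)
        assert lo == pytest.approx(0.0087, abs=5e-4)
        assert hi == pytest.approx(0.0793, abs=5e-4)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(4, 126), (0, 20), (20, 20), (33, 600), (9, 29)]:
            lo, hi = hn.binomial_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-9)
            assert hi == pytest.approx(shi, abs=1e-9)
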