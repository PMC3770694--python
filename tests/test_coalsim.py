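"""Simulator contracts: determinism, conditioning, ascertainment."""

import numpy as np
import pytest

from tyrscan import coalsim as cs
from tyrscan.exceptions import ConfigError


class TestNeutral:
    def test_zero_mutation_rate_gives_no_sites(self):
        model = cs.DemographicModel.constant(1000, mutation_rate=0.0)
        rep = cs.simulate_neutral(model, 1e4, seed=1, samples=6)
        assert rep.n_sites == 0

    def test_same_seed_identical_replicate(self):
        model = cs.DemographicModel.constant(
            5000, mutation_rate=1e-7, recombination_rate=1e-8)
        a = cs.simulate_neutral(model, 5e4, seed=99, samples=12)
        b = cs.simulate_neutral(model, 5e4, seed=99, samples=12)
        assert (a.geno == b.geno).all()
        assert (a.positions == b.positions).all()
        assert a.tmrca == b.tmrca

    def test_positions_strictly_increasing_integers(self):
        model = cs.DemographicModel.constant(20_000, mutation_rate=1e-6)
        rep = cs.simulate_neutral(model, 2e3, seed=3, samples=10)
        assert rep.positions.dtype.kind == "i"
        assert (np.diff(rep.positions) > 0).all()

    def test_population_labels_follow_sampling(self):
        model = cs.load_best_fit_model()
        rep = cs.simulate_neutral(model, 5e3, seed=5,
                                  samples={"AFR": 4, "EUR": 6})
        assert rep.pop_labels.count("AFR") == 4
        assert rep.pop_labels.count("EUR") == 6

    def test_split_time_orders_pairwise_fst(self):
        """Two isolated daughter populations differentiate with split age."""
        from tyrscan import selscan
        means = []
        for frac in (0.1, 0.5, 1.0):
            vals = []
            model = cs.DemographicModel(
                populations=[{"name": "a", "initial_size": 2000},
                             {"name": "b", "initial_size": 2000}],
                events=[{"type": "split", "time": frac * 2000,
                         "derived": ["a", "b"], "ancestral": "anc",
                         "ancestral_size": 2000}],
                mutation_rate=5e-7)
            for seed in range(20):
                rep = cs.simulate_neutral(model, 5e3, seed=seed + 1,
                                          samples={"a": 20, "b": 20})
                panel = rep.to_panel()
                fst = selscan.wc_fst(panel, "a", "b")
                vals.append(np.nanmean(fst))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestFixedS:
    def test_zero_s_is_monomorphic(self):
        rep = cs.simulate_fixed_s(8, 0, seed=1)
        assert rep.n_sites == 0

    def test_pair_with_one_mutation_always_differs(self):
        for seed in range(20):
            rep = cs.simulate_fixed_s(2, 1, seed=seed)
            assert rep.pairwise_diversity() == 1.0

    def test_exactly_s_segregating_sites(self):
        for seed in range(10):
            rep = cs.simulate_fixed_s(12, 17, seed=seed)
            counts = rep.geno.sum(axis=0)
            assert rep.n_sites == 17
            assert ((counts > 0) & (counts < 12)).all()

    def test_deterministic_given_seed(self):
        a = cs.simulate_fixed_s(10, 12, seed=7)
        b = cs.simulate_fixed_s(10, 12, seed=7)
        assert (a.geno == b.geno).all()


class TestSweep:
    def test_deterministic_given_seed(self):
        kw = dict(N=60, s=0.1, start_freq=0.1, current_freq=0.6,
                  seq_len=2e4, mu=5e-7, r=5e-7, n=20)
        a = cs.simulate_sweep(seed=11, **kw)
        b = cs.simulate_sweep(seed=11, **kw)
        assert (a.geno == b.geno).all() and a.swept_pos == b.swept_pos

    def test_sample_contains_swept_site_near_target_frequency(self):
        rep = cs.simulate_sweep(N=100, s=0.1, start_freq=0.05,
                                current_freq=0.7, seq_len=5e4, mu=1e-6,
                                r=1e-6, n=60, seed=5)
        j = int(np.searchsorted(rep.positions, rep.swept_pos))
        freq = rep.geno[:, j].mean()
        assert 0.45 < freq < 0.95        # binomial sampling around 0.7

    def test_linked_diversity_reduced_by_sweep(self):
        """Hitchhiking lowers pi relative to matched neutral replicates."""
        sweep_pi, neutral_pi = [], []
        model = cs.DemographicModel.constant(200, mutation_rate=1e-6,
                                             recombination_rate=1e-6)
        for seed in range(15):
            rep = cs.simulate_sweep(N=100, s=0.2, start_freq=0.05,
                                    current_freq=0.95, seq_len=5e4,
                                    mu=1e-6, r=1e-6, n=30, seed=seed + 1)
            sweep_pi.append(rep.pairwise_diversity())
            nrep = cs.simulate_neutral(model, 5e4, seed=seed + 100,
                                       samples=30)
            neutral_pi.append(nrep.pairwise_diversity())
        assert np.mean(sweep_pi) < np.mean(neutral_pi)

    def test_conditioning_failure_raises_with_attempt_count(self):
        with pytest.raises(cs.SweepConvergenceError) as err:
            cs.simulate_sweep(N=40, s=0.0, start_freq=0.0125,
                              current_freq=1.0, seq_len=1e3, mu=1e-7,
                              r=0.0, n=10, seed=1, max_attempts=3)
        assert err.value.attempts == 3


class TestAscertainment:
    def _rep(self, seed=2):
        model = cs.DemographicModel.constant(20_000, mutation_rate=1e-7,
                                             recombination_rate=1e-8)
        return cs.simulate_neutral(model, 5e4, seed=seed, samples=40)

    def test_no_filters_is_identity(self):
        rep = self._rep()
        panel = cs.ascertain_array(rep, maf_min=0.0, call_rate_noise=0.0)
        assert panel.n_snps == rep.n_sites
        assert (panel.geno == rep.geno).all()

    def test_sfs_left_truncated_at_maf_threshold(self):
        rep = self._rep()
        panel = cs.ascertain_array(rep, maf_min=0.05, call_rate_noise=0.02,
                                   seed=3)
        assert panel.n_snps > 0
        assert (panel.maf() > 0.05).all()
        assert (panel.call_rate() >= 0.95).all()

    def test_everything_below_threshold_gives_empty_panel(self):
        rep = self._rep()
        panel = cs.ascertain_array(rep, maf_min=0.5)
        assert panel.n_snps == 0

    def test_density_thinning(self):
        rep = self._rep()
        panel = cs.ascertain_array(rep, maf_min=0.0,
                                   target_density=min(10, rep.n_sites) / 5e4,
                                   seed=1)
        assert panel.n_snps <= 10


class TestModelConfig:
    def test_best_fit_model_loads_and_converts(self):
        model = cs.load_best_fit_model()
        dem = model.to_demography()
        dem.validate()
        assert {"AFR", "EUR", "ASIA"} <= {p.name for p in dem.populations}

    def test_json_roundtrip(self, tmp_path):
        model = cs.load_best_fit_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        again = cs.DemographicModel.from_json(path)
        assert again.populations == model.populations
        assert again.events == model.events

    def test_duplicate_population_names_rejected(self):
        with pytest.raises(ConfigError):
            cs.DemographicModel(populations=[
                {"name": "a", "initial_size": 10},
                {"name": "a", "initial_size": 20}])

    def test_uncoalescable_isolated_model_errors(self):
        model = cs.DemographicModel(
            populations=[{"name": "a", "initial_size": 100},
                         {"name": "b", "initial_size": 100}])
        with pytest.raises(ConfigError):
            cs.simulate_neutral(model, 1e3, seed=1,
                                samples={"a": 2, "b": 2})
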