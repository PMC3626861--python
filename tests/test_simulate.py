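"""Synthetic-data generators: determinism, planted structure, null behavior."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from co_atlas import simulate as sim
from co_atlas.io import read_gmt


class TestConfigValidation:
    def test_cohort_plus_planted_bounded_by_nodes(self):
        with pytest.raises(ValueError, match="exceed"):
            sim.SimulationConfig(n_nodes=10, seed_cohort_size=8, n_planted=5)

    def test_planted_edges_bounded_by_cohort(self):
        with pytest.raises(ValueError, match="cohort size"):
            sim.SimulationConfig(seed_cohort_size=5, planted_seed_edges=6)

    def test_overlap_fraction_in_unit_interval(self):
        with pytest.raises(ValueError):
            sim.SimulationConfig(planted_pathway_overlap=1.5)


class TestGenerateNetwork:
    def test_same_seed_reproduces_byte_identical_files(self, tmp_path):
        config = sim.SimulationConfig(
            n_nodes=200, er_p=0.03, seed_cohort_size=20, n_planted=5,
            planted_seed_edges=6, rng_seed=9,
        )
        for sub in ("a", "b"):
            net, cohort, planted, truth = sim.generate_network(config)
            sim.write_simulation(tmp_path / sub, config, net, cohort, planted,
                                 truth)
        for name in ("edges.tsv", "seed.txt", "truth.tsv", "config.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_no_planted_genes_empty_truth(self):
        config = sim.SimulationConfig(
            n_nodes=100, er_p=0.05, seed_cohort_size=10, n_planted=0,
            planted_seed_edges=0, rng_seed=1,
        )
        _, _, planted, truth = sim.generate_network(config)
        assert planted == set() and truth.empty

    def test_planted_genes_reach_required_cohort_connectivity(self):
        config = sim.SimulationConfig(rng_seed=7)  # strong-signal defaults
        net, cohort, planted, truth = sim.generate_network(config)
        assert len(planted) == config.n_planted
        assert (truth["cohort_edges"] >= config.planted_seed_edges).all()
        for gene in planted:
            assert len(net.neighbors(gene) & cohort) >= config.planted_seed_edges

    def test_network_is_simple_graph(self):
        config = sim.SimulationConfig(
            n_nodes=150, er_p=0.04, seed_cohort_size=15, n_planted=4,
            planted_seed_edges=5, rng_seed=2,
        )
        net, _, _, _ = sim.generate_network(config)
        for a, b, _, _ in net.edges():
            assert a != b
        assert sum(net.degree(g) for g in net.nodes) == 2 * net.n_edges

    def test_configuration_model_heavy_tail(self):
        config = sim.SimulationConfig(
            n_nodes=800, edge_model="configuration", seed_cohort_size=30,
            n_planted=5, planted_seed_edges=8, rng_seed=3,
        )
        net, _, planted, truth = sim.generate_network(config)
        degrees = np.array([net.degree(g) for g in net.nodes])
        # power-law-ish: many leaves, a few hubs
        assert (degrees <= 2).mean() > 0.4
        assert degrees.max() >= 10
        assert (truth["cohort_edges"] >= config.planted_seed_edges).all()


class TestGeneratePathways:
    @pytest.fixture()
    def small_world(self):
        config = sim.SimulationConfig(
            n_nodes=300, er_p=0.02, seed_cohort_size=25, n_planted=10,
            planted_seed_edges=8, n_pathways=10, n_enriched=3,
            pathway_size_range=(20, 20), rng_seed=11,
        )
        net, cohort, planted, _ = sim.generate_network(config)
        return config, net, cohort, planted

    def test_same_seed_identical_gmt(self, small_world, tmp_path):
        config, net, cohort, planted = small_world
        from co_atlas.io import write_gmt

        for sub in ("a", "b"):
            pathways, _ = sim.generate_pathways(config, cohort, planted, net.nodes)
            (tmp_path / sub).mkdir()
            write_gmt(pathways, tmp_path / sub / "p.gmt")
        assert (tmp_path / "a" / "p.gmt").read_bytes() == (
            tmp_path / "b" / "p.gmt"
        ).read_bytes()

    def test_full_overlap_pathway_within_signal_pool(self, small_world):
        config, net, cohort, planted = small_world
        config = sim.SimulationConfig(
            **{**config.__dict__, "planted_pathway_overlap": 1.0,
               "pathway_size_range": (10, 10)}
        )
        pathways, truth = sim.generate_pathways(config, cohort, planted, net.nodes)
        pool = cohort | planted
        for pw in pathways:
            if truth[pw.id]:
                assert pw.members <= pool

    def test_truth_labels_match_enriched_count(self, small_world):
        config, net, cohort, planted = small_world
        _, truth = sim.generate_pathways(config, cohort, planted, net.nodes)
        assert sum(truth.values()) == config.n_enriched

    def test_size_exceeding_universe_is_error(self, small_world):
        config, net, cohort, planted = small_world
        bad = sim.SimulationConfig(
            **{**config.__dict__, "pathway_size_range": (400, 400)}
        )
        with pytest.raises(ValueError, match="universe"):
            sim.generate_pathways(bad, cohort, planted, net.nodes)

    def test_zero_overlap_membership_independent_of_cohort(self):
        """With planted_pathway_overlap = 0 the cohort is not over-represented:
        aggregated membership counts over 200 replicates pass a chi-square
        independence test at the 0.001 level."""
        universe = {f"G{i:04d}" for i in range(500)}
        cohort = {f"G{i:04d}" for i in range(60)}  # fixed 60-gene cohort
        in_cohort = out_cohort = 0
        n_pathways = 0
        for r in range(200):
            config = sim.SimulationConfig(
                n_nodes=500, seed_cohort_size=60, n_planted=0,
                planted_seed_edges=0, n_pathways=4, n_enriched=2,
                pathway_size_range=(30, 30), planted_pathway_overlap=0.0,
                rng_seed=40_000 + r,
            )
            pathways, _ = sim.generate_pathways(config, cohort, set(), universe)
            for pw in pathways:
                in_cohort += len(pw.members & cohort)
                out_cohort += len(pw.members - cohort)
                n_pathways += 1
        total_slots = in_cohort + out_cohort
        table = np.array(
            [
                [in_cohort, out_cohort],
                [
                    len(cohort) * n_pathways - in_cohort,
                    (len(universe) - len(cohort)) * n_pathways - out_cohort,
                ],
            ]
        )
        assert total_slots == 30 * n_pathways
        _, p_value, _, _ = chi2_contingency(table)
        assert p_value > 0.001


class TestPermuteSeedLabels:
    def test_full_size_returns_all_nodes(self):
        config = sim.SimulationConfig(
            n_nodes=50, er_p=0.1, seed_cohort_size=5, n_planted=0,
            planted_seed_edges=0, rng_seed=1,
        )
        net, _, _, _ = sim.generate_network(config)
        assert sim.permute_seed_labels(net, 50, 0) == net.nodes

    def test_zero_size_empty(self):
        config = sim.SimulationConfig(
            n_nodes=30, er_p=0.1, seed_cohort_size=3, n_planted=0,
            planted_seed_edges=0, rng_seed=1,
        )
        net, _, _, _ = sim.generate_network(config)
        assert sim.permute_seed_labels(net, 0, 0) == set()

    def test_distinct_seeds_give_distinct_subsets(self):
        config = sim.SimulationConfig(
            n_nodes=100, er_p=0.05, seed_cohort_size=5, n_planted=0,
            planted_seed_edges=0, rng_seed=1,
        )
        net, _, _, _ = sim.generate_network(config)
        draws = {
            frozenset(sim.permute_seed_labels(net, 10, s)) for s in range(50)
        }
        assert len(draws) > 45  # collisions astronomically unlikely

    def test_deterministic_per_seed(self):
        config = sim.SimulationConfig(
            n_nodes=40, er_p=0.1, seed_cohort_size=4, n_planted=0,
            planted_seed_edges=0, rng_seed=1,
        )
        net, _, _, _ = sim.generate_network(config)
        assert sim.permute_seed_labels(net, 8, 5) == sim.permute_seed_labels(
            net, 8, 5
        )


def test_simulation_bundle_gmt_parses_back(tmp_path):
    config = sim.SimulationConfig(
        n_nodes=120, er_p=0.05, seed_cohort_size=12, n_planted=4,
        planted_seed_edges=5, n_pathways=6, n_enriched=2,
        pathway_size_range=(8, 12), rng_seed=13,
    )
    net, cohort, planted, truth = sim.generate_network(config)
    pathways, _ = sim.generate_pathways(config, cohort, planted, net.nodes)
    sim.write_simulation(tmp_path, config, net, cohort, planted, truth, pathways)
    reloaded = read_gmt(tmp_path / "pathways.gmt")
    assert {p.id for p in reloaded} == {p.id for p in pathways}
    assert {p.id: p.members for p in reloaded} == {
        p.id: p.members for p in pathways
    }
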