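"""Generator ground truth: planted structure, closed-form checks, determinism."""

import itertools
import json

import numpy as np
import pytest
from scipy import special

from liconet.fingerprints import dice_similarity
from liconet.ppi_hub import mcc_scores
from liconet.stats import correlation_screen
from liconet.synthetic import (
    ConfigurationError,
    SimulationConfig,
    expected_intra_cluster_dice,
    gen_compound_library,
    gen_expression_matrix,
    gen_ppi_graph,
    gen_target_tables,
    write_bundle,
)
from liconet.targets import (
    compound_disease_intersection,
    consensus_deg,
    filter_disease_genes,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bit_density": 1.5},
            {"flip_rate": -0.1},
            {"noise_edge_prob": 2.0},
            {"planted_correlation": 1.2},
            {"core_size": 30, "target_set_size": 25},
            {"nbits": 32},
            {"nbits": 64, "bit_density": 0.001},
            {"clique_size": 1},
            {"clique_size": 500, "n_ppi_nodes": 100},
            {"n_samples": 3},
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_streams_are_independent(self):
        """Changing the expression block never perturbs the compound stream."""
        a = gen_compound_library(SimulationConfig(seed=3))
        b = gen_compound_library(
            SimulationConfig(seed=3, n_samples=50, n_expr_genes=10, n_corr_genes=2)
        )
        assert {k: v.on_bits for k, v in a.fingerprints.items()} == {
            k: v.on_bits for k, v in b.fingerprints.items()
        }


class TestCompoundLibrary:
    def test_counts_and_balanced_labels(self):
        cfg = SimulationConfig(seed=0, n_clusters=3, members_per_cluster=5, n_background=0)
        lib = gen_compound_library(cfg)
        assert len(lib.fingerprints) == 15
        labels = list(lib.labels.values())
        assert all(labels.count(k) == 5 for k in range(3))

    def test_zero_flip_rate_gives_identical_members(self):
        cfg = SimulationConfig(seed=1, n_clusters=2, members_per_cluster=4, n_background=0, flip_rate=0.0)
        lib = gen_compound_library(cfg)
        for k in range(2):
            members = [cid for cid, lab in lib.labels.items() if lab == k]
            for a, b in itertools.combinations(members, 2):
                assert dice_similarity(lib.fingerprints[a], lib.fingerprints[b]) == 1.0

    def test_mean_intra_dice_matches_closed_form(self):
        """Monte-Carlo mean of within-cluster Dice agrees with the analytic
        shared/total on-bit expectation under independent flips."""
        cfg = SimulationConfig(
            seed=2, n_clusters=8, members_per_cluster=12, n_background=0,
            flip_rate=0.01, bit_density=0.02, nbits=2048,
        )
        lib = gen_compound_library(cfg)
        sims = []
        for k in range(cfg.n_clusters):
            members = [cid for cid, lab in lib.labels.items() if lab == k]
            sims.extend(
                dice_similarity(lib.fingerprints[a], lib.fingerprints[b])
                for a, b in itertools.combinations(members, 2)
            )
        expected = expected_intra_cluster_dice(0.02, 0.01)
        assert np.mean(sims) == pytest.approx(expected, abs=0.01)

    def test_background_gets_singleton_labels(self):
        cfg = SimulationConfig(seed=0, n_background=5)
        lib = gen_compound_library(cfg)
        bg = [lab for cid, lab in lib.labels.items() if cid.startswith("BG")]
        assert len(set(bg)) == 5 and all(lab < 0 for lab in bg)


class TestTargetTables:
    def test_planted_structure_recovered_by_downstream_filters(self):
        cfg = SimulationConfig(seed=9)
        tables = gen_target_tables(cfg)
        disease = filter_disease_genes(tables.disease_scores)
        assert disease.genes == tables.disease.genes
        degs_dir = consensus_deg(tables.deg_table, k=3)
        degs = degs_dir["up"].genes | degs_dir["down"].genes
        assert degs == tables.deg_consensus.genes
        for comp, gs in tables.compound_targets.items():
            inter = compound_disease_intersection(gs, disease, degs_dir["up"])
            # up-only intersection is a subset; the full intersection is exact
            assert inter.genes <= gs.genes
            full = gs.genes & disease.genes & degs
            assert full == gs.genes
            assert len(gs) == cfg.target_set_size

    def test_equal_target_sizes_give_planted_intersection_size(self):
        cfg = SimulationConfig(seed=4)
        tables = gen_target_tables(cfg)
        disease = filter_disease_genes(tables.disease_scores)
        degs_dir = consensus_deg(tables.deg_table, k=3)
        degs = degs_dir["up"].genes | degs_dir["down"].genes
        for gs in tables.compound_targets.values():
            assert len(gs.genes & disease.genes & degs) == cfg.target_set_size


class TestPPIGraph:
    def test_pure_clique_is_k4_with_mcc_six(self):
        cfg = SimulationConfig(seed=0, clique_size=4, n_ppi_nodes=4, noise_edge_prob=0.0)
        ppi = gen_ppi_graph(cfg)
        g = ppi.graph()
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 6
        scores = mcc_scores(g).scores
        assert all(scores[v] == 6 for v in ppi.clique)

    def test_single_edge_clique_both_endpoints_score_one(self):
        cfg = SimulationConfig(seed=0, clique_size=2, n_ppi_nodes=2, noise_edge_prob=0.0)
        ppi = gen_ppi_graph(cfg)
        scores = mcc_scores(ppi.graph()).scores
        assert list(scores.values()) == [1, 1]

    def test_no_self_loops_or_duplicate_edges(self):
        cfg = SimulationConfig(seed=3, noise_edge_prob=0.05)
        ppi = gen_ppi_graph(cfg)
        pairs = list(zip(ppi.edges["gene_a"], ppi.edges["gene_b"]))
        assert all(a != b for a, b in pairs)
        assert len({frozenset(p) for p in pairs}) == len(pairs)


class TestExpression:
    def test_perfect_correlation_reproduced_exactly(self):
        cfg = SimulationConfig(seed=0, planted_correlation=1.0, n_expr_genes=5, n_corr_genes=2)
        planted = gen_expression_matrix(cfg)
        screen = correlation_screen(planted.expr, planted.query)
        for gene in planted.planted_genes:
            assert screen.loc[screen.gene == gene, "r"].item() == pytest.approx(1.0, abs=1e-9)

    def test_null_mean_abs_correlation_matches_theory(self):
        """Under ρ_g = 0 the mean |r| across genes matches the closed-form
        null expectation E|r| = (1/(a+1)) / B(1/2, a+1), a = (S-4)/2."""
        S = 200
        cfg = SimulationConfig(
            seed=1, planted_correlation=0.0, n_samples=S, n_expr_genes=400, n_corr_genes=0
        )
        planted = gen_expression_matrix(cfg)
        screen = correlation_screen(planted.expr, planted.query)
        rest = screen[screen.gene != planted.query]
        a = (S - 4) / 2
        expected = (1 / (a + 1)) / special.beta(0.5, a + 1)
        assert rest["r"].abs().mean() == pytest.approx(expected, abs=0.01)

    def test_shape_with_minimal_samples(self):
        cfg = SimulationConfig(seed=0, n_samples=4, n_expr_genes=3, n_corr_genes=0)
        planted = gen_expression_matrix(cfg)
        assert planted.expr.shape == (4, 4)  # 3 genes + query column


class TestBundleDeterminism:
    def test_same_config_writes_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=12)
        paths_a = write_bundle(cfg, tmp_path / "a")
        paths_b = write_bundle(cfg, tmp_path / "b")
        assert paths_a.keys() == paths_b.keys()
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key

    def test_seed_recorded_in_sidecar(self, tmp_path):
        cfg = SimulationConfig(seed=77)
        paths = write_bundle(cfg, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == 77
        assert len(truth["core_genes"]) == cfg.core_size
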