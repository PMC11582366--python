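import numpy as np
import pytest

import isoanchor as ia
from isoanchor.errors import ValidationError
from isoanchor.markers import MarkerSet
from isoanchor.qc import completeness
from isoanchor.simulate import (
    ANCHOR_ID,
    SimulationConfig,
    compose_divergence,
    expected_ani_classes,
    load_ground_truth,
    mutate_sequence,
    planted_rank_counts,
    simulate_incomplete_genomes,
    simulate_marker_inventories,
    simulate_recruitment,
    simulate_taxonomy,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimulationConfig()

    def test_mismatched_family_vectors_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_families=3)

    def test_infeasible_losses_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(marker_universe_size=30, anchor_missing=28,
                             family_extra_losses=(12, 24, 11, 1))

    def test_non_monotone_divergence_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(within_genus_divergence=0.3)

    def test_single_genome_genus_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(genomes_per_genus=1)


class TestTaxonomy:
    def test_minimal_config_collapses_family_into_root(self):
        cfg = SimulationConfig(
            n_families=1, genera_per_family=(1,), genomes_per_genus=2,
            family_extra_losses=(1,), family_surface_shares=(1.0,),
            family_depth_gradients=(0.0,),
        )
        tree, labels = simulate_taxonomy(cfg)
        # root -> (genus node with 2 leaves, anchor leaf); no unary family node
        nodes = list(tree.preorder_node_iter())
        assert sum(1 for n in nodes if n.is_leaf()) == 3  # incl. anchor
        assert len(nodes) == 5
        assert all(len(n.child_nodes()) != 1 for n in nodes)
        assert planted_rank_counts(cfg) == {"family": 0, "genus": 1}
        red = ia.compute_red(tree)
        ranks = ia.assign_ranks(red, tree)
        assert ranks.counts["genus"] == 1

    def test_default_structure(self):
        cfg = SimulationConfig(seed=3)
        tree, labels = simulate_taxonomy(cfg)
        assert len(labels) == 4 * 0 + sum(g * 3 for g in cfg.genera_per_family) + 1
        assert labels["is_anchor"].sum() == 1
        assert labels.loc[labels["is_anchor"], "genome_id"].iloc[0] == ANCHOR_ID
        assert labels["family"].nunique() == 4
        assert labels["genus"].nunique() == 23  # 22 environmental + anchor genus

    def test_planted_nodes_land_in_red_bands(self):
        cfg = SimulationConfig(seed=5)
        tree, labels = simulate_taxonomy(cfg)
        red = ia.compute_red(tree)
        ranks = ia.assign_ranks(red, tree)
        assert ranks.counts == planted_rank_counts(cfg)


class TestMarkerInventories:
    def test_anchor_misses_exactly_the_anchor_absent_set(self):
        cfg = SimulationConfig(seed=2)
        _, labels = simulate_taxonomy(cfg)
        matrix, losses = simulate_marker_inventories(labels, cfg)
        universe = set(matrix.marker_universe.markers)
        assert len(losses["anchor_absent"]) == cfg.anchor_missing
        assert matrix[ANCHOR_ID].present == universe - set(losses["anchor_absent"])

    def test_family_losses_are_anchor_absent_plus_extras(self):
        cfg = SimulationConfig(seed=2)
        _, labels = simulate_taxonomy(cfg)
        matrix, losses = simulate_marker_inventories(labels, cfg)
        for fam, extra in zip(cfg.family_names, cfg.family_extra_losses):
            assert len(losses["family_extra"][fam]) == extra
            assert set(losses["family_losses"][fam]) == (
                set(losses["anchor_absent"]) | set(losses["family_extra"][fam])
            )
        # every environmental genome lacks exactly its family's losses
        for row in labels.itertuples(index=False):
            if row.is_anchor:
                continue
            missing = set(matrix.marker_universe.markers) - matrix[row.genome_id].present
            assert missing == set(losses["family_losses"][row.family])


class TestIncompleteGenomes:
    def test_planted_completeness_085_recovered_within_2_points(self):
        cfg = SimulationConfig(
            seed=9, completeness_min=0.85, completeness_max=0.85,
            genera_per_family=(10, 10, 10, 10), genomes_per_genus=5,
        )
        _, labels = simulate_taxonomy(cfg)
        true_matrix, losses = simulate_marker_inventories(labels, cfg)
        observed, records, planted, _ = simulate_incomplete_genomes(true_matrix, labels, cfg)
        measured = []
        for row in labels.itertuples(index=False):
            if row.is_anchor:
                continue
            fam_set = MarkerSet(
                "true",
                tuple(
                    m for m in true_matrix.marker_universe.markers
                    if m not in set(losses["family_losses"][row.family])
                ),
            )
            measured.append(completeness(observed[row.genome_id], fam_set))
        assert 83.0 <= float(np.mean(measured)) <= 87.0

    def test_anchor_stays_complete(self):
        cfg = SimulationConfig(seed=4)
        _, labels = simulate_taxonomy(cfg)
        true_matrix, _ = simulate_marker_inventories(labels, cfg)
        observed, records, planted, true_length = simulate_incomplete_genomes(
            true_matrix, labels, cfg
        )
        assert planted[ANCHOR_ID] == 1.0
        assert observed[ANCHOR_ID].present == true_matrix[ANCHOR_ID].present
        assert records[ANCHOR_ID].assembly_length == pytest.approx(true_length[ANCHOR_ID])

    def test_block_dropout_mode(self):
        cfg = SimulationConfig(seed=4, dropout_mode="block")
        _, labels = simulate_taxonomy(cfg)
        true_matrix, _ = simulate_marker_inventories(labels, cfg)
        observed, _, planted, _ = simulate_incomplete_genomes(true_matrix, labels, cfg)
        gid = labels.loc[~labels["is_anchor"], "genome_id"].iloc[0]
        assert observed[gid].present <= true_matrix[gid].present


class TestSequences:
    def test_mutate_sequence_rate(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, 200000, dtype=np.uint8)
        mutated = mutate_sequence(codes, 0.1, np.random.default_rng(1))
        frac = float((codes != mutated).mean())
        assert frac == pytest.approx(0.1, abs=0.005)

    def test_compose_divergence(self):
        assert compose_divergence(0.0, 0.3) == pytest.approx(0.3)
        # saturation: two long branches approach 0.75, never exceed it
        assert compose_divergence(0.74, 0.74) < 0.75

    def test_expected_ani_ladder_matches_config(self):
        cfg = SimulationConfig()
        classes = expected_ani_classes(cfg)
        assert classes["within_genus"] > 93.0 > classes["within_family"]
        assert classes["within_family"] > classes["between_family"]
        # small-rate composition keeps totals near the configured ladder
        assert classes["within_genus"] == pytest.approx(
            100 * (1 - cfg.within_genus_divergence), abs=0.1
        )


class TestRecruitment:
    def test_sample_grid_and_probability_budget(self):
        cfg = SimulationConfig(seed=6)
        _, labels = simulate_taxonomy(cfg)
        true_matrix, _ = simulate_marker_inventories(labels, cfg)
        _, records, _, _ = simulate_incomplete_genomes(true_matrix, labels, cfg)
        summaries, truth = simulate_recruitment(labels, records, cfg)
        n_samples = len(cfg.regions) * len(cfg.sample_depths) * cfg.samples_per_condition
        assert len({s.sample_id for s in summaries}) == n_samples
        assert len(summaries) == n_samples * len(labels)
        for sample, fams in truth["expected_family_abundance"].items():
            assert sum(fams.values()) <= 100.0
        # genus shares sum to 1 within each family
        for fam in cfg.family_names:
            genera = labels.loc[labels["family"] == fam, "genus"].unique()
            assert sum(truth["genus_share"][g] for g in genera) == pytest.approx(1.0)


class TestBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=11)
        p1 = ia.simulate_bundle(cfg, tmp_path / "a")
        p2 = ia.simulate_bundle(cfg, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        a = ia.simulate_bundle(SimulationConfig(seed=1), tmp_path / "a")
        b = ia.simulate_bundle(SimulationConfig(seed=2), tmp_path / "b")
        assert a["marker_hits"].read_bytes() != b["marker_hits"].read_bytes()

    def test_validate_bundle_passes_and_catches_tampering(self, default_bundle, tmp_path):
        assert ia.validate_bundle(default_bundle)
        tampered = tmp_path / "tampered"
        tampered.mkdir()
        for f in default_bundle.iterdir():
            (tampered / f.name).write_bytes(f.read_bytes())
        truth = load_ground_truth(tampered)
        hits = (tampered / "marker_hits.tsv").read_text().splitlines()
        lost = truth["anchor_absent"][0]
        hits.append(f"{ANCHOR_ID}\t{lost}\t1")
        (tampered / "marker_hits.tsv").write_text("\n".join(hits) + "\n")
        with pytest.raises(ValidationError):
            ia.validate_bundle(tampered)
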