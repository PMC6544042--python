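import numpy as np
import pytest

from efp_loopscape.simulate import (
    AMINO_ACIDS,
    BACKBONE,
    PairedCharacterModel,
    SimulationConfig,
    emit_protein_set,
    make_pair_model,
    simulate_character,
    simulate_dataset,
    simulate_paired_characters,
    simulate_yule_tree,
)
from efp_loopscape.trees import serialize_newick, tree_height


class TestYuleTree:
    def test_single_leaf_degenerate(self):
        tree = simulate_yule_tree(1, 1.0, 7)
        leaves = tree.leaf_nodes()
        assert len(leaves) == 1
        assert leaves[0].taxon.label == "G0001"
        assert sum(1 for _ in tree.preorder_node_iter()) == 1

    def test_two_leaves_single_split(self):
        tree = simulate_yule_tree(2, 1.0, 7)
        assert len(tree.leaf_nodes()) == 2
        assert len(tree.seed_node.child_nodes()) == 2
        for leaf in tree.leaf_nodes():
            assert leaf.edge.length > 0

    @pytest.mark.parametrize("n_tips", [5, 40])
    def test_leaf_count_and_unique_labels(self, n_tips):
        tree = simulate_yule_tree(n_tips, 2.0, 123)
        labels = [l.taxon.label for l in tree.leaf_nodes()]
        assert len(labels) == n_tips == len(set(labels))
        assert all(l.startswith("G") for l in labels)

    def test_mean_root_height_matches_pure_birth_expectation(self):
        # E[height] = sum_{k=2..n} 1/(k * birth_rate) for the conditioned
        # pure-birth process (analytic waiting-time oracle)
        n, rate, reps = 100, 1.0, 1000
        heights = np.array(
            [tree_height(simulate_yule_tree(n, rate, seed)) for seed in range(reps)]
        )
        expected = sum(1.0 / (k * rate) for k in range(2, n + 1))
        se = heights.std(ddof=1) / np.sqrt(reps)
        assert abs(heights.mean() - expected) < 3 * se

    def test_deterministic_under_seed(self):
        a = serialize_newick(simulate_yule_tree(20, 1.5, 42))
        b = serialize_newick(simulate_yule_tree(20, 1.5, 42))
        c = serialize_newick(simulate_yule_tree(20, 1.5, 43))
        assert a == b
        assert a != c

    @pytest.mark.parametrize("n,rate", [(0, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_parameters(self, n, rate):
        with pytest.raises(ValueError):
            simulate_yule_tree(n, rate, 1)


class TestPairedCharacters:
    def test_zero_rates_freeze_root_state(self):
        tree = simulate_yule_tree(10, 1.0, 5)
        k = len(PairedCharacterModel().joint_states)
        model = PairedCharacterModel(rate_matrix=np.zeros((k, k)), root_state=("R", "X"))
        states = simulate_paired_characters(tree, model, 9)
        assert set(states.values()) == {("R", "X")}

    def test_zero_branch_lengths_freeze_root_state(self):
        tree = simulate_yule_tree(8, 1.0, 5)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.0
        states = simulate_paired_characters(tree, make_pair_model(), 9)
        assert set(states.values()) == {("K", "P")}

    def test_every_node_labeled_and_assigned(self):
        tree = simulate_yule_tree(12, 1.0, 6)
        states = simulate_paired_characters(tree, make_pair_model(), 1)
        n_nodes = sum(1 for _ in tree.preorder_node_iter())
        assert len(states) == n_nodes

    def test_single_edge_change_fraction_matches_matrix_exponential(self):
        # 2-state symmetric chain on one edge: the realized change fraction
        # over many replicate draws must match expm of the rate matrix
        from efp_loopscape.trees import parse_newick
        from scipy.linalg import expm

        mu, t, reps = 0.8, 0.6, 10000
        q = np.array([[-mu, mu], [mu, -mu]])
        p_change = expm(q * t)[0, 1]
        changes = 0
        tree = parse_newick(f"(A:{t});")
        tree.is_rooted = True
        for seed in range(reps):
            states = simulate_character(tree, q, ("0", "1"), "0", seed)
            if states["A"] == "1":
                changes += 1
        frac = changes / reps
        se = np.sqrt(p_change * (1 - p_change) / reps)
        assert abs(frac - p_change) < 3 * se

    def test_deterministic_under_seed(self):
        tree = simulate_yule_tree(15, 1.0, 2)
        a = simulate_paired_characters(tree, make_pair_model(), 7)
        b = simulate_paired_characters(tree, make_pair_model(), 7)
        assert a == b


class TestPairModel:
    def test_rows_sum_to_zero_and_offdiag_nonneg(self):
        q = make_pair_model().rate_matrix
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        off = q - np.diag(np.diag(q))
        assert (off >= 0).all()

    def test_coupling_override(self):
        m = make_pair_model(coupling=0.9)
        # rate X->P given K is relax * 0.9; P->X given K is relax * 0.1
        i_kx = m.joint_states.index(("K", "X"))
        i_kp = m.joint_states.index(("K", "P"))
        assert m.rate_matrix[i_kx, i_kp] / (
            m.rate_matrix[i_kx, i_kp] + m.rate_matrix[i_kp, i_kx]
        ) == pytest.approx(0.9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            make_pair_model(coupling=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=0)
        with pytest.raises(ValueError):
            SimulationConfig(decoy_fraction=1.0)


class TestEmission:
    def test_noiseless_emission_matches_consensus(self, noiseless_dataset):
        res = noiseless_dataset
        leaf_states = res.leaf_states()
        efp_ids = set(res.truth.loc[res.truth["kind"] == "efp", "protein_id"])
        for rec in res.records:
            if rec.protein_id not in efp_ids:
                continue
            genome = rec.genome_id
            tip, m2 = leaf_states[genome]
            window = rec.sequence[30:37]
            assert window[3] == tip
            assert (window[1] == "P") == (m2 == "P")
            # outside the window the backbone is untouched at zero noise
            assert rec.sequence[:30] == BACKBONE[:30]
            assert rec.sequence[37:] == BACKBONE[37:]

    def test_efp_records_carry_exactly_three_domains(self, noiseless_dataset):
        res = noiseless_dataset
        by_protein = {}
        for h in res.hits:
            if h.evalue <= 1e-3:
                by_protein.setdefault(h.protein_id, set()).add(h.domain_name)
        efp_ids = set(res.truth.loc[res.truth["kind"] == "efp", "protein_id"])
        for pid in efp_ids:
            assert by_protein[pid] == {"EFP_N", "EFP", "Elong-fact-P_C"}

    def test_decoy_count_recountable(self, small_dataset):
        res = small_dataset
        n_decoys = (res.truth["kind"].isin(["yeip", "wrong_architecture"])).sum()
        assert n_decoys == round(res.config.decoy_fraction * res.config.n_tips)

    def test_conservation_counts(self, small_dataset):
        res = small_dataset
        n_leaves = len(res.tree.leaf_nodes())
        assert (res.truth["kind"] == "efp").sum() == n_leaves
        assert set(res.annotations["genome_id"]) == {
            l.taxon.label for l in res.tree.leaf_nodes()
        }

    def test_leaf_without_state_raises(self):
        tree = simulate_yule_tree(4, 1.0, 1)
        cfg = SimulationConfig(n_tips=4, seed=1)
        with pytest.raises(ValueError, match="state"):
            emit_protein_set(tree, {}, cfg)

    def test_byte_identical_outputs(self, tmp_path):
        import filecmp

        for tag in ("a", "b"):
            simulate_dataset(SimulationConfig(n_tips=25, seed=17)).write(tmp_path / tag)
        for name in (tmp_path / "a").iterdir():
            assert filecmp.cmp(name, tmp_path / "b" / name.name, shallow=False)


class TestCouplingStatistics:
    def test_leaf_cooccurrence_tracks_configured_coupling(self):
        # >= 2000 leaves; observed P(P | K) within 3 binomial SE of c
        c = 0.95
        cfg = SimulationConfig(
            n_tips=2000,
            seed=21,
            pair_model=make_pair_model(coupling=c),
            decoy_fraction=0.0,
            backbone_noise_rate=0.0,
        )
        res = simulate_dataset(cfg)
        efp = res.truth[res.truth["kind"] == "efp"]
        k_rows = efp[efp["tip"] == "K"]
        frac = (k_rows["minus2"] == "P").mean()
        se = np.sqrt(c * (1 - c) / len(k_rows))
        assert abs(frac - c) < 3 * se
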