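"""Inner composition alignment: exactness, asymmetry, significance, networks."""

import numpy as np
import pandas as pd
import pytest
from _oracles import iota_bruteforce

from ccmgrn import synthetic
from ccmgrn.iota import (
    DirectedNetwork,
    degree_stats,
    extract_subnetwork,
    iota,
    iota_pvalue,
    read_edge_list,
    reconstruct_network,
    shared_targets,
    sorting_permutation,
)


class TestSortingPermutation:
    def test_unsorted_vector(self):
        assert list(sorting_permutation([3, 1, 2])) == [1, 2, 0]

    def test_sorted_is_identity(self):
        assert list(sorting_permutation([1.0, 2.0, 5.0])) == [0, 1, 2]

    def test_all_ties_stable_identity(self):
        assert list(sorting_permutation([7, 7, 7, 7])) == [0, 1, 2, 3]


class TestIotaScore:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),          # monotone: no crossing
            ([1, 2, 3, 4], [2, 4, 1, 3], 1 / 3),        # two crossings of three
            ([1, 2, 3, 4], [1, 4, 2, 3], 1.0),          # forward direction
            ([1, 4, 2, 3], [1, 2, 3, 4], 2 / 3),        # ... but not backward
            ([1, 2, 3], [3, 2, 1], 1.0),                # decreasing is monotone too
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert iota(x, y).iota == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(1000):
            m = int(rng.integers(3, 11))
            x = rng.normal(size=m)
            y = rng.normal(size=m)
            assert iota(x, y).iota == iota_bruteforce(list(x), list(y))

    def test_invariant_under_increasing_transforms(self, rng):
        for _ in range(50):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            base = iota(x, y).iota
            assert iota(np.exp(x), y).iota == base
            assert iota(x, y ** 3 + 2 * y).iota == base  # strictly increasing

    def test_monotone_relation_scores_one(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            assert iota(x, np.exp(x)).iota == 1.0
            assert iota(x, -x ** 3).iota == 1.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            iota([1, 2], [3, 4])


class TestIotaPvalue:
    def test_constant_target_degenerate_null(self):
        # every permutation of a constant series is monotone: p = 1
        assert iota_pvalue([1, 2, 3, 4], [5, 5, 5, 5], n_perm=200, seed=0) == 1.0

    def test_monotone_pair_significant_at_m12(self):
        x = np.arange(12.0)
        y = np.arange(12.0) ** 2
        assert iota_pvalue(x, y, n_perm=10000, seed=1) <= 0.01

    def test_seed_determinism(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        a = iota_pvalue(x, y, n_perm=500, seed=7)
        assert a == iota_pvalue(x, y, n_perm=500, seed=7)
        assert 0 < a <= 1

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            iota_pvalue([1, 2, 3], [1, 2, 3], n_perm=0)


class TestReconstructNetwork:
    def test_single_gene_empty_network(self):
        net = reconstruct_network(pd.DataFrame([[1.0, 2.0, 3.0]]), n_perm=50)
        assert net.edges.empty and net.nodes == ["0"]

    def test_contract_on_coupled_system(self):
        exp = synthetic.simulate_grn_timeseries(
            10, edge_density=0.18, coupling=3.0, noise_sd=0.05,
            n_timepoints=12, n_replicates=1, seed=5,
        )
        prof = pd.DataFrame(np.log2(exp.expression[:, :, 0]),
                            index=exp.gene_ids)
        net = reconstruct_network(prof, alpha=0.01, n_perm=2000, seed=9)
        off_diag = ~np.eye(len(net.nodes), dtype=bool)
        assert np.isfinite(net.iota_matrix.to_numpy()[off_diag]).all()
        assert np.isfinite(net.p_matrix.to_numpy()[off_diag]).all()
        assert (net.edges["p"] <= 0.01).all()
        assert not (net.edges["regulator"] == net.edges["target"]).any()

    def test_seed_determinism(self, rng):
        prof = pd.DataFrame(rng.normal(size=(5, 12)))
        a = reconstruct_network(prof, n_perm=300, seed=3)
        b = reconstruct_network(prof, n_perm=300, seed=3)
        pd.testing.assert_frame_equal(a.p_matrix, b.p_matrix)

    def test_constant_profile_excluded_with_warning(self):
        prof = pd.DataFrame([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]],
                            index=["a", "b", "c"], dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            net = reconstruct_network(prof, n_perm=50, seed=0)
        assert net.excluded == ["b"]
        assert net.nodes == ["a", "c"]

    def test_edge_recovery_on_planted_pairs(self):
        """Direct edges separate from everything else on paired topologies."""
        edges = [(0, 5), (1, 6), (2, 7), (3, 8), (4, 9)]
        true_scores, other_scores = [], []
        for seed in range(20):
            exp = synthetic.simulate_grn_timeseries(
                10, edge_density=0.1, coupling=3.0, noise_sd=0.05,
                n_timepoints=12, n_replicates=5, seed=seed, edges=edges,
            )
            prof = np.log2(exp.expression).mean(axis=2)
            for i in range(10):
                for j in range(10):
                    if i == j:
                        continue
                    score = iota(prof[i], prof[j]).iota
                    if (i, j) in set(edges):
                        true_scores.append(score)
                    else:
                        other_scores.append(score)
        assert np.median(true_scores) > np.percentile(other_scores, 95)


    def test_bh_correction_is_more_conservative(self, rng):
        prof = pd.DataFrame(rng.normal(size=(8, 12)))
        raw = reconstruct_network(prof, alpha=0.05, n_perm=500, seed=4)
        bh = reconstruct_network(prof, alpha=0.05, n_perm=500, seed=4,
                                 correction="bh")
        assert len(bh.edges) <= len(raw.edges)
        pd.testing.assert_frame_equal(raw.p_matrix, bh.p_matrix)


class TestDegreeStats:
    def test_hand_counted_triangle(self):
        edges = pd.DataFrame(
            [("A", "B", 1.0, 0.001), ("A", "C", 1.0, 0.001),
             ("B", "C", 1.0, 0.001)],
            columns=["regulator", "target", "iota", "p"],
        )
        net = DirectedNetwork(
            nodes=["A", "B", "C"], edges=edges,
            iota_matrix=pd.DataFrame(), p_matrix=pd.DataFrame(),
            alpha=0.01, n_perm=100,
        )
        stats = degree_stats(net)
        assert stats["mean_out_degree"] == 1.0
        assert stats["out_degree"] == {"A": 2, "B": 1, "C": 0}

    def test_empty_edge_set_all_zero(self):
        net = DirectedNetwork(
            nodes=["A", "B"],
            edges=pd.DataFrame(columns=["regulator", "target", "iota", "p"]),
            iota_matrix=pd.DataFrame(), p_matrix=pd.DataFrame(),
            alpha=0.01, n_perm=100,
        )
        assert degree_stats(net)["mean_out_degree"] == 0.0

    def test_empty_node_set_raises(self):
        net = DirectedNetwork(
            nodes=[], edges=pd.DataFrame(columns=["regulator", "target",
                                                  "iota", "p"]),
            iota_matrix=pd.DataFrame(), p_matrix=pd.DataFrame(),
            alpha=0.01, n_perm=100,
        )
        with pytest.raises(ValueError):
            degree_stats(net)

    def test_read_edge_list_roundtrip(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("regulator\ttarget\tp\nA\tB\t0.001\nA\tC\t0.002\n")
        g = read_edge_list(path)
        assert degree_stats(g)["n_edges"] == 2


class TestSubnetwork:
    @pytest.fixture()
    def planted_network(self):
        """Lcr1-like regulator with 5 targets, 4 shared with a second TF."""
        pairs = ([("Lcr1", t) for t in ("a", "b", "c", "d", "e")]
                 + [("Lcr2", t) for t in ("b", "c", "d", "e")])
        edges = pd.DataFrame(
            [(r, t, 1.0, 0.001) for r, t in pairs],
            columns=["regulator", "target", "iota", "p"],
        )
        nodes = ["Lcr1", "Lcr2", "a", "b", "c", "d", "e", "isolated"]
        return DirectedNetwork(
            nodes=nodes, edges=edges,
            iota_matrix=pd.DataFrame(index=nodes, columns=nodes),
            p_matrix=pd.DataFrame(index=nodes, columns=nodes),
            alpha=0.01, n_perm=100,
        )

    def test_planted_targets_recovered(self, planted_network):
        sub = extract_subnetwork(planted_network, ["Lcr1"])
        targets = set(sub.edges[sub.edges["regulator"] == "Lcr1"]["target"])
        assert targets == {"a", "b", "c", "d", "e"}
        assert "isolated" not in sub.nodes

    def test_shared_targets_of_two_regulators(self, planted_network):
        assert shared_targets(planted_network, "Lcr1", "Lcr2") == {
            "b", "c", "d", "e"}

    def test_seed_without_outgoing_edges(self, planted_network):
        sub = extract_subnetwork(planted_network, ["isolated"])
        assert sub.nodes == ["isolated"] and sub.edges.empty

    def test_unknown_seed_raises(self, planted_network):
        with pytest.raises(KeyError):
            extract_subnetwork(planted_network, ["nope"])
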