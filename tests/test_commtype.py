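"""UniFrac, UPGMA, pseudo-F, diversity and PCoA: hand oracles and properties."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from semtype import commtype
from semtype.commtype import (
    CommunityTyper,
    chao1,
    choose_k,
    compare_group_diversity,
    diversity_table,
    pcoa,
    pseudo_f,
    shannon,
    unifrac_matrix,
    upgma_cluster,
    weighted_unifrac,
)

from conftest import random_tree


def brute_force_weighted_unifrac(newick: str, pA: dict, pB: dict) -> float:
    """Independent oracle: enumerate every branch with dendropy, sum
    length * |A-through - B-through|, normalize by abundance-weighted
    root-to-leaf depths."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    raw = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        leaves = [lf.taxon.label for lf in edge.head_node.leaf_iter()]
        a = sum(pA.get(l, 0.0) for l in leaves)
        b = sum(pB.get(l, 0.0) for l in leaves)
        raw += edge.length * abs(a - b)
    denom = 0.0
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        node = leaf
        while node.parent_node is not None:
            depth += node.edge.length or 0.0
            node = node.parent_node
        lbl = leaf.taxon.label
        denom += depth * (pA.get(lbl, 0.0) + pB.get(lbl, 0.0))
    return raw / denom if denom else 0.0


def tree_of(newick: str) -> TreeNode:
    return TreeNode.read([newick], convert_underscores=False)


class TestWeightedUnifrac:
    def test_identical_profiles_have_zero_distance(self):
        t = tree_of("((L1:1,L2:1):1,(L3:1,L4:1):1);")
        p = {"L1": 0.25, "L2": 0.25, "L3": 0.25, "L4": 0.25}
        assert weighted_unifrac(p, p, t) == 0.0

    def test_disjoint_two_leaf_profiles_are_maximally_distant(self):
        t = tree_of("(L1:1,L2:1);")
        assert np.isclose(weighted_unifrac({"L1": 1.0}, {"L2": 1.0}, t), 1.0)

    def test_four_leaf_hand_case_matches_brute_force(self):
        nwk = "((L1:1,L2:1):1,(L3:1,L4:1):1);"
        pA = {"L1": 0.5, "L2": 0.5}
        pB = {"L3": 0.5, "L4": 0.5}
        got = weighted_unifrac(pA, pB, tree_of(nwk))
        assert np.isclose(got, brute_force_weighted_unifrac(nwk, pA, pB))
        # by hand: raw = 1*.5+1*.5+1*1+1*.5+1*.5+1*1 = 4; denom = 4*2*.5 = 4
        assert np.isclose(got, 1.0)

    def test_oracle_equivalence_on_random_trees(self):
        """200 random trees (<= 8 leaves) with random Dirichlet profiles agree
        with the branch-enumeration oracle."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            nwk = random_tree(rng, n)
            leaves = [f"L{i}" for i in range(n)]
            pA = dict(zip(leaves, rng.dirichlet(np.ones(n))))
            pB = dict(zip(leaves, rng.dirichlet(np.ones(n))))
            got = weighted_unifrac(pA, pB, tree_of(nwk))
            want = brute_force_weighted_unifrac(nwk, pA, pB)
            assert np.isclose(got, want), (nwk, pA, pB)
            assert 0.0 <= got <= 1.0 + 1e-12
            sym = weighted_unifrac(pB, pA, tree_of(nwk))
            assert np.isclose(got, sym)

    def test_agrees_with_skbio_reference_implementation(self):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        rng = np.random.default_rng(5)
        nwk = random_tree(rng, 6)
        leaves = [f"L{i}" for i in range(6)]
        ca = rng.integers(1, 1000, size=6)
        cb = rng.integers(1, 1000, size=6)
        a, b = ca / ca.sum(), cb / cb.sum()
        got = weighted_unifrac(dict(zip(leaves, a)), dict(zip(leaves, b)), tree_of(nwk))
        want = skbio_wu(ca, cb, taxa=leaves, tree=tree_of(nwk), normalized=True)
        assert np.isclose(got, float(want))

    def test_unknown_leaf_rejected(self):
        t = tree_of("(L1:1,L2:1);")
        with pytest.raises(ValueError):
            weighted_unifrac({"L9": 1.0}, {"L1": 1.0}, t)

    def test_non_simplex_rejected(self):
        t = tree_of("(L1:1,L2:1);")
        with pytest.raises(ValueError):
            weighted_unifrac({"L1": 0.7}, {"L2": 1.0}, t)

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(3)
        nwk = random_tree(rng, 5)
        leaves = [f"L{i}" for i in range(5)]
        profiles = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=4), index=list("abcd"), columns=leaves
        )
        dm = unifrac_matrix(profiles, tree_of(nwk))
        for i, si in enumerate("abcd"):
            for j, sj in enumerate("abcd"):
                want = weighted_unifrac(
                    profiles.loc[si], profiles.loc[sj], tree_of(nwk)
                )
                assert np.isclose(dm[i, j], want)


class TestUPGMA:
    def test_three_point_hand_case(self):
        dm = DistanceMatrix(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], ids=["a", "b", "c"]
        )
        den = upgma_cluster(dm)
        assert den.linkage[0, 0] == 0 and den.linkage[0, 1] == 1
        assert den.linkage[0, 2] == 0.5  # merge height = d/2
        assert den.linkage[1, 2] == 5.0

    def test_equal_distances_follow_lexicographic_tie_break(self):
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=["d", "b", "a", "c"])
        den = upgma_cluster(dm)
        # first merge must be the lexicographically smallest pair: (a, b)
        first = {den.ids[int(den.linkage[0, 0])], den.ids[int(den.linkage[0, 1])]}
        assert first == {"a", "b"}

    def test_two_samples_single_merge(self):
        dm = DistanceMatrix([[0, 2], [2, 0]], ids=["a", "b"])
        den = upgma_cluster(dm)
        assert den.linkage.shape == (1, 4)
        assert den.cut(2).tolist() == ["G1", "G2"]

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(8)
        x = rng.random((12, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        den = upgma_cluster(dm)
        z = linkage(squareform(d), method="average")
        np.testing.assert_allclose(sorted(den.linkage[:, 2]), sorted(z[:, 2] / 2))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            upgma_cluster(DistanceMatrix([[0.0]], ids=["a"]))

    def test_newick_export_roundtrips_leaves(self):
        dm = DistanceMatrix([[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=["a", "b", "c"])
        nwk = upgma_cluster(dm).to_newick()
        t = TreeNode.read([nwk])
        assert {lf.name for lf in t.tips()} == {"a", "b", "c"}


class TestPseudoF:
    def test_two_far_clouds_match_hand_formula(self):
        # points 0, 0.1 | 10, 10.1 -> TSS = 100.01, WSS = 0.01, F = 20000
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        d = np.abs(x - x.T)
        labels = pd.Series(["a", "a", "b", "b"], index=["0", "1", "2", "3"])
        f = pseudo_f(DistanceMatrix(d, ids=["0", "1", "2", "3"]), labels)
        assert np.isclose(f, 20000.0, rtol=1e-6)
        f_dist = pseudo_f(
            DistanceMatrix(d, ids=["0", "1", "2", "3"]), labels, on="distance"
        )
        assert np.isclose(f_dist, 20000.0, rtol=1e-6)

    def test_random_labels_on_structureless_cloud_give_f_near_one(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(40, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(40)])
        coords, _ = pcoa(dm)
        fs = []
        for _ in range(300):
            labels = pd.Series(
                rng.permutation(["a"] * 20 + ["b"] * 20), index=[str(i) for i in range(40)]
            )
            fs.append(pseudo_f(dm, labels, coords=coords))
        assert abs(np.mean(fs) - 1.0) < 0.15

    def test_identical_centroids_give_zero(self):
        # duplicated points split across clusters: WSS == TSS
        x = np.array([[0.0], [1.0], [0.0], [1.0]])
        d = np.abs(x - x.T)
        labels = pd.Series(["a", "a", "b", "b"], index=["0", "1", "2", "3"])
        f = pseudo_f(DistanceMatrix(d, ids=["0", "1", "2", "3"]), labels)
        assert np.isclose(f, 0.0, atol=1e-9)

    def test_degenerate_k_rejected(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=["0", "1", "2"])
        with pytest.raises(ValueError):
            pseudo_f(d, pd.Series(["a", "a", "a"], index=["0", "1", "2"]))
        with pytest.raises(ValueError):
            pseudo_f(d, pd.Series(["a", "b", "c"], index=["0", "1", "2"]))


def _cloud_dm(rng, centers, n_per, spread=0.5):
    pts = np.vstack([rng.normal(c, spread, size=(n_per, 2)) for c in centers])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[str(i) for i in range(len(pts))])


class TestChooseK:
    def test_three_planted_clouds_select_three(self):
        rng = np.random.default_rng(0)
        dm = _cloud_dm(rng, [(0, 0), (10, 0), (0, 10)], 10)
        k, trace = choose_k(dm, upgma_cluster(dm))
        assert k == 3 and trace[3] == max(trace.values())

    def test_two_planted_clouds_select_two(self):
        rng = np.random.default_rng(1)
        dm = _cloud_dm(rng, [(0, 0), (12, 0)], 12)
        k, _ = choose_k(dm, upgma_cluster(dm))
        assert k == 2

    def test_true_k_recovered_in_at_least_95_percent_of_replicates(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            dm = _cloud_dm(rng, [(0, 0), (8, 0), (0, 8)], 20, spread=1.0)
            k, _ = choose_k(dm, upgma_cluster(dm))
            hits += k == 3
        assert hits >= 95


class TestAlphaDiversity:
    def test_shannon_closed_forms(self):
        assert shannon([1.0]) == 0.0
        assert np.isclose(shannon(np.full(7, 1 / 7)), np.log(7))
        assert np.isclose(shannon([0.5, 0.25, 0.25]), 1.039721, atol=1e-6)

    def test_shannon_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            shannon([0.5, 0.2])

    def test_chao1_hand_cases(self):
        assert chao1([5, 4, 3]) == 3.0  # no singletons -> S_obs
        assert np.isclose(chao1([1, 1, 2, 2, 5]), 5 + 2 * 1 / (2 * 3))
        assert np.isclose(chao1([1, 1, 1]), 6.0)

    def test_chao1_rejects_proportions(self):
        with pytest.raises(ValueError):
            chao1([0.5, 0.3, 0.2])

    def test_chao1_at_least_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 10, size=20)
            if counts.sum() == 0:
                continue
            assert chao1(counts) >= (counts > 0).sum()

    def test_diversity_table_bounds(self):
        counts = pd.DataFrame(
            [[10, 1, 1, 0], [5, 5, 5, 5]], index=["S1", "S2"], columns=list("abcd")
        )
        tab = diversity_table(counts)
        assert (tab["shannon"] >= 0).all()
        assert (tab["chao1"] >= tab["observed_taxa"]).all()
        assert np.isclose(tab.loc["S2", "shannon"], np.log(4))


class TestPCoA:
    def test_points_on_a_line_are_reconstructed(self):
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None])
        coords, evals = pcoa(d)
        rec = np.abs(coords.iloc[:, 0].to_numpy()[:, None] - coords.iloc[:, 0].to_numpy()[None])
        np.testing.assert_allclose(rec, d, atol=1e-8)
        assert (evals[1:] < 1e-8).all()

    def test_euclidean_matrix_fully_reconstructed(self):
        rng = np.random.default_rng(21)
        pts = rng.random((10, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, _ = pcoa(d)
        rec = np.sqrt(
            ((coords.to_numpy()[:, None] - coords.to_numpy()[None]) ** 2).sum(-1)
        )
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_zero_matrix_gives_no_axes(self):
        coords, evals = pcoa(np.zeros((4, 4)))
        assert coords.shape[1] == 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0, 1], [2, 0]]))

    def test_matches_skbio_pcoa_coordinates(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(2)
        pts = rng.random((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords, _ = pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d, ids=[str(i) for i in range(8)]))
        got = np.abs(coords.to_numpy())
        want = np.abs(ref.samples.to_numpy()[:, : got.shape[1]])
        np.testing.assert_allclose(got, want, atol=1e-8)


class TestGroupDiversity:
    def test_identical_groups_not_significant(self):
        tab = pd.DataFrame({"shannon": [1.0, 1.0, 1.0, 1.0]}, index=list("abcd"))
        grouping = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        res = compare_group_diversity(tab, grouping)
        assert (res["p"] == 1.0).all()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(1.5, 0.2, size=25)  # ~50% higher diversity
        g2 = rng.normal(1.0, 0.2, size=55)
        tab = pd.DataFrame({"shannon": np.concatenate([g1, g2])})
        tab.index = [f"s{i}" for i in range(80)]
        grouping = pd.Series(["G1"] * 25 + ["G2"] * 55, index=tab.index)
        res = compare_group_diversity(tab, grouping)
        assert res["p"].iloc[0] < 0.05

    def test_missing_samples_and_empty_groups_rejected(self):
        tab = pd.DataFrame({"shannon": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compare_group_diversity(tab, pd.Series(["x", "x"], index=["a", "b"]))
        with pytest.raises(ValueError):
            compare_group_diversity(tab, pd.Series(["x", "y"], index=["a", "zz"]))


class TestCommunityTyper:
    def test_recovers_planted_types_from_compositions(self, default_refdb):
        from sklearn.metrics import adjusted_rand_score

        from semtype.syndata import DEFAULT_TYPE_SPECS, sample_composition

        rng = np.random.default_rng(6)
        rows, truth, ids = [], [], []
        for ct, n in [("G1", 12), ("G2", 25), ("G3", 8)]:
            for _ in range(n):
                rows.append(sample_composition(DEFAULT_TYPE_SPECS[ct], default_refdb, rng))
                truth.append(ct)
                ids.append(f"S{len(ids):03d}")
        profiles = pd.DataFrame(rows, index=ids, columns=default_refdb.species_ids)
        typer = CommunityTyper(tree=default_refdb.tree())
        labels = typer.fit_predict(profiles)
        assert typer.chosen_k_ == 3
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert typer.chosen_k_ == max(
            typer.pseudo_f_trace_, key=typer.pseudo_f_trace_.get
        )

    def test_sklearn_params_roundtrip(self):
        typer = CommunityTyper(k=3, normalized=False)
        params = typer.get_params()
        assert params["k"] == 3 and params["normalized"] is False
        typer2 = CommunityTyper(**params)
        assert typer2.k == 3
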