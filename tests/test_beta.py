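"""UniFrac against a brute-force branch-classification oracle; PCoA
against a geometric oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from airmic.beta import (
    OrdinationResult,
    distance_matrix,
    pcoa,
    unifrac_unweighted,
    unifrac_weighted,
)
from airmic.io import CountTable

from _oracles import (
    brute_unifrac_unweighted,
    brute_unifrac_weighted,
    random_tree,
)


def _random_instance(rng, n_tips=None):
    n_tips = n_tips or int(rng.integers(4, 17))
    tree = random_tree(n_tips, rng)
    taxa = [t.name for t in tree.tips()]
    # sparse random counts; guarantee both samples non-empty
    counts = rng.integers(0, 5, size=(2, n_tips))
    counts[rng.random(size=counts.shape) < 0.4] = 0
    for row in counts:
        if row.sum() == 0:
            row[int(rng.integers(n_tips))] = 1
    table = CountTable(pd.DataFrame(counts, index=["x", "y"], columns=taxa))
    return tree, table, taxa


class TestUniFracOracle:
    def test_identity_pairs_are_zero(self, four_tip_tree, four_tip_table):
        assert unifrac_unweighted(four_tip_table, four_tip_tree, ("ab", "ab")) == 0.0
        assert unifrac_weighted(four_tip_table, four_tip_tree, ("ab", "ab")) == 0.0

    def test_scaled_counts_identical_for_both_metrics(self, four_tip_tree, four_tip_table):
        # "ab" = (1,1,0,0), "ab2" = (2,2,0,0): same relative abundances
        assert unifrac_unweighted(four_tip_table, four_tip_tree, ("ab", "ab2")) == 0.0
        assert unifrac_weighted(four_tip_table, four_tip_tree, ("ab", "ab2")) == 0.0

    def test_disjoint_clades_give_unweighted_one(self, four_tip_tree, four_tip_table):
        assert unifrac_unweighted(four_tip_table, four_tip_tree, ("ab", "cd")) == 1.0

    def test_weighted_hand_enumeration(self, four_tip_tree, four_tip_table):
        """All mass on tip A vs all on tip C: raw W is the 4-branch path
        A->root->C; the normalised value is exactly 1."""
        raw = unifrac_weighted(
            four_tip_table, four_tip_tree, ("a_only", "c_only"), normalized=False
        )
        assert raw == pytest.approx(4.0)
        norm = unifrac_weighted(four_tip_table, four_tip_tree, ("a_only", "c_only"))
        assert norm == pytest.approx(1.0)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            tree, table, taxa = _random_instance(rng)
            a = dict(zip(taxa, table.counts.loc["x"]))
            b = dict(zip(taxa, table.counts.loc["y"]))
            u = unifrac_unweighted(table, tree, ("x", "y"))
            assert u == pytest.approx(brute_unifrac_unweighted(tree, a, b), abs=1e-12)
            for normalized in (False, True):
                w = unifrac_weighted(table, tree, ("x", "y"), normalized=normalized)
                assert w == pytest.approx(
                    brute_unifrac_weighted(tree, a, b, normalized), abs=1e-12
                )
            assert 0.0 <= u <= 1.0

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(7)
        tree, table, taxa = _random_instance(rng, n_tips=10)
        u1 = unifrac_unweighted(table, tree, ("x", "y"))
        u2 = unifrac_unweighted(table, tree, ("y", "x"))
        assert u1 == pytest.approx(u2, abs=1e-14)
        # rotate children everywhere: distances unchanged
        rotated = tree.copy()
        for node in rotated.non_tips(include_self=True):
            node.children.reverse()
        u3 = unifrac_unweighted(table, rotated, ("x", "y"))
        w1 = unifrac_weighted(table, tree, ("x", "y"))
        w3 = unifrac_weighted(table, rotated, ("x", "y"))
        assert u3 == pytest.approx(u1, abs=1e-12)
        assert w3 == pytest.approx(w1, abs=1e-12)

    def test_matrix_agrees_with_per_pair(self):
        rng = np.random.default_rng(11)
        tree = random_tree(12, rng)
        taxa = [t.name for t in tree.tips()]
        counts = rng.integers(0, 6, size=(6, 12))
        counts[:, 0] += 1  # non-empty
        table = CountTable(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(6)], columns=taxa)
        )
        for metric, normalized in (("unweighted", True), ("weighted", True), ("weighted", False)):
            dm = distance_matrix(table, tree, metric=metric, normalized=normalized)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0.0)
            for i in table.sample_ids:
                for j in table.sample_ids:
                    if i == j:
                        continue
                    if metric == "unweighted":
                        ref = unifrac_unweighted(table, tree, (i, j))
                    else:
                        ref = unifrac_weighted(table, tree, (i, j), normalized=normalized)
                    assert dm[i, j] == pytest.approx(ref, abs=1e-12)

    def test_merging_identical_profile_tips_preserves_distances(self):
        """Collapsing a cherry whose two tips have identical per-sample
        counts into a single tip leaves each metric unchanged, with the
        merged branch length that conserves that metric's branch mass:
        the presence-based metric sees both parallel tip branches
        (stem + l_A + l_B), the abundance-based metric sees the
        abundance-weighted mean (stem + (l_A + l_B)/2)."""
        from io import StringIO
        from skbio import TreeNode

        tree = TreeNode.read(StringIO("(((A:1,B:1):2,C:3):1,D:4);"))
        merged_presence = TreeNode.read(StringIO("((M:4,C:3):1,D:4);"))
        merged_abund = TreeNode.read(StringIO("((M:3,C:3):1,D:4);"))
        # A and B identical occupancy and abundance in every sample
        counts = pd.DataFrame(
            [[2, 2, 1, 0], [1, 1, 0, 3], [0, 0, 2, 2]],
            index=["s1", "s2", "s3"],
            columns=list("ABCD"),
        )
        counts_m = pd.DataFrame(
            {"M": counts["A"] + counts["B"], "C": counts["C"], "D": counts["D"]}
        )
        t1 = CountTable(counts)
        t2 = CountTable(counts_m)
        for pair in (("s1", "s2"), ("s1", "s3"), ("s2", "s3")):
            assert unifrac_unweighted(t1, tree, pair) == pytest.approx(
                unifrac_unweighted(t2, merged_presence, pair), abs=1e-12
            )
            assert unifrac_weighted(t1, tree, pair, normalized=False) == pytest.approx(
                unifrac_weighted(t2, merged_abund, pair, normalized=False), abs=1e-12
            )

    def test_taxa_missing_from_tree_error(self, four_tip_tree):
        table = CountTable(
            pd.DataFrame([[1, 1]], index=["s"], columns=["A", "ZZZ"])
        )
        with pytest.raises(KeyError):
            distance_matrix(
                CountTable(pd.DataFrame([[1, 1], [1, 0]], index=["s", "t"], columns=["A", "ZZZ"])),
                four_tip_tree,
            )

    def test_between_site_exceeds_within_site(self, small_bundle):
        """Site-dominant composition shows up as larger between-site
        than within-site UniFrac distances."""
        _, bundle = small_bundle
        table = bundle.table.drop_empty_samples()
        md = bundle.metadata.loc[table.sample_ids]
        ids = md.index[(md["time"] == 0) & (md["side"] == "left")]
        sub = table.select_samples(ids)
        dm = distance_matrix(sub, bundle.tree, metric="unweighted")
        sites = md.loc[ids, "site"].to_numpy()
        d = dm.data
        same = sites[:, None] == sites[None, :]
        iu = np.triu_indices_from(d, k=1)
        within = d[iu][same[iu]]
        between = d[iu][~same[iu]]
        assert between.mean() > within.mean()


class TestPCoA:
    def test_planar_points_reconstructed(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abc"))
        res = pcoa(dm)
        rec = squareform(pdist(res.coordinates))
        assert np.abs(rec - dm.data).max() < 1e-10
        assert (res.eigenvalues > 1e-10).sum() == 2

    def test_random_point_clouds_reconstructed(self):
        rng = np.random.default_rng(12)
        for dim in (2, 3):
            pts = rng.normal(size=(15, dim))
            dm = DistanceMatrix(
                squareform(pdist(pts)), ids=[str(i) for i in range(15)]
            )
            res = pcoa(dm)
            rec = squareform(pdist(res.coordinates))
            assert np.abs(rec - dm.data).max() < 1e-8
            assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_zero_matrix(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0
        assert np.allclose(res.eigenvalues, 0.0)

    def test_non_euclidean_negative_eigenvalues_excluded(self):
        # violates the triangle-embedding: d(a,b)=d(a,c)=d(b,c)=1 except one huge
        d = np.array(
            [
                [0, 1, 1, 1],
                [1, 0, 1, 1],
                [1, 1, 0, 3.5],
                [1, 1, 3.5, 0],
            ]
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = pcoa(dm)
        assert res.eigenvalues.min() < -1e-8  # reported
        assert res.coordinates.shape[1] == (res.eigenvalues > 1e-10 * np.abs(res.eigenvalues).max()).sum()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_axis_order_and_sign_deterministic(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        a = pcoa(dm)
        b = pcoa(dm)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert (np.diff(a.eigenvalues) <= 1e-12).all()
        for k in range(a.coordinates.shape[1]):
            col = a.coordinates[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])

        class Fake:
            data = d
            ids = list("abc")

        with pytest.raises(ValueError, match="symmetric"):
            pcoa(Fake())

    def test_agrees_with_scikit_bio_eigenvalues(self):
        """Cross-check: eigenvalues (not axes signs) match skbio's PCoA."""
        import skbio.stats.ordination as sko

        rng = np.random.default_rng(14)
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        ours = pcoa(dm)
        theirs = sko.pcoa(dm)
        assert np.allclose(
            ours.eigenvalues[:4], np.sort(theirs.eigvals.to_numpy())[::-1][:4], atol=1e-8
        )
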