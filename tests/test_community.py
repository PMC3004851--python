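"""Permutation tests, PERMANOVA, clustering bootstrap, temporal test."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from airmic.community import (
    cluster_with_bootstrap,
    permanova,
    temporal_stability_test,
    within_group_test,
    within_vs_between_test,
)
from airmic.io import CountTable

from _oracles import classical_anova_f


def _euclid_dm(x, ids=None):
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(squareform(pdist(np.atleast_2d(x).T if np.ndim(x) == 1 else x)), ids=ids)


def _two_clusters(rng, n=8, sep=10.0):
    a = rng.normal(0, 1, size=(n, 3))
    b = rng.normal(sep, 1, size=(n, 3))
    return np.vstack([a, b]), np.array(["g1"] * n + ["g2"] * n)


class TestWithinGroupTest:
    def test_all_distances_equal_gives_zero_and_p_one(self):
        d = np.ones((8, 8)) - np.eye(8)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        res = within_group_test(dm, ["a"] * 4 + ["b"] * 4, n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.direction is None

    def test_label_relabeling_equivariance(self):
        rng = np.random.default_rng(0)
        x, labels = _two_clusters(rng)
        dm = _euclid_dm(x)
        res1 = within_group_test(dm, labels, n_perm=500, seed=3)
        # permute samples and labels consistently
        perm = rng.permutation(len(labels))
        dperm = dm.data[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(dperm, ids=[f"s{i}" for i in range(len(labels))])
        res2 = within_group_test(dm2, labels[perm], n_perm=500, seed=3)
        assert res2.p_value == pytest.approx(res1.p_value, abs=0.05)

    def test_statistic_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 2))
        x[6:] *= 3.0  # second group more dispersed
        dm = _euclid_dm(x)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        swapped = np.where(labels == "a", "zb", "aa")  # reverses sort order
        r1 = within_group_test(dm, labels, n_perm=300, seed=5)
        r2 = within_group_test(dm, swapped, n_perm=300, seed=5)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.p_value == r2.p_value
        assert "more dispersed" in r1.direction

    def test_small_group_rejected(self):
        dm = _euclid_dm(np.arange(5.0))
        with pytest.raises(ValueError, match="fewer than 3"):
            within_group_test(dm, ["a", "a", "b", "b", "b"], n_perm=100)

    def test_p_floor_respected(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(0, 5.0, 10)])
        dm = _euclid_dm(x)
        res = within_group_test(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=1)
        assert res.p_value >= 1 / 200


class TestWithinVsBetween:
    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(3)
        x, labels = _two_clusters(rng, n=10, sep=50.0)
        dm = _euclid_dm(x)
        res = within_vs_between_test(dm, labels, n_perm=499, seed=2)
        assert res.p_value == pytest.approx(1 / 500)
        assert res.direction == "between greater"

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x, labels = _two_clusters(rng, n=6, sep=2.0)
        d = squareform(pdist(x))
        r1 = within_vs_between_test(
            DistanceMatrix(d, ids=[str(i) for i in range(12)]), labels, n_perm=300, seed=9
        )
        r2 = within_vs_between_test(
            DistanceMatrix(2 * d, ids=[str(i) for i in range(12)]), labels, n_perm=300, seed=9
        )
        assert r1.p_value == r2.p_value

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for i in range(100):
            x = rng.normal(size=(16, 2))
            dm = _euclid_dm(x)
            res = within_vs_between_test(
                dm, ["a"] * 8 + ["b"] * 8, n_perm=99, seed=1000 + i
            )
            ps.append(res.p_value)
        assert abs(np.mean(ps) - 0.5) < 0.1


class TestPermanova:
    def test_equals_classical_anova_on_1d(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            values = rng.normal(size=18)
            labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
            dm = _euclid_dm(values)
            res = permanova(dm, labels, n_perm=10, seed=0)
            assert res.statistic == pytest.approx(
                classical_anova_f(values, labels), abs=1e-10
            )

    def test_matches_scikit_bio_pseudo_f(self):
        import skbio.stats.distance as skd

        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 4))
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(15)])
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        ours = permanova(dm, labels, n_perm=10, seed=0)
        theirs = skd.permanova(dm, grouping=list(labels), permutations=10)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_duplicated_points_give_p_near_one(self):
        x = np.tile(np.arange(6.0), 2)
        labels = ["a"] * 6 + ["b"] * 6
        dm = _euclid_dm(x[np.argsort(np.tile(np.arange(6), 2), kind="stable")])
        # identical groups: duplicate each point once per group
        pts = np.concatenate([np.arange(6.0), np.arange(6.0)])
        dm = _euclid_dm(pts)
        res = permanova(dm, labels, n_perm=300, seed=4)
        assert res.statistic < 1e-10 or res.p_value > 0.5

    def test_ss_decomposition(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(12, 3))
        d2 = squareform(pdist(x)) ** 2
        n = 12
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        ss_total = d2.sum() / 2 / n
        ss_within = 0.0
        for g in np.unique(labels):
            mask = labels == g
            ss_within += d2[np.ix_(mask, mask)].sum() / 2 / mask.sum()
        ss_between = ss_total - ss_within
        f_manual = (ss_between / 2) / (ss_within / 9)
        dm = DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(12)])
        res = permanova(dm, labels, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(f_manual, abs=1e-10)

    def test_singleton_group_rejected(self):
        dm = _euclid_dm(np.arange(5.0))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a", "a", "a", "a", "b"], n_perm=100)


class TestSubjectAwarePermutation:
    def test_subject_permutation_keeps_subject_samples_together(self):
        """With two samples per subject, permuting subjects must leave
        each subject's two samples with a common label."""
        from airmic.community import _permuted_codes

        rng = np.random.default_rng(9)
        subjects = np.repeat([f"p{i}" for i in range(8)], 2)
        codes = np.repeat([0, 0, 0, 0, 1, 1, 1, 1], 2)
        perms = _permuted_codes(codes, 50, rng, subjects)
        for row in perms:
            for s in range(8):
                assert row[2 * s] == row[2 * s + 1]
            assert row.sum() == 8


class TestTemporalStability:
    def _dm_md(self, fidelity, rng, n_subjects=8, n_rep=4, center_scale=5.0):
        centers = rng.normal(0, center_scale, size=(n_subjects, 3))
        rows, subj = [], []
        for i in range(n_subjects):
            reps = n_rep if i < 4 else 1
            for t in range(reps):
                rows.append(centers[i] + rng.normal(0, fidelity, 3))
                subj.append(f"p{i}")
        x = np.vstack(rows)
        ids = [f"s{k}" for k in range(len(rows))]
        md = pd.DataFrame(
            {
                "subject": subj,
                "site": "oropharynx",
                "side": "left",
                "group": "smoker",
                "time": 0,
            },
            index=ids,
        )
        return DistanceMatrix(squareform(pdist(x)), ids=ids), md

    def test_high_fidelity_detected(self):
        rng = np.random.default_rng(10)
        dm, md = self._dm_md(0.1, rng)
        res = temporal_stability_test(dm, md, n_perm=500, seed=0)
        assert res.p_value < 0.05
        assert res.direction == "within-subject more similar"

    def test_no_repeats_rejected(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        md = pd.DataFrame(
            {
                "subject": [f"p{i}" for i in range(6)],
                "site": "oropharynx",
                "side": "left",
                "group": "smoker",
                "time": 0,
            },
            index=ids,
        )
        dm = DistanceMatrix(squareform(pdist(x)), ids=ids)
        with pytest.raises(ValueError, match="2 subjects"):
            temporal_stability_test(dm, md, n_perm=100)

    def test_shuffled_subjects_null(self):
        rng = np.random.default_rng(12)
        ps = []
        for i in range(40):
            # no subject structure at all: iid points
            dm, md = self._dm_md(1.0, rng, center_scale=0.0)
            res = temporal_stability_test(dm, md, n_perm=99, seed=i)
            ps.append(res.p_value)
        assert abs(np.mean(ps) - 0.5) < 0.15


def _cluster_inputs(rng, centers, n_subjects=6, noise=0.02):
    """Three strata with given genus-profile centers."""
    strata = [
        ("nasopharynx", "left", "smoker"),
        ("nasopharynx", "left", "nonsmoker"),
        ("oropharynx", "left", "smoker"),
    ]
    rows, meta = [], []
    for (site, side, group), center in zip(strata, centers):
        for j in range(n_subjects):
            profile = np.abs(center + rng.normal(0, noise, len(center)))
            counts = np.round(1000 * profile / profile.sum()).astype(int)
            sid = f"{group[:2]}{site[:2]}{j}"
            rows.append(counts)
            meta.append(
                {
                    "sample_id": f"x{len(rows)}",
                    "subject": sid,
                    "site": site,
                    "side": side,
                    "group": group,
                    "time": 0,
                }
            )
    md = pd.DataFrame(meta).set_index("sample_id")
    counts = pd.DataFrame(
        rows, index=md.index, columns=[f"g{k}" for k in range(len(centers[0]))]
    )
    return CountTable(counts), md


class TestClusterBootstrap:
    def test_separating_split_gets_full_support(self):
        rng = np.random.default_rng(13)
        base = np.array([0.4, 0.3, 0.2, 0.1])
        centers = [base, base + 0.01, np.array([0.05, 0.1, 0.25, 0.6])]
        table, md = _cluster_inputs(rng, centers)
        res = cluster_with_bootstrap(table, md, n_boot=200, seed=0, filter_fraction=0.002)
        # first merge joins the two near-identical strata, isolating the third
        assert res.support[0] >= 99.0

    def test_filter_bounds(self):
        rng = np.random.default_rng(14)
        base = np.array([0.4, 0.3, 0.2, 0.1])
        centers = [base, base + 0.01, base + 0.02]
        table, md = _cluster_inputs(rng, centers)
        res_all = cluster_with_bootstrap(table, md, n_boot=10, seed=0, filter_fraction=1e-9)
        assert len(res_all.kept_genera) == 4
        with pytest.raises(ValueError, match="filter"):
            cluster_with_bootstrap(table, md, n_boot=10, seed=0, filter_fraction=0.999999)

    def test_support_invariant_to_sample_order(self):
        rng = np.random.default_rng(15)
        base = np.array([0.4, 0.3, 0.2, 0.1])
        centers = [base, base + 0.05, np.array([0.05, 0.1, 0.25, 0.6])]
        table, md = _cluster_inputs(rng, centers)
        res1 = cluster_with_bootstrap(table, md, n_boot=100, seed=1)
        order = list(table.counts.index)[::-1]
        table2 = table.select_samples(order)
        res2 = cluster_with_bootstrap(table2, md.loc[order], n_boot=100, seed=1)
        assert res1.support == pytest.approx(res2.support)
        assert res1.leaf_names == res2.leaf_names

    def test_newick_export_contains_supports(self):
        rng = np.random.default_rng(16)
        base = np.array([0.4, 0.3, 0.2, 0.1])
        centers = [base, base + 0.01, np.array([0.05, 0.1, 0.25, 0.6])]
        table, md = _cluster_inputs(rng, centers)
        res = cluster_with_bootstrap(table, md, n_boot=50, seed=2)
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for leaf in res.leaf_names:
            assert leaf in nwk
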