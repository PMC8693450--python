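import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from dysbindex.beta_diversity import (
    distance_matrix,
    distances_to_group,
    pcoa,
    permanova,
    unweighted_unifrac,
    weighted_unifrac,
)
from dysbindex.io_formats import CohortMetadata, FeatureTable
from dysbindex.synthetic_data import generate_tree


# --- independent brute-force oracle: per-leaf root-path accumulation -------

def _leaf_paths(tree):
    paths = {}
    for leaf in tree.tips():
        node, path = leaf, []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[leaf.name] = path
    return paths


def brute_unweighted(a, b, tree):
    paths = _leaf_paths(tree)
    set_a = set().union(*(paths[t] for t, v in a.items() if v > 0))
    set_b = set().union(*(paths[t] for t, v in b.items() if v > 0))
    union = sum(n.length for n in set_a | set_b)
    unique = sum(n.length for n in set_a ^ set_b)
    return unique / union if union else 0.0


def brute_weighted(a, b, tree, normalized=True):
    paths = _leaf_paths(tree)
    ta, tb = sum(a.values()), sum(b.values())
    mass_a, mass_b = {}, {}
    for taxon, path in paths.items():
        for node in path:
            mass_a[node] = mass_a.get(node, 0.0) + a.get(taxon, 0.0) / ta
            mass_b[node] = mass_b.get(node, 0.0) + b.get(taxon, 0.0) / tb
    nodes = set(mass_a) | set(mass_b)
    raw = sum(n.length * abs(mass_a.get(n, 0) - mass_b.get(n, 0)) for n in nodes)
    if not normalized:
        return raw
    denom = sum(n.length * (mass_a.get(n, 0) + mass_b.get(n, 0)) for n in nodes)
    return raw / denom if denom else 0.0


def _random_abundances(rng, taxa, zero_frac=0.4):
    vals = {t: float(rng.gamma(1.0)) for t in taxa}
    for t in taxa:
        if rng.uniform() < zero_frac:
            vals[t] = 0.0
    if all(v == 0 for v in vals.values()):
        vals[taxa[0]] = 1.0
    return vals


class TestUnifracWorkedExamples:
    def test_identical_presence_sets_give_zero(self, four_leaf_tree):
        a = {"A": 0.6, "B": 0.4}
        b = {"A": 0.1, "B": 0.9}
        assert unweighted_unifrac(a, b, four_leaf_tree) == 0.0

    def test_disjoint_cherries(self, four_leaf_tree):
        assert unweighted_unifrac({"A": 1}, {"C": 1}, four_leaf_tree) == 1.0

    def test_partial_overlap_three_fifths(self, four_leaf_tree):
        d = unweighted_unifrac({"A": 1, "B": 1}, {"A": 1, "C": 1}, four_leaf_tree)
        assert d == pytest.approx(0.6)

    def test_weighted_zero_for_identical(self, four_leaf_tree):
        a = {"A": 0.5, "C": 0.5}
        assert weighted_unifrac(a, dict(a), four_leaf_tree) == 0.0

    def test_weighted_star_tree_saturates_at_one(self):
        star = TreeNode.read(io.StringIO("(X:1,Y:1);"))
        star.length = 0.0
        d = weighted_unifrac({"X": 1.0}, {"Y": 1.0}, star, normalized=True)
        assert d == pytest.approx(1.0)

    def test_missing_taxon_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="missing from tree"):
            unweighted_unifrac({"Z": 1.0}, {"A": 1.0}, four_leaf_tree)

    def test_empty_sample_rejected(self, four_leaf_tree):
        with pytest.raises(ValueError, match="empty"):
            unweighted_unifrac({}, {"A": 1.0}, four_leaf_tree)


class TestUnifracAgainstOracles:
    def test_matches_brute_force_on_random_trees(self, rng):
        for i in range(40):
            n = int(rng.integers(3, 17))
            taxa = [f"t{j}" for j in range(n)]
            tree = generate_tree(taxa, seed=1000 + i)
            a = _random_abundances(rng, taxa)
            b = _random_abundances(rng, taxa)
            du = unweighted_unifrac(a, b, tree)
            dw = weighted_unifrac(a, b, tree)
            assert du == pytest.approx(brute_unweighted(a, b, tree), abs=1e-12)
            assert dw == pytest.approx(brute_weighted(a, b, tree), abs=1e-12)

    def test_matches_scikit_bio(self, rng):
        """Independent library cross-check on random binary trees."""
        from skbio.diversity import beta_diversity

        for i in range(10):
            n = int(rng.integers(4, 12))
            taxa = [f"t{j}" for j in range(n)]
            tree = generate_tree(taxa, seed=2000 + i)
            rows = np.array(
                [list(_random_abundances(rng, taxa).values()) for _ in range(3)]
            )
            # scikit-bio casts counts to integers, so feed both sides counts
            rows = np.round(rows * 1000).astype(int)
            rows[rows.sum(axis=1) == 0, 0] = 1
            ids = ["s1", "s2", "s3"]
            sk_u = beta_diversity("unweighted_unifrac", (rows > 0).astype(int),
                                  ids=ids, tree=tree, taxa=taxa)
            sk_w = beta_diversity("weighted_unifrac", rows,
                                  ids=ids, tree=tree, taxa=taxa, normalized=True)
            table = FeatureTable(
                pd.DataFrame(rows / rows.sum(axis=1, keepdims=True),
                             index=ids, columns=taxa),
                unit="proportions",
            )
            du = distance_matrix(table, tree, "unweighted_unifrac")
            dw = distance_matrix(table, tree, "weighted_unifrac")
            assert np.allclose(np.asarray(du.data), np.asarray(sk_u.data), atol=1e-10)
            assert np.allclose(np.asarray(dw.data), np.asarray(sk_w.data), atol=1e-10)

    def test_range_symmetry_triangle(self, rng):
        taxa = [f"t{j}" for j in range(10)]
        tree = generate_tree(taxa, seed=7)
        samples = [_random_abundances(rng, taxa) for _ in range(6)]
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                d[i, j] = unweighted_unifrac(samples[i], samples[j], tree)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_zero_iff_equal_presence(self, rng):
        taxa = [f"t{j}" for j in range(8)]
        tree = generate_tree(taxa, seed=11)
        a = _random_abundances(rng, taxa)
        b = {t: (2.0 * v if v > 0 else 0.0) for t, v in a.items()}
        assert unweighted_unifrac(a, b, tree) == 0.0
        c = dict(a)
        absent = [t for t, v in c.items() if v == 0]
        present = [t for t, v in c.items() if v > 0]
        if absent and len(present) > 1:
            c[absent[0]] = 1.0
            assert unweighted_unifrac(a, c, tree) > 0.0


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self, four_leaf_tree):
        t = FeatureTable(
            pd.DataFrame([[0.5, 0.5, 0, 0]] * 2, index=["S1", "S2"],
                         columns=["A", "B", "C", "D"]),
            unit="proportions",
        )
        dm = distance_matrix(t, four_leaf_tree, "unweighted_unifrac")
        assert np.allclose(np.asarray(dm.data), 0.0)

    def test_driver_matches_kernels_entrywise(self, rng, four_leaf_tree):
        rows = rng.dirichlet(np.ones(4), size=5)
        rows[rows < 0.2] = 0.0
        rows = rows / rows.sum(axis=1, keepdims=True)
        ids = [f"S{i}" for i in range(5)]
        taxa = ["A", "B", "C", "D"]
        t = FeatureTable(pd.DataFrame(rows, index=ids, columns=taxa),
                         unit="proportions")
        for metric, kernel in (
            ("unweighted_unifrac", unweighted_unifrac),
            ("weighted_unifrac", weighted_unifrac),
        ):
            dm = distance_matrix(t, four_leaf_tree, metric)
            for i in range(5):
                for j in range(5):
                    expected = kernel(
                        dict(zip(taxa, rows[i])), dict(zip(taxa, rows[j])),
                        four_leaf_tree,
                    )
                    assert dm[ids[i], ids[j]] == pytest.approx(expected, abs=1e-12)


class TestPcoa:
    def test_two_points(self):
        dm = DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), ids=["a", "b"])
        ord_ = pcoa(dm)
        assert ord_.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
        coords = sorted(ord_.coordinates["PC1"].tolist())
        assert coords == pytest.approx([-1.0, 1.0])

    def test_equilateral_triangle_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        ord_ = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert ord_.eigenvalues == pytest.approx([0.5, 0.5, 0.0], abs=1e-12)

    def test_euclidean_reconstruction_and_trace(self, rng):
        from scipy.spatial.distance import pdist, squareform

        for _ in range(10):
            pts = rng.normal(size=(8, 3))
            d = squareform(pdist(pts))
            ord_ = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(8)]))
            coords = ord_.coordinates.to_numpy()
            back = squareform(pdist(coords))
            assert np.allclose(back, d, atol=1e-8)
            # trace of the centred matrix equals the eigenvalue sum
            a = -0.5 * d**2
            j = np.eye(8) - np.ones((8, 8)) / 8
            b = j @ a @ j
            assert np.trace(b) == pytest.approx(ord_.eigenvalues.sum(), abs=1e-8)

    def test_matches_scikit_bio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as sk_pcoa

        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        ours = pcoa(dm)
        theirs = sk_pcoa(dm, number_of_dimensions=6)
        assert np.allclose(
            ours.eigenvalues[:2], np.asarray(theirs.eigvals)[:2], atol=1e-8
        )

    def test_proportion_explained_sums_to_at_most_one(self, rng):
        d = np.abs(rng.normal(size=(5, 5)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ord_ = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(5)]))
        assert ord_.proportion_explained.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(ord_.eigenvalues) <= 1e-12)


class TestDistancesToGroup:
    def _setup(self):
        d = np.array([
            [0.0, 0.1, 0.2, 0.4],
            [0.1, 0.0, 0.3, 0.5],
            [0.2, 0.3, 0.0, 0.6],
            [0.4, 0.5, 0.6, 0.0],
        ])
        ids = ["c1", "c2", "p1", "p2"]
        dm = DistanceMatrix(d, ids=ids)
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["control", "control", "AIS", "AIS"]}, index=ids
        ))
        return dm, meta

    def test_mean_over_reference(self):
        dm, meta = self._setup()
        d2c = distances_to_group(dm, meta, "control")
        assert d2c["p1"] == pytest.approx((0.2 + 0.3) / 2)
        assert d2c["p2"] == pytest.approx((0.4 + 0.5) / 2)

    def test_reference_samples_use_other_references(self):
        dm, meta = self._setup()
        d2c = distances_to_group(dm, meta, "control")
        assert d2c["c1"] == pytest.approx(0.1)

    def test_sample_identical_to_all_controls(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = 0.0
        ids = ["c1", "c2", "p"]
        dm = DistanceMatrix(d, ids=ids)
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["control", "control", "T2D"]}, index=ids
        ))
        assert distances_to_group(dm, meta, "control")["p"] == 0.0


class TestPermanova:
    def _clustered(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        ids = ["a1", "a2", "b1", "b2"]
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["T2D", "T2D", "control", "control"]}, index=ids
        ))
        return DistanceMatrix(d, ids=ids), meta

    def test_exhaustive_two_plus_two(self):
        # 3 distinct partitions; only the observed one reaches the observed F
        dm, meta = self._clustered()
        _, p = permanova(dm, meta, n_permutations="exact")
        assert p == pytest.approx(1 / 3)

    def test_sample_relabelling_leaves_f_unchanged(self, rng):
        dm, meta = self._clustered()
        f1, _ = permanova(dm, meta, n_permutations=9, seed=0)
        order = ["b2", "a1", "b1", "a2"]
        d = pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids))
        dm2 = DistanceMatrix(d.loc[order, order].to_numpy(), ids=order)
        f2, _ = permanova(dm2, meta, n_permutations=9, seed=0)
        assert f1 == pytest.approx(f2)

    def test_reproducible_given_seed(self, rng):
        n = 20
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["T2D"] * 10 + ["control"] * 10}, index=ids
        ))
        r1 = permanova(dm, meta, n_permutations=99, seed=5)
        r2 = permanova(dm, meta, n_permutations=99, seed=5)
        assert r1 == r2

    def test_statistic_matches_scikit_bio(self, rng):
        from skbio.stats.distance import permanova as sk_permanova
        from scipy.spatial.distance import pdist, squareform

        n = 15
        pts = rng.normal(size=(n, 3))
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        labels = ["T2D"] * 5 + ["control"] * 5 + ["AIS"] * 5
        meta = CohortMetadata(pd.DataFrame({"group": labels}, index=ids))
        f_ours, _ = permanova(dm, meta, n_permutations=9, seed=0)
        res = sk_permanova(dm, grouping=labels, permutations=9)
        assert f_ours == pytest.approx(res["test statistic"], rel=1e-10)

    def test_singleton_group_rejected(self):
        dm, _ = self._clustered()
        meta = CohortMetadata(pd.DataFrame(
            {"group": ["T2D", "T2D", "T2D", "control"]},
            index=["a1", "a2", "b1", "b2"],
        ))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, meta)
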