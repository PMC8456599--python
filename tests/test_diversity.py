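import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oilcomm.core_io import DistanceMatrix, ValidationError
from oilcomm.diversity import (
    bray_curtis,
    lcbd,
    pcoa,
    permanova,
    richness,
    shannon,
    unweighted_unifrac,
    weighted_unifrac,
)

from conftest import make_metadata, make_table, random_proportions_table
from oracles import (
    gower_diag_bf,
    permanova_exhaustive_p,
    permanova_oneway_bf,
    unweighted_unifrac_bf,
    weighted_unifrac_bf,
)


class TestAlpha:
    @pytest.mark.parametrize(
        "col, expected",
        [([3, 0, 1], 2), ([0, 0, 0], 0), ([0.5, 0.5, 0], 2)],
    )
    def test_richness(self, col, expected):
        assert richness(np.array(col)) == expected

    @pytest.mark.parametrize(
        "col, expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5, 0, 0], 0.0),
            # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
            ([2, 1, 1], 1.0397207708399179),
        ],
    )
    def test_shannon(self, col, expected):
        assert shannon(np.array(col)) == pytest.approx(expected, abs=1e-10)

    def test_shannon_all_zero_is_error(self):
        with pytest.raises(ValidationError):
            shannon(np.zeros(3))


class TestBrayCurtis:
    def test_examples(self):
        t = make_table(
            [[0.75, 0.25, 0.0], [0.25, 0.75, 0.0], [0.0, 0.0, 1.0]],
            mode="proportions",
        )
        D = bray_curtis(t)
        assert D["s0", "s1"] == pytest.approx(0.5)
        assert D["s0", "s2"] == pytest.approx(1.0)  # disjoint supports
        assert D["s0", "s0"] == 0.0

    def test_identical_columns_zero(self):
        t = make_table([[0.4, 0.4], [0.6, 0.6]], mode="proportions")
        assert bray_curtis(t)["s0", "s1"] == 0.0

    def test_counts_mode_rejected_with_instruction(self):
        t = make_table([[1, 2], [3, 4]])
        with pytest.raises(ValidationError, match="to_relative_abundance"):
            bray_curtis(t)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_range_and_symmetry_property(self, seed):
        rng = np.random.default_rng(seed)
        t = random_proportions_table(rng, 6, 5)
        D = np.asarray(bray_curtis(t).data)
        assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()
        np.testing.assert_allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)


class TestUniFrac:
    def test_identical_columns_zero(self, two_leaf_tree):
        t = make_table([[0.5, 0.5], [0.5, 0.5]], taxa=["A", "B"],
                       mode="proportions")
        assert unweighted_unifrac(t, two_leaf_tree)["s0", "s1"] == 0.0
        assert weighted_unifrac(t, two_leaf_tree)["s0", "s1"] == 0.0

    def test_disjoint_two_leaf_tree_is_one(self, two_leaf_tree):
        t = make_table([[1.0, 0.0], [0.0, 1.0]], taxa=["A", "B"],
                       mode="proportions")
        assert unweighted_unifrac(t, two_leaf_tree)["s0", "s1"] == pytest.approx(1.0)
        assert weighted_unifrac(t, two_leaf_tree, normalized=True)[
            "s0", "s1"
        ] == pytest.approx(1.0)

    def test_missing_leaf_reported(self, two_leaf_tree):
        t = make_table([[1.0], [0.0]], taxa=["A", "Z"], mode="proportions")
        t.data.loc["Z"] = 0.0
        t2 = make_table([[0.5], [0.5]], taxa=["A", "Z"], mode="proportions")
        with pytest.raises(ValidationError, match="Z"):
            unweighted_unifrac(t2, two_leaf_tree)

    @pytest.mark.parametrize("n_random", [20])
    def test_matches_per_branch_oracle(self, n_random):
        from oilcomm.synthetic import simulate_tree

        rng = np.random.default_rng(42)
        for k in range(n_random):
            tree = simulate_tree(8, seed=k)
            taxa = [t.name for t in tree.tips()]
            t = random_proportions_table(rng, 8, 3, taxa=taxa)
            Du = unweighted_unifrac(t, tree)
            Dw = weighted_unifrac(t, tree, normalized=True)
            X = t.values
            for i, j in ((0, 1), (0, 2), (1, 2)):
                assert Du.data[i, j] == pytest.approx(
                    unweighted_unifrac_bf(X[:, i], X[:, j], taxa, tree),
                    abs=1e-10,
                )
                assert Dw.data[i, j] == pytest.approx(
                    weighted_unifrac_bf(X[:, i], X[:, j], taxa, tree),
                    abs=1e-10,
                )


class TestPCoA:
    def test_collinear_points_recovered_on_first_axis(self):
        # samples at 0, 1, 2 on a line (Euclidean distances)
        D = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                           ids=["a", "b", "c"])
        res = pcoa(D, k=2)
        x = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(x))
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-9)
        assert abs(res.eigenvalues[1]) < 1e-9
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_all_equal_samples_coordinates_zero(self):
        D = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(D, k=2)
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        X = rng.random((5, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        ids = list("abcde")
        perm = [3, 1, 4, 0, 2]
        res1 = pcoa(DistanceMatrix(D, ids=ids), k=2)
        res2 = pcoa(
            DistanceMatrix(D[np.ix_(perm, perm)], ids=[ids[i] for i in perm]),
            k=2,
        )
        a = res1.coordinates.loc[list("abcde")].to_numpy()
        b = res2.coordinates.loc[list("abcde")].to_numpy()
        # axes match up to sign
        for col in range(2):
            assert np.allclose(a[:, col], b[:, col], atol=1e-8) or np.allclose(
                a[:, col], -b[:, col], atol=1e-8
            )

    def test_agrees_with_skbio_on_euclidean_input(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(5)
        X = rng.random((6, 4))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        ours = pcoa(DistanceMatrix(D, ids=[str(i) for i in range(6)]), k=2)
        ref = skbio_pcoa(DistanceMatrix(D, ids=[str(i) for i in range(6)]),
                         dimensions=2)
        ref_coords = ref.samples.to_numpy()
        for col in range(2):
            assert np.allclose(
                ours.coordinates.to_numpy()[:, col], ref_coords[:, col],
                atol=1e-6,
            ) or np.allclose(
                ours.coordinates.to_numpy()[:, col], -ref_coords[:, col],
                atol=1e-6,
            )


def _block_distance():
    """4 samples: within-group d=0, between d=1."""
    D = np.ones((4, 4)) - np.eye(4)
    D[0, 1] = D[1, 0] = 0.0
    D[2, 3] = D[3, 2] = 0.0
    return DistanceMatrix(D, ids=[f"s{i}" for i in range(4)])


class TestPermanova:
    def test_hand_partition_perfect_separation(self):
        D = _block_distance()
        md = make_metadata([f"s{i}" for i in range(4)],
                           ["WAF", "WAF", "CEWAF", "CEWAF"], [0] * 4)
        res = permanova(D, md, ["treatment"], n_perm="exhaustive")
        assert res.table.loc["treatment", "R2"] == pytest.approx(1.0)
        # only label swaps preserving the partition keep F at its max:
        # 8 of 24 permutations tie the observed grouping
        assert res.table.loc["treatment", "p"] == pytest.approx(1 / 3)

    def test_r2_sums_to_one_and_reorder_invariance(self):
        rng = np.random.default_rng(7)
        n = 12
        t = random_proportions_table(rng, 10, n)
        D = bray_curtis(t)
        md = make_metadata(
            t.sample_ids,
            ["WAF"] * 6 + ["CEWAF"] * 6,
            [0, 0, 3, 3, 7, 7] * 2,
            list(range(1, n + 1)),
        )
        r1 = permanova(D, md, ["treatment", "day"], n_perm=49, seed=0)
        r2 = permanova(D, md, ["day", "treatment"], n_perm=49, seed=0)
        assert r1.r2.sum() == pytest.approx(2.0)  # terms+resid + total row
        assert r1.table.drop("Total")["R2"].sum() == pytest.approx(1.0, abs=1e-9)
        # sequential SS: per-term R2 depends on order, their sum does not
        pair1 = r1.table.loc[["treatment", "day"], "R2"]
        pair2 = r2.table.loc[["treatment", "day"], "R2"]
        assert pair1.sum() == pytest.approx(pair2.sum(), abs=1e-9)

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        t = random_proportions_table(rng, 8, 6)
        D = bray_curtis(t)
        md = make_metadata(t.sample_ids, ["WAF"] * 3 + ["CEWAF"] * 3,
                           [0] * 6, [1, 2, 3, 1, 2, 3])
        res = permanova(D, md, ["treatment"], n_perm="exhaustive")
        r2_bf, _ = permanova_oneway_bf(np.asarray(D.data),
                                       ["a"] * 3 + ["b"] * 3)
        p_bf = permanova_exhaustive_p(np.asarray(D.data),
                                      ["a"] * 3 + ["b"] * 3)
        assert res.table.loc["treatment", "R2"] == pytest.approx(r2_bf, abs=1e-10)
        assert res.table.loc["treatment", "p"] == pytest.approx(p_bf, abs=1e-12)

    def test_single_level_term_rejected(self):
        D = _block_distance()
        md = make_metadata([f"s{i}" for i in range(4)], ["WAF"] * 4, [0] * 4)
        with pytest.raises(ValidationError, match="single level"):
            permanova(D, md, ["treatment"], n_perm=9)

    def test_null_pvalues_roughly_uniform(self):
        # free label permutation under a true null: p approximately uniform
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(120):
            t = random_proportions_table(rng, 8, 8)
            D = bray_curtis(t)
            labels = np.array(["WAF"] * 4 + ["CEWAF"] * 4)
            rng.shuffle(labels)
            md = make_metadata(t.sample_ids, list(labels), [0] * 8,
                               list(range(8)))
            res = permanova(D, md, ["treatment"], n_perm=39, seed=1)
            pvals.append(res.table.loc["treatment", "p"])
        # mean of a uniform on the (b+1)/(m+1) grid is ~0.5
        assert np.mean(pvals) == pytest.approx(0.5, abs=0.08)
        assert (np.array(pvals) <= 0.1).mean() < 0.2


class TestLCBD:
    def test_two_samples_split_evenly(self):
        D = DistanceMatrix([[0, 0.6], [0.6, 0]], ids=["a", "b"])
        res = lcbd(D)
        np.testing.assert_allclose(res.values.to_numpy(), [0.5, 0.5])

    def test_equidistant_samples_uniform(self):
        n = 5
        D = DistanceMatrix(np.ones((n, n)) - np.eye(n),
                           ids=[str(i) for i in range(n)])
        res = lcbd(D)
        np.testing.assert_allclose(res.values.to_numpy(), np.full(n, 1 / n))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sums_to_one_property(self, seed):
        rng = np.random.default_rng(seed)
        t = random_proportions_table(rng, 7, 6)
        res = lcbd(bray_curtis(t))
        assert res.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.values >= -1e-12).all()

    def test_matches_gower_diagonal_oracle(self):
        rng = np.random.default_rng(2)
        t = random_proportions_table(rng, 9, 7)
        D = bray_curtis(t)
        res = lcbd(D)
        diag = gower_diag_bf(np.asarray(D.data))
        np.testing.assert_allclose(
            res.values.to_numpy(), diag / diag.sum(), atol=1e-12
        )

    def test_duplicated_sample_shares_value_with_twin(self):
        rng = np.random.default_rng(8)
        X = rng.dirichlet(np.ones(6), size=4).T
        X = np.column_stack([X, X[:, 0]])  # duplicate first sample
        t = make_table(X, mode="proportions")
        res = lcbd(bray_curtis(t))
        assert res.values.iloc[0] == pytest.approx(res.values.iloc[-1], abs=1e-12)

    def test_identical_samples_error(self):
        D = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValidationError, match="identical"):
            lcbd(D)

    def test_permutation_pvalues_returned(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.integers(1, 40, size=(6, 5)))
        from oilcomm.core_io import to_relative_abundance

        props = to_relative_abundance(t)
        res = lcbd(bray_curtis(props), n_perm=19, seed=0,
                   table_for_null=props)
        assert res.p is not None
        assert ((res.p >= 1 / 20) & (res.p <= 1.0)).all()
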