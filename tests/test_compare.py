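import io as _io
import itertools

import dendropy
import numpy as np
import pytest

from embryoquant.compare import (
    SimilarityMatrix,
    StageExpressionTable,
    distance_matrix,
    manders_coefficients,
    profile_vector,
    read_phylip,
    similarity,
    stage_correlation,
    tree_distances,
    tree_quality,
    upgma_newick,
    write_phylip,
)
from embryoquant.profiles import ExpressionProfile
from embryoquant.timenorm import TIME_GRID


def t_profile(values, recording_id="r", gene=""):
    return ExpressionProfile(
        kind="T",
        time_grid=TIME_GRID.copy(),
        values=np.asarray(values, float),
        valid=np.ones(TIME_GRID.size, bool),
        recording_id=recording_id,
        gene_label=gene,
    )


def apt_profile(values, recording_id="r"):
    return ExpressionProfile(
        kind="APT",
        time_grid=TIME_GRID.copy(),
        values=np.asarray(values, float),
        valid=np.ones(TIME_GRID.size, bool),
        recording_id=recording_id,
    )


class TestProfileVector:
    def test_t_profile_on_canonical_grid_is_identity(self):
        vals = np.arange(101.0)
        assert np.array_equal(profile_vector(t_profile(vals)), vals)

    def test_apt_flattens_to_2020(self):
        vec = profile_vector(apt_profile(np.ones((101, 20))))
        assert vec.shape == (2020,)

    def test_early_ending_recording_is_zero_padded(self):
        vals = np.ones(101)
        vals[81:] = 0.0
        prof = t_profile(vals)
        prof.valid = TIME_GRID <= 80
        vec = profile_vector(prof)
        assert np.all(vec[81:] == 0)
        assert np.all(~prof.valid[81:])

    def test_empty_profile_rejected(self):
        prof = t_profile(np.zeros(101))
        prof.values = np.array([])
        with pytest.raises(ValueError):
            profile_vector(prof)


class TestSimilarity:
    def test_self_comparison(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert similarity(v, v, "pearson") == pytest.approx(1.0)
        assert similarity(v, v, "l2") == 0.0

    def test_anticorrelated_vectors(self):
        assert similarity([1, 2, 3], [3, 2, 1], "pearson") == pytest.approx(-1.0)

    def test_l2_is_euclidean_345(self):
        assert similarity([0, 0, 4], [0, 3, 0], "l2") == pytest.approx(5.0)

    def test_constant_vector_under_pearson_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            similarity([1, 1, 1], [1, 2, 3], "pearson")

    def test_manders_overlap_fractions(self):
        a = np.array([1.0, 1.0, 0.0, 2.0])
        b = np.array([0.0, 3.0, 1.0, 3.0])
        m1, m2 = manders_coefficients(a, b)
        assert m1 == pytest.approx(3.0 / 4.0)  # a mass where b > 0
        assert m2 == pytest.approx(6.0 / 7.0)  # b mass where a > 0
        assert similarity(a, b, "manders") == pytest.approx((m1 + m2) / 2)

    @pytest.mark.parametrize("metric", ["pearson", "manders", "l2"])
    def test_symmetry(self, metric):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0.1, 1, 50), rng.uniform(0.1, 1, 50)
        assert similarity(a, b, metric) == pytest.approx(similarity(b, a, metric))


class TestDistanceMatrix:
    def test_identical_profiles_have_zero_distance(self):
        vals = np.sin(TIME_GRID / 15.0) + 2
        m = distance_matrix([t_profile(vals, "a"), t_profile(vals, "b")])
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_three_profiles_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        profs = [t_profile(rng.uniform(0, 1, 101), f"r{i}") for i in range(3)]
        m = distance_matrix(profs, metric="l2")
        assert m.values.shape == (3, 3)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_anticorrelated_pearson_distance_is_2(self):
        up = t_profile(TIME_GRID, "up")
        down = t_profile(TIME_GRID[::-1], "down")
        m = distance_matrix([up, down])
        assert m.values[0, 1] == pytest.approx(2.0)

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError, match="mix"):
            distance_matrix([t_profile(np.ones(101)), apt_profile(np.ones((101, 20)))])


class TestPhylip:
    def test_round_trip_to_1e6(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 2, (4, 4))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        m = SimilarityMatrix(labels=["aa", "bb", "cc", "dd"], metric="pearson", values=d)
        buf = _io.StringIO()
        write_phylip(m, buf)
        buf.seek(0)
        m2 = read_phylip(buf)
        assert m2.labels == m.labels
        np.testing.assert_allclose(m2.values, m.values, atol=1e-6)

    def test_labels_padded_to_10_chars(self):
        m = SimilarityMatrix(labels=["gene_alpha_long", "b"], metric="l2",
                             values=np.array([[0.0, 1.0], [1.0, 0.0]]))
        buf = _io.StringIO()
        write_phylip(m, buf)
        lines = buf.getvalue().splitlines()
        assert lines[1][:10] == "gene_alpha"
        assert lines[2][:10] == "b".ljust(10)


class TestTreeDistances:
    def test_sibling_leaves_are_two_edges_apart(self):
        tree = dendropy.Tree.get(data="(A,B);", schema="newick")
        labels, mu = tree_distances(tree)
        assert mu[labels.index("A"), labels.index("B")] == 2

    def test_balanced_four_leaf_tree_cross_pairs_are_4(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        labels, mu = tree_distances(tree)
        i = {l: k for k, l in enumerate(labels)}
        assert mu[i["A"], i["B"]] == 2
        assert mu[i["A"], i["C"]] == 4
        assert mu[i["B"], i["D"]] == 4

    def test_leaf_to_itself_is_zero(self):
        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        labels, mu = tree_distances(tree)
        assert np.all(np.diag(mu) == 0)

    def test_duplicate_leaf_labels_rejected(self):
        # build by hand: the newick parser itself refuses duplicate taxa
        tree = dendropy.Tree.get(data="(A,B);", schema="newick")
        for lf in tree.leaf_node_iter():
            lf.taxon = dendropy.Taxon("A")
        with pytest.raises(ValueError, match="duplicate"):
            tree_distances(tree)


SIX_LEAF = "((g1a,g1b),((g2a,g3a),(g2b,g3b)));"
SIX_GENES = {"g1a": "g1", "g1b": "g1", "g2a": "g2", "g2b": "g2",
             "g3a": "g3", "g3b": "g3"}


class TestTreeQuality:
    def test_all_sibling_duplicates_give_d2_q0(self):
        tree = dendropy.Tree.get(data="((A1,A2),(B1,B2));", schema="newick")
        rep = tree_quality(tree, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
                           n_boot=50, seed=0)
        assert rep.d == 2.0
        assert rep.q == 0.0

    def test_hand_counted_six_leaf_tree(self):
        """d and r from manual edge counting; D from exhaustive enumeration."""
        tree = dendropy.Tree.get(data=SIX_LEAF, schema="newick")
        labels, mu = tree_distances(tree)
        # manual counts: g1 pair siblings -> 2; g2 recordings sit in the two
        # sub-cherries -> 4 edges; same for g3; r is the g1-to-far-side path
        i = {l: k for k, l in enumerate(labels)}
        assert mu[i["g2a"], i["g2b"]] == 4
        assert mu[i["g3a"], i["g3b"]] == 4
        assert mu[i["g1a"], i["g2b"]] == 5
        rep = tree_quality(tree, SIX_GENES, exhaustive=True)
        assert rep.d == pytest.approx((2 + 4 + 4) / 3)
        assert rep.r == 5
        # independent exhaustive oracle over all 720 label orderings
        genes = [SIX_GENES[l] for l in labels]
        vals = []
        for perm in itertools.permutations(genes):
            per_gene = []
            for g in set(genes):
                idx = [k for k, gg in enumerate(perm) if gg == g]
                per_gene.append(min(mu[a, b] for a, b in itertools.combinations(idx, 2)))
            vals.append(np.mean(per_gene))
        assert rep.D == pytest.approx(np.mean(vals))

    def test_bootstrap_converges_to_exhaustive(self):
        tree = dendropy.Tree.get(data=SIX_LEAF, schema="newick")
        exact = tree_quality(tree, SIX_GENES, exhaustive=True)
        boot = tree_quality(tree, SIX_GENES, n_boot=4000, seed=7)
        assert boot.D == pytest.approx(exact.D, rel=0.02)

    def test_d_never_below_2(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            labels = [f"x{i}" for i in range(8)]
            genes = {l: f"g{i % 4}" for i, l in enumerate(labels)}
            perm = rng.permutation(labels)
            newick = f"((({perm[0]},{perm[1]}),({perm[2]},{perm[3]})),(({perm[4]},{perm[5]}),({perm[6]},{perm[7]})));"
            tree = dendropy.Tree.get(data=newick, schema="newick")
            rep = tree_quality(tree, genes, n_boot=20, seed=trial)
            assert rep.d >= 2.0
            assert rep.r >= rep.d

    def test_no_duplicated_gene_rejected(self):
        tree = dendropy.Tree.get(data="(A,(B,C));", schema="newick")
        with pytest.raises(ValueError, match="undefined|>= 2"):
            tree_quality(tree, {"A": "a", "B": "b", "C": "c"}, n_boot=10, seed=0)


class TestDuplicateRecovery:
    def test_noisy_duplicates_cluster_as_siblings(self):
        """Genes recorded twice with <= 10% noise end with same-gene distance
        2 in a UPGMA tree built from the Pearson-distance matrix, for at
        least 90% of genes."""
        rng = np.random.default_rng(11)
        n_genes = 12
        profs, gene_by_leaf = [], {}
        t = TIME_GRID
        for g in range(n_genes):
            onset = rng.uniform(10, 80)
            width = rng.uniform(5, 25)
            base = np.exp(-((t - onset) ** 2) / (2 * width**2))
            for rep in range(2):
                noisy = np.clip(base + rng.normal(0, 0.1 * base.max(), base.size), 0, None)
                label = f"g{g:02d}rep{rep}"
                profs.append(t_profile(noisy, recording_id=label))
                gene_by_leaf[label] = f"g{g:02d}"
        matrix = distance_matrix(profs, metric="pearson")
        tree = dendropy.Tree.get(data=upgma_newick(matrix), schema="newick")
        labels, mu = tree_distances(tree)
        genes = [gene_by_leaf[l] for l in labels]
        mins = {}
        for g in set(genes):
            idx = [k for k, gg in enumerate(genes) if gg == g]
            mins[g] = min(mu[a, b] for a, b in itertools.combinations(idx, 2))
        frac_sibling = np.mean([v == 2 for v in mins.values()])
        assert frac_sibling >= 0.9


class TestStageCorrelation:
    stages = [("s4", 4), ("s28", 28), ("s55", 55), ("s95", 95), ("s190", 190)]
    stage_times = np.array([0.0, 20.0, 40.0, 60.0, 80.0])

    def _profiles(self, seed=0, n_genes=6):
        rng = np.random.default_rng(seed)
        profs = {}
        for g in range(n_genes):
            onset = rng.uniform(10, 70)
            profs[f"gene{g}"] = np.exp(-((TIME_GRID - onset) ** 2) / 200.0)
        return profs

    def test_self_consistent_table_gives_correlation_1(self):
        profs = self._profiles()
        table = StageExpressionTable(
            stages=self.stages,
            values={g: np.interp(self.stage_times, TIME_GRID, v) for g, v in profs.items()},
        )
        mean_corr, signif = stage_correlation(profs, table, self.stage_times,
                                              n_boot=400, seed=1)
        assert mean_corr == pytest.approx(1.0, abs=1e-9)
        assert signif > 95.0

    def test_shuffled_genes_give_weak_correlation(self):
        profs = self._profiles(seed=3, n_genes=8)
        rng = np.random.default_rng(4)
        names = list(profs)
        shuffled = rng.permutation(names)
        table = StageExpressionTable(
            stages=self.stages,
            values={
                s: np.interp(self.stage_times, TIME_GRID, profs[g])
                for s, g in zip(names, shuffled)
            },
        )
        mean_corr, _ = stage_correlation(profs, table, self.stage_times,
                                         n_boot=200, seed=5)
        # a random pairing should sit well below perfect agreement
        assert mean_corr < 0.8

    def test_fewer_than_three_stages_rejected(self):
        profs = self._profiles()
        table = StageExpressionTable(
            stages=self.stages[:2],
            values={g: np.ones(2) for g in profs},
        )
        with pytest.raises(ValueError, match=">= 3 stages"):
            stage_correlation(profs, table, self.stage_times[:2], n_boot=10, seed=0)

    def test_fewer_than_two_shared_genes_rejected(self):
        profs = self._profiles(n_genes=1)
        table = StageExpressionTable(
            stages=self.stages,
            values={"other": np.ones(5)},
        )
        with pytest.raises(ValueError, match="shared genes"):
            stage_correlation(profs, table, self.stage_times, n_boot=10, seed=0)
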