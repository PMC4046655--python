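"""Poisson-corrected distances and neighbor-joining tree construction."""

import math

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from ctrascan.phylo import (
    ProteinAlignment,
    complete_deletion,
    nj_tree,
    p_distance,
    pipeline_ctra_phylogeny,
    poisson_distance,
    poisson_distance_matrix,
    read_alignment_fasta,
    total_length,
    write_newick,
)
from ctrascan.synthetic_data import evolve_proteins, random_binary_tree


def _aln(*rows, taxa=None):
    taxa = taxa or tuple(f"t{i}" for i in range(len(rows)))
    return ProteinAlignment(taxa=tuple(taxa), rows=tuple(rows))


class TestCompleteDeletion:
    def test_gap_columns_removed(self):
        out = complete_deletion(_aln("AC-D", "ACAD"))
        assert out.rows == ("ACD", "ACD")

    def test_gap_free_alignment_unchanged(self):
        aln = _aln("ACDE", "ACDF")
        assert complete_deletion(aln) == aln

    @pytest.mark.parametrize("bad", ["?", "X", "-"])
    def test_missing_and_ambiguous_treated_like_gaps(self, bad):
        out = complete_deletion(_aln(f"A{bad}CD", "AACD"))
        assert out.rows == ("ACD", "ACD")

    def test_no_complete_columns_is_an_error(self):
        with pytest.raises(ValueError, match="no columns"):
            complete_deletion(_aln("A-", "-A"))


class TestDistances:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("AAAA", "AAAA", 0.0), ("AAAA", "AAAT", 0.25), ("AC", "CA", 1.0)],
    )
    def test_p_distance_examples(self, a, b, expected):
        assert p_distance(a, b) == expected

    def test_p_distance_matches_positional_oracle(self, rng):
        aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(rng.choice(aa, size=200))
        b = "".join(rng.choice(aa, size=200))
        expected = sum(x != y for x, y in zip(a, b)) / 200
        assert p_distance(a, b) == expected

    def test_p_distance_length_mismatch(self):
        with pytest.raises(ValueError):
            p_distance("AA", "AAA")

    @pytest.mark.parametrize(
        "p, expected", [(0.0, 0.0), (0.5, pytest.approx(math.log(2), abs=1e-4))]
    )
    def test_poisson_examples(self, p, expected):
        assert poisson_distance(p) == expected

    def test_poisson_saturated_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            poisson_distance(1.0)

    def test_poisson_is_increasing_and_never_shortens(self):
        ps = np.linspace(0, 0.95, 50)
        ds = [poisson_distance(p) for p in ps]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))
        assert all(d >= p for p, d in zip(ps, ds))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]], ["A", "B", "C"])
        tree = nj_tree(dm)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == {
            "A": pytest.approx(0.1),
            "B": pytest.approx(0.3),
            "C": pytest.approx(0.5),
        }
        assert total_length(tree) == pytest.approx(0.9)

    @pytest.mark.parametrize("n_taxa", [4, 6, 9, 12])
    def test_exact_recovery_of_additive_matrices(self, n_taxa):
        """NJ reproduces tree-like distance matrices to numerical precision."""
        true_tree = random_binary_tree(n_taxa, seed=100 + n_taxa)
        dm = true_tree.tip_tip_distances()
        tree = nj_tree(dm)
        recovered = tree.tip_tip_distances().filter(dm.ids)
        np.testing.assert_allclose(recovered.data, dm.data, atol=1e-9)
        assert true_tree.compare_rfd(tree) == 0.0

    def test_agrees_with_reference_implementation(self):
        """Same topology as scikit-bio's NJ on an additive matrix."""
        true_tree = random_binary_tree(7, seed=77)
        dm = true_tree.tip_tip_distances()
        assert nj_tree(dm).compare_rfd(skbio_nj(dm)) == 0.0

    def test_zero_matrix_gives_zero_lengths(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("ABCD"))
        tree = nj_tree(dm)
        assert total_length(tree) == 0.0
        assert len(list(tree.tips())) == 4

    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix([[0, 0.3], [0.3, 0]], ["A", "B"])
        tree = nj_tree(dm)
        tips = list(tree.tips())
        assert len(tips) == 2
        assert total_length(tree) == pytest.approx(0.3)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0.0]], ["A"]))

    def test_nan_matrix_rejected(self):
        # skbio's DistanceMatrix rejects NaN itself, so feed the validator a bare container
        mat = np.zeros((3, 3))
        mat[0, 1] = mat[1, 0] = np.nan

        class FakeDM:
            data = mat
            ids = ("A", "B", "C")

        with pytest.raises(ValueError, match="non-finite"):
            nj_tree(FakeDM())

    def test_negative_branches_kept_unless_clamped(self):
        # strongly non-additive: the two-point formulas go negative
        dm = DistanceMatrix(
            [
                [0.0, 1.31, 0.61, 0.18],
                [1.31, 0.0, 0.13, 1.65],
                [0.61, 0.13, 0.0, 1.83],
                [0.18, 1.65, 1.83, 0.0],
            ],
            list("ABCD"),
        )
        free = nj_tree(dm)
        clamped = nj_tree(dm, clamp_negative=True)
        assert min(n.length for n in free.traverse(include_self=False)) < 0
        assert min(n.length for n in clamped.traverse(include_self=False)) == 0.0


class TestPipeline:
    def test_reports_retained_positions(self):
        tree = random_binary_tree(10, seed=9)
        alignment, truth = evolve_proteins(tree, 300, seed=9, gap_columns=20)
        _, _, report = pipeline_ctra_phylogeny(alignment)
        assert report["n_taxa"] == 10
        assert report["n_positions_input"] == 300
        assert report["n_positions_retained"] == 280

    def test_identical_sequences_form_zero_length_pair(self):
        aln = _aln("AAAAAAAAAA", "AAAAAAAAAA", "CCAAAAAAAA", "ADDWAAAAAA")
        tree, dm, _ = pipeline_ctra_phylogeny(aln)
        assert dm["t0", "t1"] == 0.0
        assert tree.find("t0").length == pytest.approx(0.0)
        assert tree.find("t1").length == pytest.approx(0.0)
        assert tree.find("t0").parent is tree.find("t1").parent

    def test_saturated_pair_aborts_with_stage_and_pair_named(self):
        aln = _aln("AAAA", "CCCC", "AACC")
        with pytest.raises(ValueError, match=r"poisson_distance.*t0.*t1"):
            pipeline_ctra_phylogeny(aln)

    def test_newick_round_trip_preserves_total_length(self, tmp_path):
        tree = random_binary_tree(9, seed=17)
        alignment, _ = evolve_proteins(tree, 500, seed=18)
        built, _, report = pipeline_ctra_phylogeny(alignment)
        path = tmp_path / "tree.nwk"
        write_newick(built, path)
        reread = TreeNode.read(str(path))
        assert total_length(reread) == pytest.approx(report["total_branch_length"])
        dtree = dendropy.Tree.get(path=str(path), schema="newick")
        assert dtree.length() == pytest.approx(report["total_branch_length"])

    def test_unaligned_fasta_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises(ValueError, match="align"):
            read_alignment_fasta(path)

    def test_aligned_fasta_read(self, tmp_path):
        path = tmp_path / "ok.fasta"
        path.write_text(">a\nAC-E\n>b\nACDE\n")
        aln = read_alignment_fasta(path)
        assert aln.taxa == ("a", "b") and aln.n_columns == 4


class TestEvolutionModel:
    def test_zero_length_branches_give_identical_leaves(self):
        tree = random_binary_tree(5, seed=1, edge_length_range=(0.0, 0.0))
        alignment, _ = evolve_proteins(tree, 100, seed=2)
        assert len(set(alignment.rows)) == 1

    def test_pairwise_divergence_matches_binomial_expectation(self):
        """Two-leaf path of 0.2 subs/site: mean p-distance ~= 1 - exp(-0.2)."""
        newick = "(a:0.1,b:0.1);"
        n_reps, length = 20, 10000
        expected = 1 - math.exp(-0.2)
        ps = []
        for rep in range(n_reps):
            alignment, _ = evolve_proteins(newick, length, seed=1000 + rep)
            ps.append(p_distance(*alignment.rows))
        se = math.sqrt(expected * (1 - expected) / (length * n_reps))
        assert abs(np.mean(ps) - expected) < 3 * se

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            evolve_proteins("(a:0.1,b:-0.1);", 100, seed=0)
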