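import numpy as np
import pytest

from genesieve.region_phylo import (
    DistanceMatrix,
    RegionSpec,
    extract_regions,
    identity_matrix,
    identity_to_distance,
    neighbor_joining,
    pairwise_identity,
    read_region_specs,
    validate_region_set,
)
from oracles import random_additive_tree


def patristic_matrix(newick: str, labels: list[str]) -> np.ndarray:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestExtractRegions:
    def test_concatenation_in_spec_order(self):
        specs = [RegionSpec("a", 1, 3), RegionSpec("b", 5, 6)]
        assert extract_regions("MKTAQW", specs) == "MKTQW"

    def test_single_full_length_region_is_identity(self):
        assert extract_regions("MKTAQW", [RegionSpec("all", 1, 6)]) == "MKTAQW"

    def test_region_past_end_rejected(self):
        with pytest.raises(ValueError, match="alpha1"):
            extract_regions("MKTAQW", [RegionSpec("alpha1", 10, 12)])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            validate_region_set([RegionSpec("a", 1, 5), RegionSpec("b", 4, 8)])

    def test_dash_positions_preserved(self):
        assert extract_regions("MK-AQW", [RegionSpec("a", 2, 4)]) == "K-A"

    def test_region_spec_tsv_round_trip(self, tmp_path):
        p = tmp_path / "regions.tsv"
        p.write_text("name\tstart\tend\nalpha1\t1\t10\nbeta\t20\t30\n")
        specs = read_region_specs(p)
        assert specs == [RegionSpec("alpha1", 1, 10), RegionSpec("beta", 20, 30)]


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAA", "AAAT", 75.0),
            ("MKTA", "MKTA", 100.0),
            ("A-AA", "AGAT", 100 * 2 / 3),  # gap column excluded
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        assert pairwise_identity("MKWA", "MKTA") == pairwise_identity("MKTA", "MKWA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_identity("MK", "MKT")

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("--AA", "AA--")

    @pytest.mark.parametrize("identity,expected", [(100.0, 0.0), (0.0, 100.0), (60.0, 40.0)])
    def test_identity_to_distance(self, identity, expected):
        assert identity_to_distance(identity) == expected


class TestNeighborJoining:
    def test_four_taxon_additive_tree_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1): path-length matrix by hand
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        newick = neighbor_joining(DistanceMatrix(labels, D))
        recovered = patristic_matrix(newick, labels)
        np.testing.assert_allclose(recovered, D, atol=1e-9)

    def test_equidistant_three_taxa(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        newick = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        recovered = patristic_matrix(newick, ["A", "B", "C"])
        np.testing.assert_allclose(recovered, D, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_random_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            labels, D = random_additive_tree(n, rng)
            newick = neighbor_joining(DistanceMatrix(labels, D))
            recovered = patristic_matrix(newick, labels)
            np.testing.assert_allclose(recovered, D, atol=1e-9)

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(17)
        labels, D = random_additive_tree(6, rng)
        perm = rng.permutation(6)
        newick_a = neighbor_joining(DistanceMatrix(labels, D))
        newick_b = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], D[np.ix_(perm, perm)])
        )
        np.testing.assert_allclose(
            patristic_matrix(newick_a, labels), patristic_matrix(newick_b, labels), atol=1e-9
        )

    def test_divergent_taxon_gets_longer_terminal_branch(self):
        # mirror of the long-branch signal: more substitutions in a region
        # extract monotonically lengthen that taxon's terminal branch
        base = "MKTAYIAKQRNDWEHLFVGS"
        variants = {"ref1": base, "ref2": base[:-1] + "W"}
        lengths = []
        for k in (4, 8, 12):
            mutated = "".join(
                ("W" if c != "W" else "Y") if i < k else c for i, c in enumerate(base)
            )
            seqs = dict(variants, outlier=mutated)
            newick = neighbor_joining(identity_matrix(seqs))
            import dendropy

            tree = dendropy.Tree.get(data=newick, schema="newick")
            leaf = [l for l in tree.leaf_node_iter() if l.taxon.label == "outlier"][0]
            lengths.append(leaf.edge.length)
        assert lengths[0] < lengths[1] < lengths[2]


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_identity_matrix_of_identical_sequences_is_zero(self):
        dm = identity_matrix({"a": "MKTA", "b": "MKTA", "c": "MKTW"})
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(25.0)
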