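import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matloci.allelic import (
    AAIMatrix,
    aai_cluster,
    clade_concordance,
    nj_tree,
    pairwise_aai,
    reciprocal_monophyly,
)
from matloci.errors import ValidationError
from matloci.io import read_newick

from conftest import make_alignment


def prot_alignment(seqs):
    return make_alignment(seqs, alphabet="protein")


class TestAAI:
    def test_identical_proteins_100(self):
        m = pairwise_aai(prot_alignment({"A1": "MKLV", "A2": "MKLV"}))
        assert m.value("A1", "A2") == 100.0

    def test_single_mismatch(self):
        m = pairwise_aai(prot_alignment({"A1": "AAAA", "A2": "AAAT"}))
        assert m.value("A1", "A2") == 75.0

    def test_gap_vs_residue_counts_as_mismatch(self):
        m = pairwise_aai(prot_alignment({"A1": "AA-A", "A2": "AAAA"}))
        assert m.value("A1", "A2") == 75.0

    def test_gap_vs_gap_column_excluded(self):
        m = pairwise_aai(prot_alignment({"A1": "AA-A", "A2": "AA-A"}))
        assert m.value("A1", "A2") == 100.0

    def test_dna_alignment_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_aai(make_alignment({"A1": "ACGT", "A2": "ACGT"}))


def block_matrix(sizes, within=95.0, between=70.0):
    """Matrix of blocks with high within- and low between-identity."""
    labels = []
    for bi, size in enumerate(sizes):
        labels += [f"s{bi}_{i}" for i in range(size)]
    n = len(labels)
    blocks = np.repeat(np.arange(len(sizes)), sizes)
    mat = np.where(blocks[:, None] == blocks[None, :], within, between)
    np.fill_diagonal(mat, 100.0)
    return AAIMatrix(strains=labels, matrix=mat)


class TestCluster:
    def test_all_similar_is_one_class(self):
        cls = aai_cluster(block_matrix([5], within=95.0), tau=86.0)
        assert cls.n_classes == 1

    def test_two_blocks_match_connected_components(self):
        m = block_matrix([3, 4])
        cls = aai_cluster(m, tau=86.0)
        assert cls.n_classes == 2
        # brute-force connected components oracle on the >= tau graph
        adj = m.matrix >= 86.0
        seen, comps = set(), []
        for i in range(len(m.strains)):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(v for v in range(len(m.strains)) if adj[u, v])
            seen |= comp
            comps.append(frozenset(m.strains[v] for v in comp))
        got = {
            frozenset(cls.members(c)) for c in set(cls.class_of.values())
        }
        assert got == set(comps)

    def test_labels_canonical_largest_first(self):
        cls = aai_cluster(block_matrix([2, 5]), tau=86.0)
        assert len(cls.members(1)) == 5
        assert len(cls.members(2)) == 2

    def test_order_invariance(self):
        m = block_matrix([3, 2, 4])
        cls1 = aai_cluster(m, tau=86.0)
        perm = [7, 2, 5, 0, 8, 1, 3, 6, 4]
        m2 = AAIMatrix(
            strains=[m.strains[i] for i in perm],
            matrix=m.matrix[np.ix_(perm, perm)],
        )
        cls2 = aai_cluster(m2, tau=86.0)
        assert cls1.class_of == cls2.class_of

    def test_chain_connectivity_single_linkage(self):
        # a-b and b-c similar but a-c dissimilar: single linkage joins all
        mat = np.array(
            [[100.0, 90.0, 50.0], [90.0, 100.0, 90.0], [50.0, 90.0, 100.0]]
        )
        m = AAIMatrix(strains=["a", "b", "c"], matrix=mat)
        assert aai_cluster(m, tau=86.0).n_classes == 1

    def test_threshold_inclusive(self):
        mat = np.array([[100.0, 86.0], [86.0, 100.0]])
        m = AAIMatrix(strains=["a", "b"], matrix=mat)
        assert aai_cluster(m, tau=86.0).n_classes == 1

    def test_bad_tau(self):
        with pytest.raises(ValidationError):
            aai_cluster(block_matrix([3]), tau=0.0)
        with pytest.raises(ValidationError):
            aai_cluster(block_matrix([3]), tau=101.0)


def _tree_distances(newick, labels):
    """Leaf-to-leaf path distances from a Newick string (via dendropy)."""
    tree = read_newick(newick)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d


def _topology(newick):
    """Set of non-trivial splits (as frozensets of leaf labels)."""
    tree = read_newick(newick)
    leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    splits = set()
    for node in tree.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(clade) < len(leaves) - 1:
            comp = leaves - clade
            if len(clade) != len(comp):
                canon = clade if len(clade) < len(comp) else comp
            else:
                canon = min(clade, comp, key=lambda s: tuple(sorted(s)))
            splits.add(canon)
    return leaves, splits


class TestNJ:
    def test_additive_distances_recover_topology(self):
        # distances generated on ((a,b),(c,d)) with known branch lengths
        gen = "((a:0.02,b:0.03):0.05,(c:0.04,d:0.01):0.05);"
        labels = ["a", "b", "c", "d"]
        d = _tree_distances(gen, labels)
        m = AAIMatrix(strains=labels, matrix=100.0 - 100.0 * d)
        nwk = nj_tree(m)
        _, splits = _topology(nwk)
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits

    def test_matches_skbio_on_additive_6_taxon_trees(self, rng):
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        for rep in range(5):
            # random additive tree over 6 taxa
            labels = [f"t{i}" for i in range(6)]
            nwk = _random_tree_newick(labels, rng)
            d = _tree_distances(nwk, labels)
            m = AAIMatrix(strains=labels, matrix=100.0 - 100.0 * d)
            ours = nj_tree(m)
            dm = skbio.DistanceMatrix(d, ids=labels)
            theirs = skbio.tree.nj(dm)
            _, splits_ours = _topology(ours)
            _, splits_ref = _topology(str(theirs).strip())
            assert splits_ours == splits_ref

    def test_equal_distances_deterministic(self):
        mat = np.full((4, 4), 80.0)
        np.fill_diagonal(mat, 100.0)
        m = AAIMatrix(strains=["a", "b", "c", "d"], matrix=mat)
        assert nj_tree(m) == nj_tree(m)

    def test_fewer_than_three_taxa_rejected(self):
        mat = np.array([[100.0, 90.0], [90.0, 100.0]])
        with pytest.raises(ValidationError):
            nj_tree(AAIMatrix(strains=["a", "b"], matrix=mat))


def _random_tree_newick(labels, rng):
    """Random binary tree with random positive branch lengths."""
    nodes = [f"{l}:{rng.uniform(0.01, 0.2):.4f}" for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.01, 0.2):.4f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


class TestCladeConcordance:
    def test_matching_classes_concordant(self):
        from matloci.allelic import AllelicClassification

        cls = AllelicClassification(
            "g", {"a": 1, "b": 1, "c": 2, "d": 2}, 86.0, 2
        )
        flags = clade_concordance(cls, "((a,b),(c,d));")
        assert flags == {1: True, 2: True}

    def test_crossing_classes_discordant(self):
        from matloci.allelic import AllelicClassification

        cls = AllelicClassification(
            "g", {"a": 1, "c": 1, "b": 2, "d": 2}, 86.0, 2
        )
        flags = clade_concordance(cls, "((a,b),(c,d));")
        assert flags == {1: False, 2: False}

    def test_leaf_mismatch_lists_difference(self):
        from matloci.allelic import AllelicClassification

        cls = AllelicClassification("g", {"a": 1, "b": 1, "x": 2}, 86.0, 2)
        with pytest.raises(ValidationError, match="x"):
            clade_concordance(cls, "((a,b),(c,d));")


class TestReciprocalMonophyly:
    @pytest.mark.parametrize(
        "newick,expected_a,expected_b",
        [
            ("(((A1,A2),(B1,B2)),OUT);", True, True),
            ("(((A1,B1),(A2,B2)),OUT);", False, False),
            ("((((B1,B2),A1),A2),OUT);", False, True),
        ],
    )
    def test_rooted_examples(self, newick, expected_a, expected_b):
        species_of = {
            "A1": "A", "A2": "A", "B1": "B", "B2": "B", "OUT": "out",
        }
        sp = {k: v for k, v in species_of.items() if k != "OUT"}
        flags, overall = reciprocal_monophyly(newick, sp, outgroup_label="OUT")
        assert flags["A"] is expected_a
        assert flags["B"] is expected_b
        assert overall is (expected_a and expected_b)

    def test_missing_outgroup_raises(self):
        with pytest.raises(ValidationError, match="OUT"):
            reciprocal_monophyly(
                "((A1,A2),(B1,B2));",
                {"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
                outgroup_label="OUT",
            )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    sizes=st.lists(st.integers(min_value=1, max_value=4), min_size=2, max_size=4),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_cluster_invariant_to_input_order(sizes, seed):
    """Canonical labelling makes aai_cluster exactly order-invariant."""
    m = block_matrix(sizes)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(m.strains))
    m2 = AAIMatrix(
        strains=[m.strains[i] for i in perm],
        matrix=m.matrix[np.ix_(perm, perm)],
    )
    assert aai_cluster(m, 86.0).class_of == aai_cluster(m2, 86.0).class_of
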