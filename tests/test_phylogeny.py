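import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from domainmine.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    compute_distances,
    midpoint_root,
    neighbor_joining,
    read_newick,
    write_newick,
)


def random_binary_tree(n_leaves, rng):
    tns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        nd = dendropy.Node(taxon=tns.new_taxon(f"L{i}"))
        nd.edge.length = rng.exponential(0.3) + 0.05
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = dendropy.Node()
        p.add_child(nodes[int(i)])
        p.add_child(nodes[int(j)])
        p.edge.length = rng.exponential(0.3) + 0.05
        nodes = [n for k, n in enumerate(nodes) if k not in (int(i), int(j))] + [p]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = False
    return tree


def path_distance_matrix(tree):
    """Additive matrix straight from the generating tree (the oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, D


def rf_distance(newick_a, newick_b):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return treecompare.symmetric_difference(a, b)


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        dm = compute_distances({"a": "MKLV", "b": "MKLV", "c": "MKIV"})
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.matrix[i, j] == 0.0

    def test_p_distance_closed_form(self):
        row = "A" * 100
        row2 = "C" + "A" * 99
        dm = compute_distances({"a": row, "b": row2, "c": row}, model="p-distance")
        assert dm.matrix[dm.labels.index("a"), dm.labels.index("b")] == pytest.approx(0.01)

    def test_poisson_correction_dominates_p_distance(self, ks_db):
        p = compute_distances(ks_db.alignment, model="p-distance")
        poisson = compute_distances(ks_db.alignment, model="poisson")
        assert (poisson.matrix >= p.matrix - 1e-12).all()

    def test_sparse_overlap_pairs_are_flagged(self):
        rows = {
            "a": "MKLVWYHHDE" + "-" * 30,
            "b": "-" * 30 + "MKLVWYHHDE",
            "c": "MKLVWYHHDE" + "MKLVWYHHDE" + "MKLVWYHHDE" + "MKLVWYHHDE",
        }
        dm = compute_distances(rows)
        assert ("a", "b") in dm.flagged_pairs

    def test_fewer_than_three_rows_rejected(self):
        with pytest.raises(PhylogenyError):
            compute_distances({"a": "MK", "b": "MK"})


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D, []))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0), "c": pytest.approx(3.0)}

    def test_recovers_additive_topologies_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            true = random_binary_tree(8, rng)
            labels, D = path_distance_matrix(true)
            est = neighbor_joining(DistanceMatrix(labels, D, []))
            assert rf_distance(write_newick(est), true.as_string(schema="newick")) == 0

    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        true = random_binary_tree(8, rng)
        labels, D = path_distance_matrix(true)
        perm = rng.permutation(len(labels))
        t1 = neighbor_joining(DistanceMatrix(labels, D, []))
        t2 = neighbor_joining(
            DistanceMatrix([labels[k] for k in perm], D[np.ix_(perm, perm)], [])
        )
        assert rf_distance(write_newick(t1), write_newick(t2)) == 0

    def test_agrees_with_scikit_bio(self):
        """Dual-route check against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        true = random_binary_tree(10, rng)
        labels, D = path_distance_matrix(true)
        ours = neighbor_joining(DistanceMatrix(labels, D, []))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        assert rf_distance(write_newick(ours), str(theirs)) == 0

    def test_nonfinite_distances_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(PhylogenyError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], np.nan_to_num(D) * np.nan, []))


class TestRooting:
    def test_two_leaf_midpoint_splits_evenly(self):
        tree = read_newick("(A:0.6,B:0.4);")
        rooted = midpoint_root(tree)
        lengths = sorted(lf.edge.length for lf in rooted.leaf_node_iter())
        assert lengths == [pytest.approx(0.5), pytest.approx(0.5)]

    def test_long_terminal_branch_attracts_the_root(self):
        tree = read_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:5.0):0.1);")
        rooted = midpoint_root(tree)
        # root children: D alone on one side of the longest path midpoint
        sides = [
            {lf.taxon.label for lf in child.leaf_iter()}
            for child in rooted.seed_node.child_nodes()
        ]
        assert {"D"} in sides

    def test_midpoint_rooting_is_topology_idempotent(self):
        rng = np.random.default_rng(23)
        tree = random_binary_tree(8, rng)
        r1 = midpoint_root(tree)
        r2 = midpoint_root(r1)
        assert rf_distance(write_newick(r1), write_newick(r2)) == 0


class TestNewick:
    def test_parse_two_leaves(self):
        tree = read_newick("(A:1,B:2);")
        assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"A", "B"}

    def test_round_trip_corpus(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tree = random_binary_tree(int(rng.integers(4, 12)), rng)
            text = write_newick(tree)
            assert write_newick(read_newick(text)) == text

    def test_labels_with_spaces_are_quoted(self):
        tree = read_newick("('my taxon':1,B:2);")
        text = write_newick(tree)
        assert "my taxon" in text
        assert {lf.taxon.label for lf in read_newick(text).leaf_node_iter()} == {"my taxon", "B"}

    def test_malformed_newick_raises(self):
        with pytest.raises(PhylogenyError):
            read_newick("((A:1,B:2;")


def test_reference_tree_separates_fas_from_type_i(ks_db):
    """On the shipped reference set the FAS clade stays apart from the
    modular type I PKS classes, mirroring the canonical KS split."""
    dm = compute_distances(ks_db.alignment)
    rooted = midpoint_root(neighbor_joining(dm))
    fas = {d.domain_id for d in ks_db if d.class_label == "FAS"}
    type_i = {d.domain_id for d in ks_db if d.class_label in ("Cis-AT", "Trans-AT")}
    mrca = rooted.mrca(taxon_labels=sorted(fas))
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    assert fas <= clade
    assert not (clade & type_i)
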